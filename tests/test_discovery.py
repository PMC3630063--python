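"""Hairpin excision, star location, plant miRNA criteria, catalog summaries."""

import numpy as np
import pytest

from plantmir.catalog import load_novel_mirna_catalog
from plantmir.discovery import (
    HairpinCandidate,
    NovelMiRNA,
    Rejection,
    discover_novel,
    evaluate_meyers,
    excise_and_fold,
    find_star,
    summarize_novel,
)
from plantmir.fold import fold_rna
from plantmir.preprocess import Locus, UniqueTag
from plantmir.seqtools import random_rna, revcomp


def make_hairpin(mature, prefix=2, suffix=4, loop="AAUAAUAA", rng=None):
    """Precursor with the mature on the 5' arm of a perfect stem."""
    rng = rng or np.random.default_rng(0)
    arm5 = random_rna(rng, prefix) + mature + random_rna(rng, suffix)
    pre = arm5 + loop + revcomp(arm5)
    structure, mfe = fold_rna(pre)
    return HairpinCandidate(
        pre, Locus("s1", 1, len(pre), "+"), structure, mfe, prefix, len(mature)
    )


class TestFindStar:
    def test_hand_constructed_perfect_stem(self):
        """Star pairs mature positions 1..L-2 and adds a 2-nt 3' overhang."""
        rng = np.random.default_rng(1)
        mature = random_rna(rng, 21)
        h = make_hairpin(mature, prefix=2, suffix=2, rng=rng)
        star, off = find_star(h)
        assert len(star) == 21
        # paired block: reverse complement of mature positions 1..19
        assert star[:19] == revcomp(mature[:19])
        # the 2-nt 3' overhang pairs the two bases 5' of the mature
        assert star[19:] == revcomp(h.precursor[:2])

    def test_planted_simulator_pairs(self, default_sim):
        for m in default_sim["truth"].mirnas:
            structure, mfe = fold_rna(m.precursor)
            h = HairpinCandidate(
                m.precursor,
                Locus(m.scaffold, m.start, m.end, m.strand),
                structure,
                mfe,
                m.mature_offset,
                len(m.mature),
            )
            star, _ = find_star(h)
            assert star == m.star

    def test_mature_on_loop_is_an_error(self):
        rng = np.random.default_rng(2)
        arm = random_rna(rng, 25)
        pre = arm + random_rna(rng, 21) + revcomp(arm)
        structure, mfe = fold_rna(pre)
        h = HairpinCandidate(pre, Locus("s1", 1, len(pre), "+"), structure, mfe, 27, 17)
        with pytest.raises(ValueError):
            find_star(h)


class TestExciseAndFold:
    def test_planted_tag_yields_candidate_with_correct_arm(self, default_sim):
        truth = default_sim["truth"]
        genome = default_sim["genome"]
        for m in truth.mirnas[:4]:
            if m.strand == "+":
                t_start = m.start + m.mature_offset
            else:
                t_start = m.end - m.mature_offset - len(m.mature) + 1
            hit = Locus(m.scaffold, t_start, t_start + len(m.mature) - 1, m.strand)
            cands = excise_and_fold(hit, genome, len(m.mature))
            assert cands, f"no hairpin for planted {m.name}"
            best = min(cands, key=lambda c: c.mfe)
            assert best.arm == m.arm
            assert best.locus.start <= m.end and best.locus.end >= m.start

    def test_lp_equals_interval_length(self, default_sim):
        m = default_sim["truth"].mirnas[0]
        t_start = m.start + m.mature_offset
        hit = Locus(m.scaffold, t_start, t_start + len(m.mature) - 1, "+")
        for cand in excise_and_fold(hit, default_sim["genome"], len(m.mature)):
            assert cand.lp == cand.locus.end - cand.locus.start + 1

    def test_random_loci_never_yield_accepted_mirnas(self, rng):
        """Random tags may sit in fortuitous stems, but without star reads
        and duplex geometry none survives the full criteria."""
        genome = {"chr": random_rna(rng, 40_000)}
        accepted = 0
        for _ in range(30):
            start = int(rng.integers(300, 39_700))
            tag_seq = genome["chr"][start - 1 : start + 20]
            hit = Locus("chr", start, start + 20, "+")
            for cand in excise_and_fold(hit, genome, 21):
                res = evaluate_meyers(cand, {tag_seq: (5, 5)})
                accepted += isinstance(res, NovelMiRNA)
        assert accepted == 0


class TestEvaluateMeyers:
    def test_planted_with_star_reads_accepted(self, default_sim):
        m = default_sim["truth"].mirnas[0]
        structure, mfe = fold_rna(m.precursor)
        h = HairpinCandidate(
            m.precursor, Locus(m.scaffold, m.start, m.end, m.strand), structure, mfe,
            m.mature_offset, len(m.mature),
        )
        res = evaluate_meyers(h, {m.mature: (10, 12), m.star: (1, 0)})
        assert isinstance(res, NovelMiRNA)
        assert res.star == m.star
        assert res.count_control == 10 and res.star_count_drought == 0

    def test_no_star_reads_rejected(self, default_sim):
        m = default_sim["truth"].mirnas[0]
        structure, mfe = fold_rna(m.precursor)
        h = HairpinCandidate(
            m.precursor, Locus(m.scaffold, m.start, m.end, m.strand), structure, mfe,
            m.mature_offset, len(m.mature),
        )
        res = evaluate_meyers(h, {m.mature: (10, 12)})
        assert isinstance(res, Rejection)
        assert res.reason == "no star evidence"

    def test_unstable_precursor_rejected(self):
        rng = np.random.default_rng(3)
        mature = random_rna(rng, 21)
        h = make_hairpin(mature, rng=rng)
        star, _ = find_star(h)
        res = evaluate_meyers(h, {mature: (5, 5), star: (1, 1)}, mfe_threshold=-500.0)
        assert isinstance(res, Rejection)
        assert "stable" in res.reason

    def test_five_duplex_mismatches_rejected(self):
        rng = np.random.default_rng(4)
        mature = random_rna(rng, 21)
        arm5 = "GC" + mature + "GCAU"
        arm3 = list(revcomp(arm5))
        # disrupt 5 pairings inside the mature body (positions 5..9)
        n = 2 * len(arm5) + 8
        for mpos in (5, 6, 7, 8, 9):
            p = n + 1 - (2 + mpos)  # partner of precursor position 2+mpos
            i = p - len(arm5) - 8 - 1
            base = arm3[i]
            arm3[i] = {"A": "C", "C": "A", "G": "A", "U": "C"}[base]
        pre = arm5 + "AAUAAUAA" + "".join(arm3)
        structure, mfe = fold_rna(pre)
        h = HairpinCandidate(pre, Locus("s1", 1, len(pre), "+"), structure, mfe, 2, 21)
        star, _ = find_star(h)
        res = evaluate_meyers(h, {mature: (5, 5), star: (1, 1)})
        assert isinstance(res, Rejection)
        assert res.reason in ("duplex mismatches", "duplex bulge")


class TestDiscoverNovel:
    def test_recovers_all_planted_without_false_loci(self, annotated_tags, default_sim):
        novel, _rej = discover_novel(annotated_tags, default_sim["genome"])
        truth = default_sim["truth"]
        planted = [(m.scaffold, m.strand, m.start, m.end) for m in truth.mirnas]

        def overlaps_planted(m):
            l = m.hairpin.locus
            return any(
                l.scaffold == s and l.strand == st and l.start <= e and l.end >= a
                for s, st, a, e in planted
            )

        assert all(overlaps_planted(m) for m in novel)
        recovered = sum(
            1
            for s, st, a, e in planted
            if any(
                m.hairpin.locus.scaffold == s
                and m.hairpin.locus.strand == st
                and m.hairpin.locus.start <= e
                and m.hairpin.locus.end >= a
                for m in novel
            )
        )
        assert recovered >= 0.9 * len(planted)

    def test_family_grouping_by_identical_sequence(self, annotated_tags, default_sim):
        novel, _ = discover_novel(annotated_tags, default_sim["genome"])
        by_family = {}
        for m in novel:
            by_family.setdefault(m.family, set()).add(m.mature)
        for seqs in by_family.values():
            assert len(seqs) == 1  # one sequence per family
        seq_to_family = {}
        for m in novel:
            assert seq_to_family.setdefault(m.mature, m.family) == m.family


@pytest.fixture(scope="module")
def catalog():
    return load_novel_mirna_catalog()


class TestCatalogSummary:

    def test_entry_count(self, catalog):
        assert len(catalog) == 65

    def test_length_histogram(self, catalog):
        s = summarize_novel(catalog)
        assert s["length_histogram"] == {19: 5, 20: 5, 21: 47, 22: 8}

    def test_family_count(self, catalog):
        assert summarize_novel(catalog)["n_families"] == 54

    def test_least_stable_precursor(self, catalog):
        assert summarize_novel(catalog)["mef_max"] == pytest.approx(-31.9)

    def test_coordinate_length_convention(self, catalog):
        row = catalog[catalog["name"] == "Ptc-miRn5"].iloc[0]
        assert row["interval_length"] == 103 == row["lp_nt"]

    def test_first_nucleotide_bias_is_computed(self, catalog):
        s = summarize_novel(catalog)
        assert sum(s["first_nucleotide_counts"].values()) == 65
        assert max(s["first_nucleotide_fraction"], key=s["first_nucleotide_fraction"].get) == "U"
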