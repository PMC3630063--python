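"""Read cleaning, collapsing, exact mapping, annotation, siRNA duplexes."""

import numpy as np
import pytest

from plantmir.preprocess import (
    GenomeIndex,
    Locus,
    UniqueTag,
    annotate_tags,
    clean_and_collapse,
    length_stats,
    map_perfect,
    merge_tag_sets,
    parse_gff3_structural,
    sirna_duplex_scan,
    tags_to_fasta,
)
from plantmir.seqtools import random_rna, revcomp, to_dna

ADAPTER = "UCGUAUGCCGUCUUCUGCUUG"


def fastq(*reads, qual_char="I"):
    out = []
    for i, seq in enumerate(reads):
        out.append(f"@r{i}\n{to_dna(seq)}\n+\n{qual_char * len(seq)}\n")
    return "".join(out)


class TestCleanAndCollapse:
    def test_trims_adapter_and_keeps_insert(self):
        insert = "ACGUACGUACGUACGUACGUA"  # 21 nt
        tags = clean_and_collapse(fastq(insert + ADAPTER), ADAPTER)
        assert len(tags) == 1
        assert tags[0].sequence == insert
        assert tags[0].count_control == 1

    def test_identical_reads_merge_counts(self):
        insert = "ACGUACGUACGUACGUACGUA"
        tags = clean_and_collapse(fastq(insert + ADAPTER, insert + ADAPTER), ADAPTER)
        assert len(tags) == 1 and tags[0].count_control == 2

    def test_length_gates(self):
        short = "ACGUACGUACGUACGUA"  # 17 nt: below the 18-nt floor
        long31 = "ACGUACGUACGUACGUACGUACGUACGUACG"  # 31 nt
        ok = "ACGUACGUACGUACGUAC"  # 18 nt
        tags = clean_and_collapse(
            fastq(short + ADAPTER, long31 + ADAPTER, ok + ADAPTER), ADAPTER
        )
        assert [t.sequence for t in tags] == [ok]

    def test_low_quality_dropped(self):
        insert = "ACGUACGUACGUACGUACGUA"
        text = fastq(insert + ADAPTER, qual_char="#")  # Phred 2
        assert clean_and_collapse(text, ADAPTER) == []

    def test_no_adapter_discarded_and_t_mapped_to_u(self):
        insert = "ACGTACGTACGTACGTACGTA"
        tags = clean_and_collapse(fastq(insert + ADAPTER), ADAPTER)
        assert tags[0].sequence == insert.replace("T", "U")
        assert clean_and_collapse(fastq(insert), ADAPTER) == []

    def test_malformed_fastq_names_record(self):
        good = f"@r0\nACGT\n+\nIIII\n"
        bad = "@r1\nACGTACGT\n+\nII\n"  # quality length mismatch
        with pytest.raises(ValueError, match="record"):
            clean_and_collapse(good + bad, ADAPTER)

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            clean_and_collapse("", "")

    def test_drought_library_fills_other_count(self):
        insert = "ACGUACGUACGUACGUACGUA"
        tags = clean_and_collapse(fastq(insert + ADAPTER), ADAPTER, library="drought")
        assert tags[0].count_drought == 1 and tags[0].count_control == 0


def test_merge_tag_sets_sums_per_library():
    a = [UniqueTag("ACGU" * 5, count_control=3)]
    b = [UniqueTag("ACGU" * 5, count_drought=4), UniqueTag("UGCA" * 5, count_drought=1)]
    merged = {t.sequence: t for t in merge_tag_sets(a, b)}
    assert merged["ACGU" * 5].count_control == 3
    assert merged["ACGU" * 5].count_drought == 4
    assert merged["UGCA" * 5].count_drought == 1


class TestMapPerfect:
    def test_unique_hit_and_absent_tag(self, rng):
        genome = {"s1": random_rna(rng, 5000)}
        tag_seq = genome["s1"][100:121]
        absent = "U" * 21  # poly-U will not occur by chance at this length
        tags = [UniqueTag(tag_seq), UniqueTag(absent)]
        map_perfect(tags, genome)
        assert tags[0].hits == [Locus("s1", 101, 121, "+")]
        assert tags[1].annotation == "unmapped" and tags[1].hits == []

    def test_reverse_strand_hit(self, rng):
        genome = {"s1": random_rna(rng, 2000)}
        tag_seq = revcomp(genome["s1"][500:522])
        (tag,) = map_perfect([UniqueTag(tag_seq)], genome)
        assert tag.hits == [Locus("s1", 501, 522, "-")]

    def test_multi_hit_cap(self, rng):
        core = random_rna(rng, 30)
        genome = {"s1": core.join(random_rna(rng, 50) for _ in range(25))}
        (tag,) = map_perfect([UniqueTag(core[:20])], genome, max_hits=5)
        assert tag.annotation == "unmapped"

    def test_agrees_with_naive_full_scan(self, rng):
        genome = {"a": random_rna(rng, 30_000), "b": random_rna(rng, 20_000)}
        index = GenomeIndex(genome)
        queries = []
        for _ in range(500):
            sc = "a" if rng.random() < 0.5 else "b"
            n = int(rng.integers(18, 31))
            i = int(rng.integers(0, len(genome[sc]) - n))
            q = genome[sc][i : i + n]
            queries.append(revcomp(q) if rng.random() < 0.5 else q)
        queries += [random_rna(rng, 21) for _ in range(500)]

        def naive(q):
            hits = []
            for name, seq in genome.items():
                for probe, strand in ((q, "+"), (revcomp(q), "-")):
                    start = seq.find(probe)
                    while start >= 0:
                        hits.append(Locus(name, start + 1, start + len(q), strand))
                        start = seq.find(probe, start + 1)
            return sorted(hits, key=lambda h: (h.scaffold, h.start, h.strand))

        tags = [UniqueTag(q) for q in queries]
        map_perfect(tags, index, max_hits=10**9)
        for tag in tags:
            assert tag.hits == naive(tag.sequence)


class TestAnnotate:
    GFF = "##gff-version 3\ns1\tx\trRNA\t101\t220\t.\t+\t.\tID=r1\n"

    def test_structural_beats_known(self):
        tag = UniqueTag("ACGUACGUACGUACGUACGUA", hits=[Locus("s1", 150, 170, "+")])
        annotate_tags([tag], self.GFF, {"mir": tag.sequence})
        assert tag.annotation == "structural"

    def test_shifted_known_match(self):
        mature = "ACGUACGUACGUACGUACGUA"
        tag = UniqueTag(mature + "G", hits=[Locus("s1", 1000, 1021, "+")])
        annotate_tags([tag], self.GFF, {"mir": mature})
        assert tag.annotation == "known_mirna"

    def test_shift_beyond_two_is_not_known(self):
        mature = "ACGUACGUACGUACGUACGUA"
        tag = UniqueTag(mature + "GGG", hits=[Locus("s1", 1000, 1023, "+")])
        annotate_tags([tag], self.GFF, {"mir": mature})
        assert tag.annotation == "candidate"

    def test_unmatched_tag_is_candidate(self):
        tag = UniqueTag("ACGUACGUACGUACGUACGUA", hits=[Locus("s1", 1000, 1020, "+")])
        annotate_tags([tag], self.GFF, {})
        assert tag.annotation == "candidate"

    def test_structural_by_sequence_identity_option(self):
        rrna = "ACGUACGUACGUACGUACGUACGUACGUACGUA"
        tag = UniqueTag(rrna[4:28], hits=[Locus("s2", 500, 523, "+")])
        annotate_tags([tag], self.GFF, {}, structural_sequences={"rrna1": rrna})
        assert tag.annotation == "structural"

    def test_bad_gff_rejected(self):
        with pytest.raises(ValueError, match="end < start"):
            parse_gff3_structural("s1\tx\trRNA\t220\t101\t.\t+\t.\tID=r1")


class TestLengthStats:
    def test_worked_example(self):
        tags = [
            UniqueTag("A" * 21, count_control=10),
            UniqueTag("C" * 21, count_control=2),
            UniqueTag("G" * 24, count_control=1),
        ]
        df = length_stats(tags).set_index("length")
        assert df.loc[21, "unique"] == 2 and df.loc[21, "redundant"] == 12
        assert df.loc[21, "ratio"] == 6.0
        assert df.loc[24, "unique"] == 1 and df.loc[24, "ratio"] == 1.0

    def test_empty(self):
        assert length_stats([]).empty

    def test_conservation_on_simulated_library(self, annotated_tags, default_sim):
        df = length_stats(annotated_tags)
        assert df["redundant"].sum() == sum(t.total for t in annotated_tags)
        assert (df["ratio"][df["unique"] > 0] >= 1.0).all()


def _duplex_tags(rng, length=24, overhang_ok=True):
    genome = {"s1": random_rna(rng, 3000)}
    s1 = 1000
    e1 = s1 + length - 1
    guide = genome["s1"][s1 - 1 : e1]
    if overhang_ok:
        s2, e2 = s1 - 2, e1 - 2
    else:
        s2, e2 = s1, e1  # blunt
    passenger = revcomp(genome["s1"][s2 - 1 : e2])
    a = UniqueTag(guide, hits=[Locus("s1", s1, e1, "+")])
    b = UniqueTag(passenger, hits=[Locus("s1", s2, e2, "-")])
    return a, b


class TestSirnaDuplexScan:
    def test_detects_constructed_duplex(self, rng):
        a, b = _duplex_tags(rng)
        pairs = sirna_duplex_scan([a, b])
        assert len(pairs) == 1
        assert a.annotation == b.annotation == "sirna_candidate"

    def test_blunt_pair_rejected(self, rng):
        a, b = _duplex_tags(rng, overhang_ok=False)
        assert sirna_duplex_scan([a, b]) == []

    def test_21mer_pair_outside_length_gate(self, rng):
        a, b = _duplex_tags(rng, length=21)
        assert sirna_duplex_scan([a, b]) == []

    def test_finds_planted_pairs_in_simulation(self, annotated_tags, default_sim):
        pairs = sirna_duplex_scan(annotated_tags)
        assert len(pairs) >= len(default_sim["truth"].sirna_pairs)


def test_tags_to_fasta_header_convention():
    tags = [UniqueTag("ACGU" * 5, count_control=3, count_drought=7)]
    assert tags_to_fasta(tags) == ">tag1_x3_y7\nACGUACGUACGUACGUACGU\n"


def test_annotation_is_total_on_mapped_tags(annotated_tags):
    labels = {"structural", "known_mirna", "sirna_candidate", "candidate", "unmapped"}
    for t in annotated_tags:
        assert t.annotation in labels
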