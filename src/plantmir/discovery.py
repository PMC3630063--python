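"""Novel miRNA discovery: precursor excision, folding, and duplex criteria.

Candidate tags are extended into windows of genomic context, folded with the
stacking model (or a plug-in backend), and kept when the tag sits on one arm
of a single major stem.  The miRNA* (star) partner is located from the
structure under the canonical duplex geometry (star pairs mature positions
1..L-2; both strands carry 2-nt 3' overhangs).  A candidate is accepted as a
novel miRNA only when the standard plant criteria hold: sequenced star
evidence, a mature::star duplex with at most 4 mismatches and no bulge
longer than 2 nt, correct overhang geometry, and a sufficiently stable
precursor (MFE at or below -30 kcal/mol by default).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fold import fold_rna, partner_map
from .preprocess import Locus, UniqueTag
from .seqtools import revcomp, to_rna


@dataclass
class HairpinCandidate:
    """An excised precursor with its fold and mature/star placement."""

    precursor: str
    locus: Locus
    structure: str
    mfe: float
    mature_offset: int  # 0-based within the precursor
    mature_length: int
    star_offset: int = -1
    star_length: int = 0
    arm: str = "?"

    @property
    def lp(self) -> int:
        return len(self.precursor)

    @property
    def mature(self) -> str:
        return self.precursor[self.mature_offset : self.mature_offset + self.mature_length]

    @property
    def star(self) -> str:
        return self.precursor[self.star_offset : self.star_offset + self.star_length]


@dataclass
class NovelMiRNA:
    name: str
    mature: str
    star: str
    count_control: int
    count_drought: int
    star_count_control: int
    star_count_drought: int
    hairpin: HairpinCandidate
    family: str = ""


@dataclass
class Rejection:
    locus: Locus
    mature: str
    reason: str


def _tag_arm_check(structure: str, lo: int, hi: int, min_paired: int = 16, max_gap: int = 3):
    """Does the tag at [lo, hi) sit on one arm of a single major stem?

    Requires >= ``min_paired`` tag nucleotides paired, every partner on the
    same side of the tag, and the pairing to form one continuous helix:
    consecutive paired tag positions (and their partners) may be interrupted
    by at most ``max_gap`` nt (small bulges/internal loops), not by the long
    unpaired stretches of multiloop folds.  Returns (ok, arm) with arm "5'"
    when partners lie 3' of the tag.
    """
    part = partner_map(structure)
    paired = [(i, int(part[i])) for i in range(lo, hi) if part[i] >= 0]
    if len(paired) < min_paired:
        return False, "?"
    partners = [p for _i, p in paired]
    if all(p >= hi for p in partners):
        arm = "5'"
    elif all(p < lo for p in partners):
        arm = "3'"
    else:
        return False, "?"
    for (i1, p1), (i2, p2) in zip(paired, paired[1:]):
        if i2 - i1 > max_gap or abs(p1 - p2) > max_gap:
            return False, "?"
    # a single stem has little internal defect: the helix footprint on each
    # strand may exceed the number of pairs by at most a few bulged bases
    k = len(paired)
    tag_span = paired[-1][0] - paired[0][0] + 1
    partner_span = abs(paired[-1][1] - paired[0][1]) + 1
    if tag_span - k > 4 or partner_span - k > 4:
        return False, "?"
    return True, arm


def excise_and_fold(
    hit: Locus,
    genome: dict[str, str],
    tag_length: int,
    flank_max: int = 280,
    backend=None,
    min_paired: int = 16,
) -> list[HairpinCandidate]:
    """Try hairpin windows around a mapped candidate tag.

    Windows place the tag at the 5' arm (extending 3') and at the 3' arm
    (extending 5'), with window lengths stepped 60..``flank_max`` by 20.
    Each window is folded; it is kept when the tag lies on one arm with at
    least ``min_paired`` of its nucleotides paired to the other side.  The
    best window per arm (lowest MFE, ties toward the shorter window) is
    returned.  Windows clipped below 60 nt by scaffold bounds are skipped.
    """
    seq = to_rna(genome[hit.scaffold])
    best: dict[str, HairpinCandidate] = {}
    for window_len in range(60, flank_max + 1, 20):
        for mode in ("extend3", "extend5"):
            if mode == "extend3":
                g_start, g_end = hit.start, hit.start + window_len - 1
            else:
                g_start, g_end = hit.end - window_len + 1, hit.end
            g_start_c = max(1, g_start)
            g_end_c = min(len(seq), g_end)
            if g_end_c - g_start_c + 1 < 60:
                continue
            window = seq[g_start_c - 1 : g_end_c]
            if hit.strand == "-":
                window = revcomp(window)
                lo = g_end_c - hit.end
            else:
                lo = hit.start - g_start_c
            hi = lo + tag_length
            structure, mfe = fold_rna(window, backend=backend)
            ok, arm = _tag_arm_check(structure, lo, hi, min_paired=min_paired)
            if not ok:
                continue
            cand = HairpinCandidate(
                precursor=window,
                locus=Locus(hit.scaffold, g_start_c, g_end_c, hit.strand),
                structure=structure,
                mfe=mfe,
                mature_offset=lo,
                mature_length=tag_length,
                arm=arm,
            )
            old = best.get(arm)
            if old is None or (cand.mfe, cand.lp) < (old.mfe, old.lp):
                best[arm] = cand
    return [best[a] for a in sorted(best)]


def find_star(hairpin: HairpinCandidate) -> tuple[str, int]:
    """Locate the miRNA* of the hairpin's mature from its structure.

    The star is the segment pairing mature positions 1..L-2, extended so each
    strand's 3' end overhangs the other's paired region by 2 nt.  Returns
    (star sequence, 0-based star offset) and records both on the hairpin.
    Raises ValueError when fewer than 12 mature nucleotides are paired or the
    mature sits on the loop.
    """
    part = partner_map(hairpin.structure)
    a = hairpin.mature_offset  # 0-based
    b = a + hairpin.mature_length - 1
    body = range(a, b - 1)  # mature positions 1..L-2
    paired = [(i, int(part[i])) for i in body if part[i] >= 0]
    if len(paired) < 12:
        raise ValueError("mature is mostly unpaired; no star definable")
    partners = [p for _i, p in paired]
    if not (all(p > b for p in partners) or all(p < a for p in partners)):
        raise ValueError("mature does not sit on a single arm (loop or split stem)")
    # extrapolate to the ends: partner index decreases as mature index grows
    i_hi, p_hi = max(paired)  # mature position closest to L-2
    i_lo, p_lo = min(paired)  # mature position closest to 1
    star_lo = p_hi - ((b - 2) - i_hi)
    star_hi = p_lo + (i_lo - a) + 2
    n = len(hairpin.precursor)
    if star_lo < 0 or star_hi >= n:
        raise ValueError("star extends past the precursor boundary")
    if not (star_hi < a or star_lo > b):
        raise ValueError("star region overlaps the mature")
    hairpin.star_offset = star_lo
    hairpin.star_length = star_hi - star_lo + 1
    return hairpin.star, star_lo


def _duplex_defects(hairpin: HairpinCandidate) -> tuple[int, int]:
    """(mismatched positions, longest bulge) of the mature::star duplex.

    A mature position (1..L-2) unpaired or paired outside the star region
    counts as a mismatch; bulges are runs of consecutive such positions or
    jumps in the partner index.
    """
    part = partner_map(hairpin.structure)
    a = hairpin.mature_offset
    b = a + hairpin.mature_length - 1
    s_lo = hairpin.star_offset
    s_hi = s_lo + hairpin.star_length - 1
    mismatches = 0
    longest_bulge = 0
    run = 0
    prev_partner = None
    for i in range(a, b - 1):
        p = int(part[i])
        good = p >= 0 and s_lo <= p <= s_hi
        if not good:
            mismatches += 1
            run += 1
            longest_bulge = max(longest_bulge, run)
        else:
            if prev_partner is not None:
                gap = abs(prev_partner - p) - (run + 1)
                longest_bulge = max(longest_bulge, gap)
            prev_partner = p
            run = 0
    return mismatches, longest_bulge


def evaluate_meyers(
    candidate: HairpinCandidate,
    tag_counts: dict[str, tuple[int, int]],
    mfe_threshold: float = -30.0,
) -> NovelMiRNA | Rejection:
    """Accept or reject a folded candidate under the plant miRNA criteria.

    ``tag_counts`` maps tag sequence -> (control, drought) read counts and
    must contain the mature.  Acceptance requires (a) the star sequence
    observed with total count >= 1, (b) a mature::star duplex with <= 4
    mismatches and no bulge > 2 nt, (c) the 2-nt 3' overhang geometry
    (established by find_star), and (d) precursor MFE <= ``mfe_threshold``.
    Rejections name the first failed criterion.
    """
    mature = candidate.mature
    try:
        if candidate.star_offset < 0:
            find_star(candidate)
    except ValueError as exc:
        return Rejection(candidate.locus, mature, f"no star geometry: {exc}")
    star = candidate.star
    star_counts = tag_counts.get(star, (0, 0))
    if star_counts[0] + star_counts[1] < 1:
        return Rejection(candidate.locus, mature, "no star evidence")
    mismatches, bulge = _duplex_defects(candidate)
    if mismatches > 4:
        return Rejection(candidate.locus, mature, "duplex mismatches")
    if bulge > 2:
        return Rejection(candidate.locus, mature, "duplex bulge")
    if candidate.mfe > mfe_threshold:
        return Rejection(candidate.locus, mature, "precursor not stable enough")
    counts = tag_counts.get(mature, (0, 0))
    return NovelMiRNA(
        name="",
        mature=mature,
        star=star,
        count_control=counts[0],
        count_drought=counts[1],
        star_count_control=star_counts[0],
        star_count_drought=star_counts[1],
        hairpin=candidate,
    )


def discover_novel(
    tags: list[UniqueTag],
    genome: dict[str, str],
    mfe_threshold: float = -30.0,
    flank_max: int = 280,
    backend=None,
) -> tuple[list[NovelMiRNA], list[Rejection]]:
    """Run excision + folding + criteria over every candidate tag.

    One accepted miRNA is reported per (mature sequence, locus); identical
    mature sequences are assigned to one family with lettered variants
    (fam1a, fam1b, ...) in locus order.
    """
    tag_counts = {t.sequence: (t.count_control, t.count_drought) for t in tags}
    accepted: list[NovelMiRNA] = []
    rejections: list[Rejection] = []
    seen_loci: set[str] = set()
    for tag in tags:
        if tag.annotation != "candidate":
            continue
        if not 19 <= len(tag.sequence) <= 24:
            continue
        for hit in tag.hits:
            cands = excise_and_fold(
                hit, genome, len(tag.sequence), flank_max=flank_max, backend=backend
            )
            if not cands:
                rejections.append(Rejection(hit, tag.sequence, "no hairpin window"))
                continue
            got = None
            for cand in cands:
                res = evaluate_meyers(cand, tag_counts, mfe_threshold=mfe_threshold)
                if isinstance(res, NovelMiRNA):
                    got = res
                    break
            if got is None:
                res = evaluate_meyers(cands[0], tag_counts, mfe_threshold=mfe_threshold)
                assert isinstance(res, Rejection)
                rejections.append(res)
                continue
            key = str(got.hairpin.locus)
            if key not in seen_loci:
                seen_loci.add(key)
                accepted.append(got)
    accepted = _merge_arms(accepted)
    _assign_families(accepted)
    return accepted, rejections


def _merge_arms(accepted: list[NovelMiRNA]) -> list[NovelMiRNA]:
    """Collapse acceptances whose precursor loci overlap into one miRNA.

    A sequenced star passes the same criteria as its mature (the duplex is
    symmetric), so one hairpin can surface once per arm and once per window;
    the more abundant tag is kept as the mature, per the usual convention.
    """
    accepted = sorted(
        accepted,
        key=lambda m: (m.hairpin.locus.scaffold, m.hairpin.locus.strand, m.hairpin.locus.start),
    )
    clusters: list[list[NovelMiRNA]] = []
    for m in accepted:
        loc = m.hairpin.locus
        if clusters:
            last = clusters[-1][-1].hairpin.locus
            if (
                loc.scaffold == last.scaffold
                and loc.strand == last.strand
                and loc.start <= max(c.hairpin.locus.end for c in clusters[-1])
            ):
                clusters[-1].append(m)
                continue
        clusters.append([m])
    return [
        max(c, key=lambda m: (m.count_control + m.count_drought, -m.hairpin.mfe))
        for c in clusters
    ]


def _assign_families(novel: list[NovelMiRNA]) -> None:
    """Family = identical mature sequence; lettered variants per locus."""
    order: dict[str, int] = {}
    members: dict[str, int] = Counter()
    for m in novel:
        if m.mature not in order:
            order[m.mature] = len(order) + 1
    for m in novel:
        fam = order[m.mature]
        members[m.mature] += 1
        m.family = f"fam{fam}"
        m.name = f"miRn{fam}{chr(ord('a') + members[m.mature] - 1)}"
    # drop the letter where a family has a single member
    counts = Counter(m.family for m in novel)
    for m in novel:
        if counts[m.family] == 1:
            m.name = m.name[:-1]


def summarize_novel(records: pd.DataFrame | list[NovelMiRNA]) -> dict:
    """Length histogram, first-nucleotide bias, family count, LP/MFE range.

    Accepts either discovered NovelMiRNA objects or a catalog DataFrame with
    columns name, mature_sequence, lp_nt, mef_kcal_mol.
    """
    if isinstance(records, list):
        df = pd.DataFrame(
            {
                "name": [m.name for m in records],
                "mature_sequence": [m.mature for m in records],
                "lp_nt": [m.hairpin.lp for m in records],
                "mef_kcal_mol": [m.hairpin.mfe for m in records],
            }
        )
    else:
        df = records
    seqs = df["mature_sequence"].map(to_rna)
    lengths = seqs.str.len()
    first = seqs.str[0]
    families = seqs.nunique()
    n = len(df)
    return {
        "n": n,
        "length_histogram": dict(sorted(Counter(lengths).items())),
        "first_nucleotide_counts": dict(sorted(Counter(first).items())),
        "first_nucleotide_fraction": {
            k: v / n for k, v in sorted(Counter(first).items())
        },
        "n_families": int(families),
        "lp_min": int(df["lp_nt"].min()),
        "lp_max": int(df["lp_nt"].max()),
        "mef_min": float(df["mef_kcal_mol"].min()),
        "mef_max": float(df["mef_kcal_mol"].max()),
    }


def novel_to_table(novel: list[NovelMiRNA]) -> pd.DataFrame:
    """Catalog-style table: name, sequence, counts m(s), location, arm, LP, MFE."""
    rows = []
    for m in novel:
        rows.append(
            {
                "name": m.name,
                "mature_sequence": m.mature,
                "counts": f"{m.count_control + m.count_drought}"
                f"({m.star_count_control + m.star_count_drought})",
                "location": str(m.hairpin.locus),
                "arm": m.hairpin.arm,
                "lp_nt": m.hairpin.lp,
                "mef_kcal_mol": m.hairpin.mfe,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name",
            "mature_sequence",
            "counts",
            "location",
            "arm",
            "lp_nt",
            "mef_kcal_mol",
        ],
    )
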