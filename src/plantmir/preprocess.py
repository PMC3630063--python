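"""Small-RNA read cleaning, collapsing, exact mapping and annotation.

Mirrors the front half of a plant sRNA-seq pipeline: 3' adapter removal,
length and quality filtering, collapsing identical reads into unique tags
with per-library counts, perfect-match mapping to the genome on both strands,
annotation by precedence (structural RNA > known miRNA > candidate), the
redundant/unique length-distribution statistics, and a scan for siRNA-like
duplexes (22-24 nt tags on opposite strands with 2-nt 3' overhangs).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from io import StringIO

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .seqtools import revcomp, to_rna

STRUCTURAL_TYPES = {"rRNA", "tRNA", "snRNA", "snoRNA"}


@dataclass(frozen=True)
class Locus:
    """1-based inclusive genomic interval with strand."""

    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad locus {self.scaffold}:{self.start}:{self.end}")

    def __str__(self) -> str:
        return f"{self.scaffold}:{self.start}:{self.end}:{self.strand}"


@dataclass
class UniqueTag:
    """A distinct small-RNA sequence with per-library counts."""

    sequence: str
    count_control: int = 0
    count_drought: int = 0
    annotation: str = "candidate"
    hits: list[Locus] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.count_control + self.count_drought


def clean_and_collapse(
    fastq_text: str,
    adapter: str,
    min_len: int = 18,
    max_len: int = 30,
    min_qual: float = 20.0,
    library: str = "control",
) -> list[UniqueTag]:
    """Trim adapters, filter, and collapse one library's reads into tags.

    The 3' adapter is removed at the leftmost exact occurrence of its first
    8 nt; reads without that occurrence, outside [min_len, max_len], or with
    mean Phred quality below ``min_qual`` over the insert are dropped.
    Identical inserts are merged with summed counts (T mapped to U).
    ``library`` ("control" or "drought") selects which count field is filled.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if library not in ("control", "drought"):
        raise ValueError("library must be 'control' or 'drought'")
    probe = to_rna(adapter)[:8]
    probe_dna = probe.replace("U", "T")
    counts: Counter[str] = Counter()
    record_idx = 0
    try:
        for _title, seq, qual in FastqGeneralIterator(StringIO(fastq_text)):
            record_idx += 1
            seq = seq.upper()
            cut = seq.find(probe_dna)
            if cut < 0:
                cut = to_rna(seq).find(probe)
            if cut < 0:
                continue  # no adapter: discard as untrimmable
            insert = seq[:cut]
            if not min_len <= len(insert) <= max_len:
                continue
            quals = [ord(c) - 33 for c in qual[:cut]]
            if quals and sum(quals) / len(quals) < min_qual:
                continue
            counts[to_rna(insert)] += 1
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record near record {record_idx + 1}: {exc}") from exc
    tags = []
    for seq in sorted(counts):
        tag = UniqueTag(sequence=seq)
        setattr(tag, f"count_{library}", counts[seq])
        tags.append(tag)
    return tags


def merge_tag_sets(control: list[UniqueTag], drought: list[UniqueTag]) -> list[UniqueTag]:
    """Merge per-library tag lists into one list with both count fields."""
    merged: dict[str, UniqueTag] = {}
    for tags, fieldname in ((control, "count_control"), (drought, "count_drought")):
        for t in tags:
            m = merged.setdefault(t.sequence, UniqueTag(sequence=t.sequence))
            setattr(m, fieldname, getattr(m, fieldname) + getattr(t, fieldname))
    return [merged[s] for s in sorted(merged)]


class GenomeIndex:
    """Exact-match k-mer index over a genome dict {scaffold: RNA string}."""

    K = 18

    def __init__(self, scaffolds: dict[str, str]):
        self.scaffolds = {k: to_rna(v) for k, v in scaffolds.items()}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.scaffolds.items():
            for i in range(len(seq) - self.K + 1):
                self._index[seq[i : i + self.K]].append((name, i))

    def find(self, query: str) -> list[tuple[str, int]]:
        """All 0-based forward-strand occurrences of ``query``."""
        q = to_rna(query)
        if len(q) < self.K:
            out = []
            for name, seq in self.scaffolds.items():
                i = seq.find(q)
                while i >= 0:
                    out.append((name, i))
                    i = seq.find(q, i + 1)
            return out
        hits = []
        for name, i in self._index.get(q[: self.K], []):
            if self.scaffolds[name][i : i + len(q)] == q:
                hits.append((name, i))
        return hits


def map_perfect(
    tags: list[UniqueTag], genome: dict[str, str] | GenomeIndex, max_hits: int = 20
) -> list[UniqueTag]:
    """Fill each tag's hits with every perfect-match locus on both strands.

    Tags with more than ``max_hits`` loci are marked ``unmapped`` (multi-hit
    cap) and carry no hits; tags absent from the genome are ``unmapped``.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    for tag in tags:
        hits = []
        for name, i in index.find(tag.sequence):
            hits.append(Locus(name, i + 1, i + len(tag.sequence), "+"))
        for name, i in index.find(revcomp(tag.sequence)):
            hits.append(Locus(name, i + 1, i + len(tag.sequence), "-"))
        hits.sort(key=lambda h: (h.scaffold, h.start, h.strand))
        if not hits or len(hits) > max_hits:
            tag.hits = []
            tag.annotation = "unmapped"
        else:
            tag.hits = hits
            tag.annotation = "candidate"
    return tags


def parse_gff3_structural(gff_text: str) -> list[tuple[Locus, str]]:
    """Structural-RNA (rRNA/tRNA/snRNA/snoRNA) loci from GFF3 text."""
    loci = []
    for ln, line in enumerate(gff_text.splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 8:
            raise ValueError(f"GFF3 line {ln}: expected >= 8 columns")
        seqid, _src, ftype, start, end, _score, strand = parts[:7]
        if ftype not in STRUCTURAL_TYPES:
            continue
        start, end = int(start), int(end)
        if end < start:
            raise ValueError(f"GFF3 line {ln}: end < start ({start}..{end})")
        loci.append((Locus(seqid, start, end, strand if strand in "+-" else "+"), ftype))
    return loci


def _matches_catalog(seq: str, catalog: set[str]) -> bool:
    """Exact match, or a match shifted <= 2 nt at either end of a catalog mature."""
    if seq in catalog:
        return True
    return any(_shifted_match(seq, mature) for mature in catalog)


def _shifted_match(seq: str, mature: str) -> bool:
    """True when one sequence equals the other shifted <= 2 nt at each end."""
    if abs(len(seq) - len(mature)) > 4:
        return False
    for offset in (-2, -1, 0, 1, 2):
        # offset = start of seq relative to start of mature
        lo = max(0, offset)
        hi = min(len(mature), offset + len(seq))
        if hi - lo <= 0:
            continue
        if mature[lo:hi] != seq[lo - offset : hi - offset]:
            continue
        # overlap must cover all but <= 2 nt at each end of both sequences
        if lo - offset <= 2 and len(seq) - (hi - offset) <= 2 and lo <= 2 and len(mature) - hi <= 2:
            return True
    return False


def annotate_tags(
    tags: list[UniqueTag],
    gff_text: str,
    known_mature: dict[str, str] | None = None,
    structural_sequences: dict[str, str] | None = None,
) -> list[UniqueTag]:
    """Assign each mapped tag exactly one label by precedence.

    structural (any hit overlaps an annotated structural-RNA locus; locus
    overlap is the default criterion — ``structural_sequences`` additionally
    flags tags contained in a reference structural-RNA sequence, Rfam-style)
    > known_mirna (exact or <=2-nt end-shifted match to a catalog mature)
    > candidate.  Unmapped tags keep their ``unmapped`` label.
    """
    structural = parse_gff3_structural(gff_text)
    by_scaffold: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for loc, _t in structural:
        by_scaffold[loc.scaffold].append((loc.start, loc.end))
    struct_seqs = [to_rna(s) for s in (structural_sequences or {}).values()]
    catalog = set(to_rna(s) for s in (known_mature or {}).values())
    for tag in tags:
        if tag.annotation == "unmapped":
            continue
        overlaps = any(
            s <= hit.end and hit.start <= e
            for hit in tag.hits
            for s, e in by_scaffold.get(hit.scaffold, [])
        )
        if not overlaps and struct_seqs:
            overlaps = any(tag.sequence in s for s in struct_seqs)
        if overlaps:
            tag.annotation = "structural"
        elif catalog and _matches_catalog(tag.sequence, catalog):
            tag.annotation = "known_mirna"
        else:
            tag.annotation = "candidate"
    return tags


def length_stats(tags: list[UniqueTag]) -> pd.DataFrame:
    """Per-length unique/redundant counts and redundancy ratio.

    unique = number of distinct tags of that length; redundant = summed read
    counts; ratio = redundant/unique (0 where unique = 0).
    """
    uniq: Counter[int] = Counter()
    red: Counter[int] = Counter()
    for t in tags:
        uniq[len(t.sequence)] += 1
        red[len(t.sequence)] += t.total
    lengths = sorted(uniq) or []
    df = pd.DataFrame(
        {
            "length": lengths,
            "unique": [uniq[l] for l in lengths],
            "redundant": [red[l] for l in lengths],
        }
    )
    df["ratio"] = [r / u if u else 0.0 for u, r in zip(df["unique"], df["redundant"])]
    return df


def sirna_duplex_scan(tags: list[UniqueTag]) -> list[tuple[UniqueTag, UniqueTag]]:
    """Pairs of 22-24 nt tags forming duplexes with 2-nt 3' overhangs.

    Two mapped tags qualify when they sit at the same locus on opposite
    strands and each 3' end extends exactly 2 nt beyond the complementary
    region of the other: for a + tag at [s1, e1] and a - tag at [s2, e2]
    that means s2 = s1 - 2 and e2 = e1 - 2.  Both members are annotated
    ``sirna_candidate`` unless already structural or known.
    """
    plus: dict[tuple[str, int, int], UniqueTag] = {}
    minus: dict[tuple[str, int, int], UniqueTag] = {}
    for t in tags:
        if not 22 <= len(t.sequence) <= 24:
            continue
        for h in t.hits:
            key = (h.scaffold, h.start, h.end)
            (plus if h.strand == "+" else minus)[key] = t
    pairs = []
    for (sc, s1, e1), a in sorted(plus.items()):
        b = minus.get((sc, s1 - 2, e1 - 2))
        if b is None or not 22 <= len(b.sequence) <= 24:
            continue
        pairs.append((a, b))
        for t in (a, b):
            if t.annotation not in ("structural", "known_mirna"):
                t.annotation = "sirna_candidate"
    return pairs


def tags_to_fasta(tags: list[UniqueTag]) -> str:
    """Serialize collapsed tags as FASTA, headers tag{i}_x{control}_y{drought}."""
    out = []
    for i, t in enumerate(tags, 1):
        out.append(f">tag{i}_x{t.count_control}_y{t.count_drought}")
        out.append(t.sequence)
    return "\n".join(out) + ("\n" if out else "")
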