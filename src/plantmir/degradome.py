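"""Degradome (PARE) mapping, cleavage detection, and category classification.

Degradome reads are 5' ends of uncapped mRNA fragments; miRNA-guided
cleavage leaves a 5'-phosphate at the transcript nucleotide paired to miRNA
position 10, so a peak of read 5' ends at exactly that position validates a
predicted target site.  Events are classified by the abundance of the
cleavage-site signal relative to the rest of the transcript:

  I   the site's count is the transcript maximum;
  II  not the maximum, but at least the transcript median;
  III below the median.

By default the maximum and median are taken over positions with at least one
read (a zero-inflated median over all positions would make nearly every
event category II); ``median_over_all_positions`` switches to the full
transcript.  Significance comes from composition-preserving miRNA shuffles:
p = (1 + #successful shuffles) / (1 + n_shuffles).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .seqtools import to_rna
from .targets import GAP, DuplexAlignment, TranscriptomeIndex, scan_targets


@dataclass
class DegradomeProfile:
    transcript_id: str
    length: int
    counts: dict[int, int] = field(default_factory=dict)  # 1-based position -> count

    def add(self, position: int, n: int = 1) -> None:
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside transcript of length {self.length}")
        self.counts[position] = self.counts.get(position, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CleavageEvent:
    mirna_name: str
    transcript_id: str
    cleavage_site: int
    reads_at_site: int
    penalty: float
    category: str = ""
    shuffle_p: float = float("nan")


def map_degradome(
    fastq_text: str, transcripts: dict[str, str], anchor: int = 20
) -> dict[str, DegradomeProfile]:
    """Count degradome-read 5' ends per transcript position.

    A read contributes one count at position p of every transcript whose
    sense strand contains the read's first ``anchor`` nt starting at p
    (multi-mapped reads count once per matching transcript).  Reads shorter
    than ``anchor`` are ignored.
    """
    tx = {tid: to_rna(seq) for tid, seq in transcripts.items()}
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for tid, seq in tx.items():
        for i in range(len(seq) - anchor + 1):
            index[seq[i : i + anchor]].append((tid, i))
    profiles = {tid: DegradomeProfile(tid, len(seq)) for tid, seq in tx.items()}
    for _title, seq, _qual in FastqGeneralIterator(StringIO(fastq_text)):
        key = to_rna(seq[:anchor])
        if len(key) < anchor:
            continue
        for tid, i in index.get(key, []):
            profiles[tid].add(i + 1)
    return profiles


def cleavage_position(aln: DuplexAlignment) -> int | None:
    """Transcript position paired to miRNA position 10 (5' end = 1).

    None when position 10 is a gap or falls outside the site.  For an
    ungapped site the result is site_end - 9; a bulge 5' of position 10
    shifts it accordingly.
    """
    # walk states from the miRNA 5' end; the transcript index starts at
    # site_end and decreases by one for every state that consumes a
    # transcript base (everything except a bulged miRNA nucleotide)
    tpos = aln.site_end
    consumed_before = 0
    mirna_bulge = len(aln.window) < len(aln.mirna)
    for pos, st in aln.states:
        consumes = not (st == GAP and mirna_bulge)
        if pos == 10 and st != GAP:
            return aln.site_end - consumed_before
        if pos == 10 and st == GAP:
            return None
        if consumes:
            consumed_before += 1
    return None


def detect_cleavage(
    aln: DuplexAlignment, profile: DegradomeProfile
) -> CleavageEvent | None:
    """Emit a cleavage event when degradome 5' ends support the site.

    The event requires at least one read 5' end exactly at the transcript
    position paired to miRNA position 10.
    """
    pos = cleavage_position(aln)
    if pos is None:
        return None
    reads = profile.counts.get(pos, 0)
    if reads < 1:
        return None
    return CleavageEvent(
        mirna_name=aln.mirna_name,
        transcript_id=aln.transcript_id,
        cleavage_site=pos,
        reads_at_site=reads,
        penalty=aln.penalty,
    )


def categorize(
    event: CleavageEvent,
    profile: DegradomeProfile,
    median_over_all_positions: bool = False,
) -> str:
    """Assign category I/II/III from the transcript's degradome profile."""
    if event.reads_at_site < 1:
        raise ValueError("cleavage event must have at least one supporting read")
    if not profile.counts:
        raise ValueError("empty degradome profile cannot categorize an event")
    if median_over_all_positions:
        values = np.zeros(profile.length)
        for pos, c in profile.counts.items():
            values[pos - 1] = c
    else:
        values = np.array(sorted(profile.counts.values()), dtype=float)
    maximum = values.max()
    median = float(np.median(values))
    c = event.reads_at_site
    if c >= maximum:
        event.category = "I"
    elif c >= median:
        event.category = "II"
    else:
        event.category = "III"
    return event.category


def _shuffle_event_stats(
    mirna: str,
    transcripts: dict[str, str],
    profiles: dict[str, DegradomeProfile],
    n_shuffles: int,
    seed: int,
    score_cutoff: float,
) -> list[list[tuple[float, int]]]:
    """Per shuffle, the (penalty, reads_at_site) pairs of supported events."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(to_rna(mirna)))
    if not isinstance(transcripts, TranscriptomeIndex):
        transcripts = TranscriptomeIndex(transcripts)
    stats = []
    for _s in range(n_shuffles):
        shuffled = "".join(rng.permutation(letters))
        pairs = []
        for aln in scan_targets(
            shuffled, transcripts, score_cutoff=score_cutoff, require_rules=False
        ):
            ev = detect_cleavage(aln, profiles[aln.transcript_id])
            if ev is not None:
                pairs.append((aln.penalty, ev.reads_at_site))
        stats.append(pairs)
    return stats


def _pvalue_from_stats(stats, observed: CleavageEvent) -> float:
    successes = sum(
        1
        for pairs in stats
        if any(p <= observed.penalty and r >= observed.reads_at_site for p, r in pairs)
    )
    return (1 + successes) / (1 + len(stats))


def shuffle_pvalue(
    mirna: str,
    transcripts: dict[str, str],
    profiles: dict[str, DegradomeProfile],
    observed: CleavageEvent,
    n_shuffles: int = 100,
    seed: int = 0,
    score_cutoff: float = 4.0,
) -> float:
    """Empirical p-value from composition-preserving miRNA shuffles.

    Each shuffle permutes the miRNA sequence and is scanned against the
    transcriptome in degradome mode; a shuffle succeeds when it yields any
    supported event with penalty <= the observed penalty and reads at site
    >= the observed reads.  p = (1 + successes) / (1 + n_shuffles).
    """
    stats = _shuffle_event_stats(
        mirna, transcripts, profiles, n_shuffles, seed, score_cutoff
    )
    return _pvalue_from_stats(stats, observed)


def tplot_table(profile: DegradomeProfile, event: CleavageEvent | None = None) -> pd.DataFrame:
    """Per-position table for target plots: position, count, site flag."""
    rows = [
        {
            "position": pos,
            "count": c,
            "site": bool(event is not None and pos == event.cleavage_site),
        }
        for pos, c in sorted(profile.counts.items())
    ]
    return pd.DataFrame(rows, columns=["position", "count", "site"])


def confirm_targets(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    profiles: dict[str, DegradomeProfile],
    score_cutoff: float = 4.0,
    n_shuffles: int = 100,
    seed: int = 0,
    median_over_all_positions: bool = False,
) -> list[CleavageEvent]:
    """End-to-end degradome confirmation for a set of miRNAs.

    Scans each miRNA (degradome-mode cutoff, rules relaxed to the penalty
    criterion), keeps sites with degradome support at the position paired
    to miRNA nucleotide 10, classifies them, and attaches shuffle p-values.
    """
    events: list[CleavageEvent] = []
    if not isinstance(transcripts, TranscriptomeIndex):
        transcripts = TranscriptomeIndex(transcripts)
    for k, (name, seq) in enumerate(sorted(mirnas.items())):
        found = []
        for aln in scan_targets(
            seq, transcripts, score_cutoff=score_cutoff, mirna_name=name, require_rules=False
        ):
            ev = detect_cleavage(aln, profiles[aln.transcript_id])
            if ev is None:
                continue
            categorize(ev, profiles[aln.transcript_id], median_over_all_positions)
            found.append(ev)
        if found:
            # one shuffle set per miRNA serves all its events
            stats = _shuffle_event_stats(
                seq, transcripts, profiles, n_shuffles, seed + k, score_cutoff
            )
            for ev in found:
                ev.shuffle_p = _pvalue_from_stats(stats, ev)
        events.extend(found)
    return events


def events_table(events: list[CleavageEvent]) -> pd.DataFrame:
    """Events TSV layout: miRNA, transcript, category, site, reads, score, p."""
    return pd.DataFrame(
        [
            {
                "mirna": e.mirna_name,
                "transcript": e.transcript_id,
                "category": e.category,
                "cleavage_site": e.cleavage_site,
                "reads_at_site": e.reads_at_site,
                "penalty": e.penalty,
                "shuffle_p": e.shuffle_p,
            }
            for e in events
        ],
        columns=[
            "mirna",
            "transcript",
            "category",
            "cleavage_site",
            "reads_at_site",
            "penalty",
            "shuffle_p",
        ],
    )
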