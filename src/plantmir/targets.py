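"""Plant miRNA target prediction with the six-rule engine and penalty score.

A miRNA is aligned anti-parallel against a transcript window (the window is
the sense strand; the miRNA pairs its reverse complement).  Per miRNA
position, counted from the miRNA 5' end, the state is match (Watson-Crick),
GU (wobble), mismatch, or gap; at most one single-nucleotide bulge is
allowed on either strand.

Rules (positions from the miRNA 5' end):
  i    mismatch-equivalents overall <= 4 (mismatch 1, G:U 0.5, gap 1);
  ii   no run of more than 2 adjacent mismatches;
  iii  no 2 adjacent mismatches within positions 2-12;
  iv   positions 10 and 11 are not mismatches (G:U tolerated);
  v    mismatch-equivalents within positions 1-12 <= 2.5;
  vi   duplex MFE >= 74% of the MFE of the miRNA bound to its perfect
       complement (both scored with the internal stacking model).

The penalty (alignment) score weighs mismatch 1.0, G:U 0.5, gap 2.0, with
positions 2-13 doubled; candidate sites require score < cutoff (2.5 for de
novo prediction, 4.0 for degradome-supported confirmation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqtools import PAIR_VALUE, complement, encode, to_rna

MATCH, MISMATCH, GU, GAP = "match", "mismatch", "GU", "gap"

DEFAULT_WEIGHTS = {"mismatch": 1.0, "GU": 0.5, "gap": 2.0}
CORE_START, CORE_END = 2, 13  # doubled-weight positions (miRNA 5' end = 1)


@dataclass
class DuplexAlignment:
    mirna_name: str
    mirna: str
    transcript_id: str
    site_start: int  # 1-based on the transcript sense strand
    site_end: int
    states: list[tuple[int, str]]  # (miRNA position, state); gaps repeat a position
    penalty: float
    window: str = ""
    mfe_duplex: float = 0.0
    mfe_perfect: float = 0.0
    mfe_ratio: float = 0.0


@dataclass
class RuleReport:
    passes: dict[str, bool] = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return all(self.passes.values())

    @property
    def first_failure(self) -> str | None:
        for rule in ("i", "ii", "iii", "iv", "v", "vi"):
            if not self.passes.get(rule, True):
                return rule
        return None


def _pair_state(m: str, w: str) -> str:
    """State of miRNA base ``m`` against the transcript base ``w`` it faces."""
    v = PAIR_VALUE[encode(m)[0], encode(w)[0]]
    if v == 1:
        return GU
    if v > 0:
        return MATCH
    return MISMATCH


def _score_states(states, weights=None) -> float:
    w = weights or DEFAULT_WEIGHTS
    total = 0.0
    for pos, st in states:
        if st == MATCH:
            continue
        contrib = w["gap"] if st == GAP else w[st if st == "GU" else "mismatch"]
        if CORE_START <= pos <= CORE_END:
            contrib *= 2.0
        total += contrib
    return total


def align_duplex(
    mirna: str,
    window: str,
    mirna_name: str = "",
    transcript_id: str = "",
    site_start: int = 1,
    weights=None,
) -> DuplexAlignment:
    """Best anti-parallel duplex of a miRNA against a transcript window.

    The window length must be within 1 nt of the miRNA length; a shorter
    window forces a bulged miRNA nucleotide (gap on the target strand), a
    longer one a bulged window nucleotide (gap on the miRNA strand).  The
    gap is placed to minimize the penalty score; ties go to the largest
    miRNA position index.
    """
    m = to_rna(mirna)
    w = to_rna(window)
    L = len(m)
    diff = len(w) - L
    if abs(diff) > 1:
        raise ValueError("window length must be within 1 nt of the miRNA length")
    wr = w[::-1]  # wr[i] faces miRNA position i+1 in an ungapped duplex

    def ungapped_states():
        return [(i + 1, _pair_state(m[i], wr[i])) for i in range(L)]

    candidates = []
    if diff == 0:
        candidates.append(ungapped_states())
    elif diff == -1:
        # one miRNA position g is bulged (pairs nothing)
        for g in range(1, L + 1):
            states = []
            for i in range(1, L + 1):
                if i == g:
                    states.append((i, GAP))
                elif i < g:
                    states.append((i, _pair_state(m[i - 1], wr[i - 1])))
                else:
                    states.append((i, _pair_state(m[i - 1], wr[i - 2])))
            candidates.append(states)
    else:
        # one window nucleotide is bulged between miRNA positions g and g+1
        for g in range(1, L + 1):
            states = []
            for i in range(1, L + 1):
                if i <= g:
                    states.append((i, _pair_state(m[i - 1], wr[i - 1])))
                else:
                    states.append((i, _pair_state(m[i - 1], wr[i])))
            states.insert(g, (g, GAP))
            candidates.append(states)
    best = None
    for states in candidates:
        score = _score_states(states, weights)
        gap_pos = max((p for p, s in states if s == GAP), default=0)
        key = (score, -gap_pos)
        if best is None or key < best[0]:
            best = (key, states, score)
    _key, states, score = best
    aln = DuplexAlignment(
        mirna_name=mirna_name,
        mirna=m,
        transcript_id=transcript_id,
        site_start=site_start,
        site_end=site_start + len(w) - 1,
        states=states,
        penalty=score,
        window=w,
    )
    duplex_energy(aln)
    return aln


def penalty_score(aln: DuplexAlignment, weights=None) -> float:
    """Weighted sum over duplex positions (mismatch 1, G:U 0.5, gap 2;
    miRNA positions 2-13 doubled)."""
    return _score_states(aln.states, weights)


def duplex_energy(aln: DuplexAlignment) -> tuple[float, float, float]:
    """Stacking energies of the duplex and of the miRNA:perfect-complement.

    Consecutive paired positions (match or G:U) stack and contribute the
    mean of the two pair values (G:C -3, A:U -2, G:U -1 kcal/mol); the
    perfect duplex is the miRNA against its exact complement.  Records and
    returns (mfe_duplex, mfe_perfect, mfe_ratio).
    """
    m = aln.mirna
    comp = complement(m)

    def pairval(i: int) -> int:  # pair value of miRNA position i (1-based)
        return int(PAIR_VALUE[encode(m[i - 1])[0], encode(comp[i - 1])[0]])

    # duplex: walk states; a stack forms between adjacent entries that are
    # both paired and adjacent on both strands (no gap between them)
    score2 = 0  # in units of -0.5 kcal/mol
    prev_paired_pos = None
    prev_entry_paired = False
    for pos, st in aln.states:
        paired = st in (MATCH, GU)
        if paired:
            if prev_entry_paired and prev_paired_pos == pos - 1:
                v1 = pairval(prev_paired_pos) if _state_at(aln, prev_paired_pos) == MATCH else 1
                v2 = pairval(pos) if st == MATCH else 1
                score2 += v1 + v2
            prev_paired_pos = pos
        prev_entry_paired = paired
    mfe_duplex = -score2 / 2.0
    perfect2 = sum(pairval(i) + pairval(i + 1) for i in range(1, len(m)))
    mfe_perfect = -perfect2 / 2.0
    ratio = (mfe_duplex / mfe_perfect) if mfe_perfect < 0 else 0.0
    aln.mfe_duplex = mfe_duplex
    aln.mfe_perfect = mfe_perfect
    aln.mfe_ratio = ratio
    return mfe_duplex, mfe_perfect, ratio


def _state_at(aln: DuplexAlignment, pos: int) -> str:
    for p, st in aln.states:
        if p == pos and st != GAP:
            return st
    return GAP


def check_rules(aln: DuplexAlignment, mfe_ratio_min: float = 0.74) -> RuleReport:
    """Evaluate rules i-vi on a computed alignment."""
    report = RuleReport()
    equivalents = {MISMATCH: 1.0, GU: 0.5, GAP: 1.0, MATCH: 0.0}
    total = sum(equivalents[st] for _p, st in aln.states)
    report.passes["i"] = total <= 4.0

    mismatch_like = [st in (MISMATCH, GAP) for _p, st in aln.states]
    run = longest = 0
    for flag in mismatch_like:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    report.passes["ii"] = longest <= 2

    adjacent_core = False
    entries = aln.states
    for k in range(len(entries) - 1):
        p1, s1 = entries[k]
        p2, s2 = entries[k + 1]
        if s1 in (MISMATCH, GAP) and s2 in (MISMATCH, GAP):
            if 2 <= p1 <= 12 and 2 <= p2 <= 12:
                adjacent_core = True
    report.passes["iii"] = not adjacent_core

    bad_1011 = any(
        st in (MISMATCH, GAP) for p, st in aln.states if p in (10, 11)
    )
    report.passes["iv"] = not bad_1011

    core_total = sum(equivalents[st] for p, st in aln.states if 1 <= p <= 12)
    report.passes["v"] = core_total <= 2.5

    report.passes["vi"] = aln.mfe_perfect < 0 and aln.mfe_ratio >= mfe_ratio_min
    return report


# ---------------------------------------------------------------------------
# transcriptome scanning


# 5th row/column: sentinel code used to pad between concatenated
# transcripts; a huge finite penalty (not inf, which stalls reductions)
# keeps any window touching the pad far above every cutoff.  Penalties and
# their window sums are exact in float32 (halves well below 2**24).
_BIG = float(2**30)
_PEN = np.zeros((5, 5), dtype=np.float32)
for _i in range(4):
    for _j in range(4):
        v = PAIR_VALUE[_i, _j]
        _PEN[_i, _j] = 0.0 if v >= 2 else (0.5 if v == 1 else 1.0)
_PEN[4, :] = _BIG
_PEN[:, 4] = _BIG


def _row(M, i, off, ns, n):
    """Row of the penalty matrix shifted by ``off``, or a BIG fill."""
    if 0 <= off <= n - ns:
        return M[i - 1, off : off + ns]
    return np.full(ns, _BIG, dtype=np.float32)


def _screen_penalties(m_codes, t_codes):
    """Minimal penalty per window start for lengths L-1, L, L+1.

    One core-weighted penalty matrix M[i, pos] (miRNA position i+1 against
    transcript base pos) serves all three lengths.  For the gapped lengths
    the minimum over gap positions g of prefix(g) + suffix(g) follows the
    difference recurrence D[g+1] = D[g] + rowA[g] - rowB[g+1], so only two
    running rows are materialized.  Returns {window_length: penalties}.
    """
    L = len(m_codes)
    n = len(t_codes)
    w = np.array(
        [2.0 if CORE_START <= i <= CORE_END else 1.0 for i in range(1, L + 1)],
        dtype=np.float32,
    )
    M = _PEN[m_codes[:, None], t_codes[None, :]] * w[:, None]
    out = {}
    ns = n - L + 1
    if ns <= 0:
        out[L] = np.empty(0, dtype=np.float32)
    else:
        total = np.zeros(ns, dtype=np.float32)
        for i in range(1, L + 1):
            total += M[i - 1, L - i : L - i + ns]
        out[L] = total
    gap_w = DEFAULT_WEIGHTS["gap"]
    for wlen in (L - 1, L + 1):
        ns = n - wlen + 1
        if ns <= 0:
            out[wlen] = np.empty(0, dtype=np.float32)
            continue
        # register A: miRNA i faces window offset wlen - i; register B is
        # shifted one window position past the gap
        def offA(i):
            return wlen - i

        def offB(i):
            return offA(i) + (1 if wlen == L - 1 else -1)

        # D(g) = sum over head rows 1..h(g) under register A plus suffix
        # rows g+1..L under register B, with h(g) = g-1 for a bulged miRNA
        # base and h(g) = g for a bulged window base
        head_last = (lambda g: g - 1) if wlen == L - 1 else (lambda g: g)
        D = np.zeros(ns, dtype=np.float32)
        for i in range(1, head_last(1) + 1):
            D += _row(M, i, offA(i), ns, n)
        for i in range(2, L + 1):
            D += _row(M, i, offB(i), ns, n)
        best = np.full(ns, np.inf, dtype=np.float32)
        for g in range(1, L + 1):
            cost = gap_w * (2.0 if CORE_START <= g <= CORE_END else 1.0)
            cand = D + np.float32(cost)
            np.minimum(best, cand, out=best)
            if g < L:
                nh = head_last(g + 1)  # row joining the head under A
                if nh >= 1:
                    D += _row(M, nh, offA(nh), ns, n)
                D -= _row(M, g + 1, offB(g + 1), ns, n)
        out[wlen] = best
    return out


class TranscriptomeIndex:
    """Encoded, sentinel-padded concatenation of a transcriptome.

    Build once and pass in place of the transcripts dict when scanning the
    same transcriptome repeatedly (e.g. over miRNA shuffles).
    """

    PAD = 32  # longer than any single bulge-extended window overhang

    def __init__(self, transcripts: dict[str, str]):
        self.tids = sorted(transcripts)
        self.seqs = {tid: to_rna(transcripts[tid]) for tid in self.tids}
        pad = np.full(self.PAD, 4, dtype=np.int8)
        chunks = []
        starts = []
        pos = 0
        for tid in self.tids:
            starts.append(pos)
            codes = encode(self.seqs[tid])
            chunks.append(codes)
            chunks.append(pad)
            pos += len(codes) + self.PAD
        self.t_codes = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int8)
        self._starts = starts
        self._ends = [s + len(self.seqs[t]) for s, t in zip(starts, self.tids)]

    def owner(self, start: int, wlen: int):
        """(transcript id, local 0-based start) or None across a boundary."""
        import bisect

        idx = bisect.bisect_right(self._starts, start) - 1
        if idx < 0:
            return None
        if start + wlen <= self._ends[idx]:
            return self.tids[idx], start - self._starts[idx]
        return None


def scan_targets(
    mirna: str,
    transcripts: dict[str, str] | TranscriptomeIndex,
    score_cutoff: float = 2.5,
    mirna_name: str = "",
    mfe_ratio_min: float = 0.74,
    require_rules: bool = True,
):
    """Scan a transcriptome for target sites of one miRNA.

    Every window of length L-1, L, L+1 on every transcript is evaluated; a
    site is kept when its penalty score is below ``score_cutoff`` and (by
    default) rules i-vi pass.  Overlapping sites on one transcript keep the
    lowest-scoring window.  Output is sorted by (score, transcript id,
    position).
    """
    m = to_rna(mirna)
    m_codes = encode(m)
    L = len(m)
    index = (
        transcripts
        if isinstance(transcripts, TranscriptomeIndex)
        else TranscriptomeIndex(transcripts)
    )
    if not index.tids:
        return []
    tids, seqs, t_codes, owner = index.tids, index.seqs, index.t_codes, index.owner

    per_tx: dict[str, list[DuplexAlignment]] = {tid: [] for tid in tids}
    screened = _screen_penalties(m_codes, t_codes)
    for wlen in (L - 1, L, L + 1):
        pens = screened[wlen]
        for s in np.nonzero(pens < score_cutoff)[0]:
            where = owner(int(s), wlen)
            if where is None:
                continue
            tid, local = where
            window = seqs[tid][local : local + wlen]
            aln = align_duplex(
                m, window, mirna_name=mirna_name, transcript_id=tid, site_start=local + 1
            )
            if aln.penalty >= score_cutoff:
                continue
            if require_rules and not check_rules(aln, mfe_ratio_min).all_pass:
                continue
            per_tx[tid].append(aln)
    hits: list[DuplexAlignment] = []
    for tid in tids:
        # merge overlapping sites, keeping the lowest score
        cands = sorted(per_tx[tid], key=lambda a: (a.penalty, a.site_start, a.site_end))
        kept: list[DuplexAlignment] = []
        for aln in cands:
            if any(
                a.site_start <= aln.site_end and aln.site_start <= a.site_end for a in kept
            ):
                continue
            kept.append(aln)
        hits.extend(kept)
    hits.sort(key=lambda a: (a.penalty, a.transcript_id, a.site_start))
    return hits


def render_duplex(aln: DuplexAlignment) -> str:
    """Three-line ASCII rendering: miRNA 5'->3' over the reversed target."""
    top, mid, bot = [], [], []
    m = aln.mirna
    wr = list(aln.window[::-1])  # faces miRNA positions left to right
    wi = 0
    for pos, st in aln.states:
        if st == GAP:
            # gap on one strand: the other shows its bulged base
            if len(aln.window) < len(m):
                top.append(m[pos - 1])
                bot.append("-")
            else:
                top.append("-")
                bot.append(wr[wi])
                wi += 1
            mid.append(" ")
            continue
        top.append(m[pos - 1])
        bot.append(wr[wi])
        wi += 1
        mid.append("|" if st == MATCH else ("o" if st == GU else " "))
    return (
        f"miRNA  5'-{''.join(top)}-3'\n"
        f"          {''.join(mid)}\n"
        f"target 3'-{''.join(bot)}-5' ({aln.transcript_id}:{aln.site_start}-{aln.site_end})"
    )
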