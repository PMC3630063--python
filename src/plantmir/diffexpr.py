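"""Count-based differential expression between two small-RNA libraries.

The test is the exact Audic-Claverie-type comparison of one tag's counts x
(control, library total N1) and y (drought, library total N2):

    p(y|x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)
    p      = min( sum_{k<=y} p(k|x),  sum_{k>=y} p(k|x) )

p(.|x) is a negative-binomial distribution in y, so the upper tail is the
exact complement of the lower partial sum.  Terms are computed in log space
and accumulated with exact compensated summation (math.fsum).

Normalization is reads-per-million (RPM); ratios are log2 of RPM.  Calls
require |log2 ratio| >= log2(fold) at p <= alpha after discarding tags with
RPM < min_rpm in BOTH libraries (so on/off tags are kept).  RT-qPCR relative
expression uses the standard 2^-ddCt method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass
class ExpressionRecord:
    name: str
    x: int  # control count
    y: int  # drought count
    n1: int  # control library total
    n2: int  # drought library total
    rpm_control: float = 0.0
    rpm_drought: float = 0.0
    log2_ratio: float = float("nan")
    p_value: float = 1.0


@dataclass
class QpcrRecord:
    ct_target_treat: float
    ct_ref_treat: float
    ct_target_ctrl: float
    ct_ref_ctrl: float
    ddct: float
    relative_expression: float


def rpm_normalize(count: float, library_total: int) -> float:
    """Reads per million: count / library_total * 1e6."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return count / library_total * 1_000_000


def log2_ratio(rpm_drought: float, rpm_control: float) -> float:
    """log2(drought RPM / control RPM); NaN when either side is not positive."""
    if rpm_drought <= 0 or rpm_control <= 0:
        return float("nan")
    return math.log2(rpm_drought / rpm_control)


def _log_pmf_terms(x: int, ks: np.ndarray, log_r: float) -> np.ndarray:
    """log p(k|x) for an array of k, with r = N2/N1."""
    ks = ks.astype(float)
    return (
        ks * log_r
        + gammaln(x + ks + 1)
        - gammaln(x + 1)
        - gammaln(ks + 1)
        - (x + ks + 1) * np.logaddexp(0.0, log_r)
    )


def ac_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Exact two-tail p-value for counts x vs y in libraries of totals N1, N2.

    The lower tail sums p(k|x) for k = 0..y; the upper tail is evaluated as
    1 - sum_{k=0}^{y-1} p(k|x), exact because p(.|x) is a proper
    (negative-binomial) distribution.  The result is clamped to (0, 1].
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    log_r = math.log(n2) - math.log(n1)
    terms = np.exp(_log_pmf_terms(x, np.arange(y + 1), log_r))
    lower = math.fsum(terms)
    upper = 1.0 - math.fsum(terms[:-1])
    if upper < 1e-2:
        # the complement is cancellation-limited to absolute float noise;
        # in this regime the mode lies below y, so the tail can be summed
        # forward directly with full relative precision
        upper = _upper_tail_forward(x, y, log_r)
    p = min(lower, upper)
    return min(1.0, max(p, 5e-324))


def _upper_tail_forward(x: int, y: int, log_r: float) -> float:
    """sum_{k>=y} p(k|x), summed forward in chunks until convergence."""
    r = math.exp(log_r)
    sd = math.sqrt(max(1.0, r * (1.0 + r) * (x + 1)))
    chunk = max(1024, int(4 * sd))
    pieces = []
    first = None
    k = y
    while True:
        ks = np.arange(k, k + chunk)
        vals = np.exp(_log_pmf_terms(x, ks, log_r))
        pieces.append(math.fsum(vals))
        if first is None:
            first = float(vals[0]) if len(vals) else 0.0
        last = float(vals[-1])
        if last <= first * 1e-20:  # also catches joint underflow to 0.0
            break
        k += chunk
    return math.fsum(pieces)


def ddct(
    ct_target_treat: float,
    ct_ref_treat: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> QpcrRecord:
    """RT-qPCR relative expression by the 2^-ddCt method."""
    for v in (ct_target_treat, ct_ref_treat, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    d = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return QpcrRecord(
        ct_target_treat,
        ct_ref_treat,
        ct_target_ctrl,
        ct_ref_ctrl,
        ddct=d,
        relative_expression=2.0 ** (-d),
    )


def build_records(
    counts: list[tuple[str, int, int]], n1: int, n2: int
) -> list[ExpressionRecord]:
    """Expression records (RPM, ratio, exact p) for (name, x, y) triples."""
    records = []
    for name, x, y in counts:
        r = ExpressionRecord(name=name, x=x, y=y, n1=n1, n2=n2)
        r.rpm_control = rpm_normalize(x, n1)
        r.rpm_drought = rpm_normalize(y, n2)
        r.log2_ratio = log2_ratio(r.rpm_drought, r.rpm_control)
        r.p_value = ac_pvalue(x, y, n1, n2)
        records.append(r)
    return records


def _bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, pvals[idx] * n / rank)
        q[idx] = running
    return q


def call_de(
    records: list[ExpressionRecord],
    min_rpm: float = 1.0,
    fold: float = 2.0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Differential-expression table with up/down calls.

    Records with RPM < ``min_rpm`` in both libraries are discarded.  A call
    requires p <= alpha and a fold-change of at least ``fold`` in either
    direction; a tag expressed in only one library counts as an infinite
    fold-change, with direction from the expressed side.  A
    Benjamini-Hochberg q column is reported for reference but not used for
    the calls (mirroring single-library exact-test practice).
    """
    kept = [r for r in records if r.rpm_control >= min_rpm or r.rpm_drought >= min_rpm]
    rows = []
    log2_fold = math.log2(fold)
    for r in kept:
        if math.isnan(r.log2_ratio):
            big_change = r.rpm_control > 0 or r.rpm_drought > 0
            direction = "up" if r.rpm_drought > r.rpm_control else "down"
        else:
            big_change = abs(r.log2_ratio) >= log2_fold
            direction = "up" if r.log2_ratio > 0 else "down"
        call = direction if (big_change and r.p_value <= alpha) else "ns"
        rows.append(
            {
                "name": r.name,
                "x": r.x,
                "y": r.y,
                "N1": r.n1,
                "N2": r.n2,
                "rpm_control": r.rpm_control,
                "rpm_drought": r.rpm_drought,
                "log2_ratio": r.log2_ratio,
                "p_value": r.p_value,
                "call": call,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "name",
            "x",
            "y",
            "N1",
            "N2",
            "rpm_control",
            "rpm_drought",
            "log2_ratio",
            "p_value",
            "call",
        ],
    )
    if len(df):
        df["bh_q"] = _bh_qvalues(df["p_value"].to_numpy())
    else:
        df["bh_q"] = []
    return df
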