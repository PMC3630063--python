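"""Nested RNA secondary-structure prediction under a stacking energy model.

The folder fills the role a thermodynamic folder (MFOLD/RNAfold) plays in a
miRNA-discovery pipeline, with a deliberately simple, fully specified model so
that every prediction is reproducible and checkable against exhaustive
enumeration:

* allowed pairs: G:C, A:U and the G:U wobble;
* minimum hairpin loop of 3 unpaired nucleotides;
* pseudoknot-free (nested) structures only;
* energy is carried entirely by helix stacks: two pairs (i, j) and
  (i+1, j-1) stacked on each other contribute the mean of the two pair
  values, with G:C = -3.0, A:U = -2.0 and G:U = -1.0 kcal/mol.  Isolated
  pairs therefore contribute nothing, which penalises the scattered
  single pairs that a plain base-pair-maximisation recursion would report.

A plug-in backend with the same ``(sequence) -> (structure, mfe)`` contract
(e.g. a wrapper around RNAfold) can replace the internal model wherever a
folding backend is accepted.

Internally scores are integers in units of -0.5 kcal/mol (pair values
G:C = 3, A:U = 2, G:U = 1; a stack adds the sum of its two pair values),
so the dynamic programme is exact.
"""

from __future__ import annotations

import numpy as np

from .seqtools import PAIR_VALUE, encode

MIN_LOOP = 3
_NEG = -(10**9)


def _fold_arrays(codes, pv):  # pragma: no cover - exercised via wrappers
    n = codes.shape[0]
    M = np.zeros((n + 1, n + 1), dtype=np.int64)
    P = np.full((n, n), _NEG, dtype=np.int64)
    for span in range(MIN_LOOP + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            v = pv[codes[i], codes[j]]
            if v > 0:
                best = M[i + 1, j - 1]
                if P[i + 1, j - 1] > _NEG // 2:
                    cand = P[i + 1, j - 1] + v + pv[codes[i + 1], codes[j - 1]]
                    if cand > best:
                        best = cand
                P[i, j] = best
            best = M[i, j - 1]
            for k in range(i, j - MIN_LOOP - 1 + 1):
                if P[k, j] > _NEG // 2:
                    left = M[i, k - 1] if k > i else 0
                    cand = left + P[k, j]
                    if cand > best:
                        best = cand
            M[i, j] = best

    partner = np.full(n, -1, dtype=np.int64)
    # iterative traceback; each frame is (i, j, in_pair)
    stack_i = np.empty(2 * n + 4, dtype=np.int64)
    stack_j = np.empty(2 * n + 4, dtype=np.int64)
    stack_p = np.empty(2 * n + 4, dtype=np.int64)
    top = 0
    if n > 0:
        stack_i[top] = 0
        stack_j[top] = n - 1
        stack_p[top] = 0
        top += 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        inp = stack_p[top]
        if j <= i:
            continue
        if inp == 1:
            partner[i] = j
            partner[j] = i
            if j - i - 1 < MIN_LOOP + 2:
                continue
            v = pv[codes[i], codes[j]]
            # prefer the stacked continuation (smallest next 5' index)
            if P[i + 1, j - 1] > _NEG // 2 and (
                P[i + 1, j - 1] + v + pv[codes[i + 1], codes[j - 1]] == P[i, j]
            ):
                stack_i[top] = i + 1
                stack_j[top] = j - 1
                stack_p[top] = 1
                top += 1
            else:
                stack_i[top] = i + 1
                stack_j[top] = j - 1
                stack_p[top] = 0
                top += 1
            continue
        # M(i, j): scan pairings with ascending 5' index, then j unpaired
        if M[i, j] == 0:
            continue
        found = False
        for k in range(i, j - MIN_LOOP - 1 + 1):
            if P[k, j] > _NEG // 2:
                left = M[i, k - 1] if k > i else 0
                if left + P[k, j] == M[i, j]:
                    if k > i:
                        stack_i[top] = i
                        stack_j[top] = k - 1
                        stack_p[top] = 0
                        top += 1
                    stack_i[top] = k
                    stack_j[top] = j
                    stack_p[top] = 1
                    top += 1
                    found = True
                    break
        if not found:
            stack_i[top] = i
            stack_j[top] = j - 1
            stack_p[top] = 0
            top += 1
    return partner, M[0, n - 1] if n > 0 else 0


try:  # pragma: no cover - environment dependent
    from numba import njit

    _fold_arrays_jit = njit(cache=True)(_fold_arrays)
except Exception:  # pragma: no cover
    _fold_arrays_jit = None

_use_jit = True


def _run_fold(codes: np.ndarray):
    pv = PAIR_VALUE.astype(np.int64)
    if _use_jit and _fold_arrays_jit is not None:
        return _fold_arrays_jit(codes, pv)
    return _fold_arrays(codes, pv)


def partner_map(structure: str) -> np.ndarray:
    """0-based partner index per position, -1 where unpaired.

    Raises ValueError on unbalanced dot-bracket strings.
    """
    partner = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure string")
            j = stack.pop()
            partner[i] = j
            partner[j] = i
        elif c != ".":
            raise ValueError(f"bad structure character {c!r}")
    if stack:
        raise ValueError("unbalanced structure string")
    return partner


def structure_energy(seq: str, structure: str) -> float:
    """Stacking energy (kcal/mol) of a given nested structure under the model."""
    part = partner_map(structure)
    codes = encode(seq)
    score = 0
    for i, j in enumerate(part):
        if j > i and part[i + 1] == j - 1 and j - 1 > i + 1:
            score += int(PAIR_VALUE[codes[i], codes[j]])
            score += int(PAIR_VALUE[codes[i + 1], codes[j - 1]])
    return -score / 2.0


def fold_rna(sequence: str, backend=None) -> tuple[str, float]:
    """Fold an RNA sequence into its best nested structure.

    Parameters
    ----------
    sequence:
        RNA string.  T is accepted and treated as U.  Sequences shorter
        than a minimal hairpin (loop of 3 closed by a pair) fold to the
        open chain with energy 0.
    backend:
        Optional callable ``(sequence) -> (structure, mfe)`` replacing the
        internal model (e.g. an RNAfold wrapper).

    Returns
    -------
    (structure, mfe):
        Dot-bracket string of the same length and the model energy in
        kcal/mol (<= 0; ties in the optimum are broken toward the pairing
        with the smallest 5' index).
    """
    if not sequence:
        raise ValueError("empty sequence")
    if backend is not None:
        return backend(sequence)
    codes = encode(sequence)
    partner, score = _run_fold(codes)
    chars = []
    for i, j in enumerate(partner):
        if j < 0:
            chars.append(".")
        elif j > i:
            chars.append("(")
        else:
            chars.append(")")
    return "".join(chars), -float(score) / 2.0 + 0.0
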