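"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (pairwise comparisons, explicit
loops, focal-set enumeration) and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# -- rough set -------------------------------------------------------------


def brute_partition(rows: list[tuple], col_indices: list[int]) -> set[frozenset]:
    """Blocks via all-pairs comparison of the selected columns."""
    n = len(rows)
    # union-find-free: block of i = all j agreeing with i on every column
    blocks = set()
    for i in range(n):
        block = frozenset(
            j
            for j in range(n)
            if all(rows[j][c] == rows[i][c] for c in col_indices)
        )
        blocks.add(block)
    return blocks


def brute_conditional_entropy(
    attr_blocks: set[frozenset], dec_blocks: set[frozenset], n: int
) -> float:
    """-sum_b p(b) sum_d p(d|b) ln p(d|b) with 0 ln 0 = 0, by explicit loops."""
    h = 0.0
    for b in attr_blocks:
        p_b = len(b) / n
        for d in dec_blocks:
            p_db = len(b & d) / len(b)
            if p_db > 0:
                h -= p_b * p_db * math.log(p_db)
    return h


def brute_weights(values: np.ndarray, decision: np.ndarray) -> np.ndarray:
    """Significance-normalized weights composed entirely from the oracles."""
    n, m = values.shape
    rows = [tuple(values[i]) for i in range(n)]
    dec_rows = [(decision[i],) for i in range(n)]
    dec_blocks = brute_partition(dec_rows, [0])

    def h_given(cols: list[int]) -> float:
        return brute_conditional_entropy(
            brute_partition(rows, cols), dec_blocks, n
        )

    h_full = h_given(list(range(m)))
    sig = np.array(
        [abs(h_given([c for c in range(m) if c != j]) - h_full) for j in range(m)]
    )
    sig[sig < 1e-12] = 0.0  # same roundoff clamp as the implementation
    total = sig.sum()
    if total == 0:
        return np.full(m, 1.0 / m)
    return sig / total


# -- Dempster-Shafer -------------------------------------------------------

POS = frozenset({"pos"})
NEG = frozenset({"neg"})
THETA = frozenset({"pos", "neg"})


def brute_dempster(m1: dict, m2: dict) -> dict:
    """Dempster's rule by enumerating every focal-element intersection."""
    unnorm: dict[frozenset, float] = {}
    conflict = 0.0
    for a, b in itertools.product(m1, m2):
        mass = m1[a] * m2[b]
        inter = a & b
        if inter:
            unnorm[inter] = unnorm.get(inter, 0.0) + mass
        else:
            conflict += mass
    norm = 1.0 - conflict
    return {k: v / norm for k, v in unnorm.items()}


def mass_dict(m_pos: float, m_neg: float, m_theta: float) -> dict:
    return {POS: m_pos, NEG: m_neg, THETA: m_theta}


# -- calibration / metrics -------------------------------------------------


def brute_top_left(scores, labels) -> float:
    """Exhaustive search over observed values; smallest threshold on ties."""
    n_pos = sum(1 for y in labels if y == 1)
    n_neg = sum(1 for y in labels if y == 0)
    best_t, best_d = None, None
    for t in sorted(set(scores)):
        tp = sum(1 for s, y in zip(scores, labels) if s > t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s > t and y == 0)
        d = (fp / n_neg) ** 2 + (1 - tp / n_pos) ** 2
        if best_d is None or d < best_d:
            best_t, best_d = t, d
    return best_t


def brute_auc(scores, labels) -> float:
    """All-pairs counting with ties worth 0.5."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
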