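"""Independent brute-force oracles used to pin expected values in tests.

These deliberately avoid the library code paths they check: alignment
scores come from exhaustive enumeration of alignment operation strings,
Mann-Whitney p values from full enumeration of group splits, and BH q
values from the direct step-up formula.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from math import comb

from Bio.Align import substitution_matrices


def brute_force_global(seq_a: str, seq_b: str, matrix_name: str, gap_open: int, gap_extend: int) -> float:
    """Best global alignment score by exhaustive enumeration of op strings.

    Affine gaps: a gap of length k costs gap_open + k * gap_extend.  End
    gaps are penalized (plain Needleman-Wunsch semantics).  Feasible only
    for very short sequences.
    """
    matrix = substitution_matrices.load(matrix_name.upper())

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        # state: last op ('M', 'I', 'D', or 'S' for start)
        if i == len(seq_a) and j == len(seq_b):
            return 0.0
        candidates = []
        if i < len(seq_a) and j < len(seq_b):
            candidates.append(matrix[seq_a[i], seq_b[j]] + best(i + 1, j + 1, "M"))
        if i < len(seq_a):  # gap in seq_b
            cost = gap_extend if state == "D" else gap_open + gap_extend
            candidates.append(-cost + best(i + 1, j, "D"))
        if j < len(seq_b):  # gap in seq_a
            cost = gap_extend if state == "I" else gap_open + gap_extend
            candidates.append(-cost + best(i, j + 1, "I"))
        return max(candidates)

    return best(0, 0, "S")


def brute_force_local(seq_a: str, seq_b: str, matrix_name: str, gap_open: int, gap_extend: int) -> float:
    """Best local alignment score: max over all substring pairs of the
    end-gap-free global score, floored at 0 (empty alignment)."""
    best_score = 0.0
    for i0 in range(len(seq_a) + 1):
        for i1 in range(i0 + 1, len(seq_a) + 1):
            for j0 in range(len(seq_b) + 1):
                for j1 in range(j0 + 1, len(seq_b) + 1):
                    score = brute_force_global(
                        seq_a[i0:i1], seq_b[j0:j1], matrix_name, gap_open, gap_extend
                    )
                    best_score = max(best_score, score)
    return best_score


def mann_whitney_enumeration_p(x: list[float], y: list[float]) -> float:
    """Two-sided Mann-Whitney p by full enumeration of group splits."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(group_a: list[float], group_b: list[float]) -> float:
        u = 0.0
        for a in group_a:
            for b in group_b:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    mu = n1 * len(y) / 2.0
    observed_dev = abs(u_stat(x, y) - mu)
    hits = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        group_a = [pooled[i] for i in idx]
        group_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(group_a, group_b) - mu) >= observed_dev - 1e-12:
            hits += 1
    assert total == comb(len(pooled), n1)
    return hits / total


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg q values by the direct step-up formula."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        running_min = min(running_min, pvals[i] * m / rank_from_end)
        q[i] = running_min
    return q
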