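"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: statistics are
recomputed from explicit pair enumeration and textbook formulas so that
agreement is a real cross-check, not a tautology.
"""

from __future__ import annotations

from itertools import combinations
import math

import numpy as np


def brute_pairwise_mean(matrix: np.ndarray) -> float:
    """Mean number of differing sites over all haplotype pairs."""
    n = matrix.shape[0]
    pairs = list(combinations(range(n), 2))
    if not pairs:
        return float("nan")
    return float(np.mean([np.sum(matrix[i] != matrix[j]) for i, j in pairs]))


def brute_cross_mean(a: np.ndarray, b: np.ndarray) -> float:
    """Mean number of differing sites over all between-panel pairs."""
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            total += np.sum(a[i] != b[j])
    return total / (a.shape[0] * b.shape[0])


def brute_window_fst(x: np.ndarray, y: np.ndarray) -> float | None:
    """1 - Hw/Hb from full pairwise difference enumeration."""
    hw = 0.5 * (brute_pairwise_mean(x) + brute_pairwise_mean(y))
    hb = brute_cross_mean(x, y)
    if hb == 0.0:
        return None
    return 1.0 - hw / hb


def brute_tajimas_d(matrix: np.ndarray) -> float | None:
    """Direct evaluation of the 1989 formula with explicit loops."""
    n, L = matrix.shape
    if n < 4:
        return None
    seg = [
        j for j in range(L)
        if 0 < int(np.sum(matrix[:, j])) < n
    ]
    s = len(seg)
    if s == 0:
        return None
    pi = brute_pairwise_mean(matrix)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def exact_balanced_pvalue(matrix: np.ndarray, n_x: int) -> tuple[float, float]:
    """Exact permutation p over all balanced splits (small n only).

    Returns (observed F_ST, exact p) where the observed grouping is the
    first ``n_x`` rows vs the rest; ties count toward the tail.
    """
    n = matrix.shape[0]
    obs = brute_window_fst(matrix[:n_x], matrix[n_x:])
    hits = total = 0
    for combo in combinations(range(n), n_x):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        f = brute_window_fst(matrix[mask], matrix[~mask])
        if f is None:
            continue
        total += 1
        if f >= obs - 1e-12:
            hits += 1
    return obs, hits / total


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (pi0 = 1 oracle)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(q, 0, 1)
    return out
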