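"""Independent oracles used by the test suite.

Everything here is deliberately implemented by brute force / direct
enumeration, without touching the package's own code paths, so tests
compare two genuinely independent routes to each quantity.
"""

from __future__ import annotations

from math import lgamma

import numpy as np


# ---------------------------------------------------------------- NNLS
def projected_gradient_nnls(
    S: np.ndarray, c: np.ndarray, iters: int = 20000
) -> np.ndarray:
    """Solve min ||c - S x||, x >= 0 by plain projected gradient descent."""
    S = np.asarray(S, dtype=float)
    c = np.asarray(c, dtype=float)
    G = S.T @ S
    b = S.T @ c
    # Lipschitz constant of the gradient
    step = 1.0 / max(np.linalg.eigvalsh(G).max(), 1e-12)
    x = np.zeros(S.shape[1])
    for _ in range(iters):
        x_new = np.maximum(0.0, x - step * (G @ x - b))
        if np.max(np.abs(x_new - x)) < 1e-13:
            x = x_new
            break
        x = x_new
    return x


# -------------------------------------------------------- Fisher exact
def hypergeom_log_pmf(a: int, r1: int, c1: int, n: int) -> float:
    b, c, d = r1 - a, c1 - a, n - r1 - c1 + a
    return (
        lgamma(r1 + 1)
        + lgamma(n - r1 + 1)
        + lgamma(c1 + 1)
        + lgamma(n - c1 + 1)
        - lgamma(n + 1)
        - lgamma(a + 1)
        - lgamma(b + 1)
        - lgamma(c + 1)
        - lgamma(d + 1)
    )


def fisher_two_sided_enum(table, tie_rel: float = 1e-7) -> float:
    """Two-sided Fisher p by full enumeration of fixed-margin tables.

    Sums the probabilities of all tables no more probable than the
    observed one; ``tie_rel`` is the relative tolerance for probability
    ties (the convention shared by the standard implementations).
    """
    t = np.asarray(table, dtype=np.int64)
    a = int(t[0, 0])
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    if r1 in (0, n) or c1 in (0, n):
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    lp = np.array([hypergeom_log_pmf(k, r1, c1, n) for k in range(lo, hi + 1)])
    p = np.exp(lp)
    p /= p.sum()
    p_obs = p[a - lo]
    return float(p[p <= p_obs * (1.0 + tie_rel)].sum())


def fisher_two_sided_for_margins(r1: int, c1: int, n: int, tie_rel: float = 1e-7):
    """Vector of two-sided p-values for every table with the given margins."""
    if r1 in (0, n) or c1 in (0, n):
        lo, hi = max(0, r1 + c1 - n), min(r1, c1)
        return np.ones(hi - lo + 1), lo
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    lp = np.array([hypergeom_log_pmf(k, r1, c1, n) for k in range(lo, hi + 1)])
    p = np.exp(lp)
    p /= p.sum()
    ps = np.array([p[p <= p_k * (1.0 + tie_rel)].sum() for p_k in p])
    return ps, lo


# ----------------------------------------------------- string contexts
def run_length_at(seq: str, pos: int) -> int:
    """Length of the homopolymer run in ``seq`` starting at ``pos``."""
    if pos >= len(seq):
        return 0
    base = seq[pos]
    n = 0
    while pos + n < len(seq) and seq[pos + n] == base:
        n += 1
    return n


def tandem_copies_at(seq: str, pos: int, unit: str) -> int:
    """Number of consecutive copies of ``unit`` in ``seq`` from ``pos``."""
    n = 0
    size = len(unit)
    while seq[pos + n * size : pos + (n + 1) * size] == unit:
        n += 1
    return n


def flank_homology(seq: str, start: int, deleted: str) -> int:
    """Microhomology of a deletion by direct prefix/suffix comparison."""
    size = len(deleted)
    right = 0
    for k in range(1, size):
        if seq[start + size : start + size + k] == deleted[:k]:
            right = k
        else:
            break
    left = 0
    for k in range(1, size):
        if start - k < 0:
            break
        if seq[start - k : start] == deleted[size - k :]:
            left = k
        else:
            break
    return max(right, left)


def leftmost_equivalent_deletion(seq: str, start: int, size: int) -> int:
    """Smallest start whose deletion of ``size`` bases yields the same string."""
    target = seq[:start] + seq[start + size :]
    best = start
    for s in range(start - 1, -1, -1):
        if seq[:s] + seq[s + size :] == target:
            best = s
    return best


def leftmost_equivalent_insertion(seq: str, start: int, ins: str) -> tuple[int, str]:
    """Smallest (start, sequence) insertion yielding the same string."""
    target = seq[:start] + ins + seq[start:]
    best = (start, ins)
    size = len(ins)
    for s in range(start - 1, -1, -1):
        cand = target[s : s + size]
        if seq[:s] + cand + seq[s:] == target:
            best = (s, cand)
    return best


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]
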