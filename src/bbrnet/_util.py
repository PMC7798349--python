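"""Shared small-sample rank/permutation primitives.

Everything here is vectorised over leading axes so that exhaustive
permutation nulls (720 rank permutations at n=6, 924 group splits at
6+6) stay cheap even when run for tens of thousands of feature pairs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

__all__ = [
    "midrank",
    "rowwise_pearson",
    "all_permutations",
    "group_splits",
    "spearman_null_abs_rho",
]


def midrank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    """Tie-aware (average) ranks along ``axis``, 1-based.

    Uses pairwise comparisons, so it is O(n^2) per vector but fully
    vectorised; intended for the short vectors (n <= 12) this package
    ranks inside permutation loops.
    """
    a = np.asarray(a, dtype=float)
    a = np.moveaxis(a, axis, -1)
    less = (a[..., None, :] < a[..., :, None]).sum(axis=-1)
    leq = (a[..., None, :] <= a[..., :, None]).sum(axis=-1)
    ranks = (less + leq + 1) / 2.0
    return np.moveaxis(ranks, -1, axis)


def rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation along the last axis of two broadcastable arrays.

    Rows where either vector is constant yield NaN (no correlation defined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    num = (xc * yc).sum(axis=-1)
    den = np.sqrt((xc**2).sum(axis=-1) * (yc**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(den > 0, r, np.nan)


def all_permutations(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) int array. n <= 9."""
    if n > 9:
        raise ValueError(f"refusing to enumerate {n}! permutations; use an approximation")
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def group_splits(n1: int, n2: int) -> np.ndarray:
    """All C(n1+n2, n1) assignments of pooled samples to group 1.

    Returns a boolean matrix (n_splits, n1+n2); True marks group-1
    membership. Row 0 is the observed assignment (first n1 samples).
    """
    n = n1 + n2
    combos = list(itertools.combinations(range(n), n1))
    mask = np.zeros((len(combos), n), dtype=bool)
    for i, c in enumerate(combos):
        mask[i, list(c)] = True
    # put the observed labelling first
    obs = np.zeros(n, dtype=bool)
    obs[:n1] = True
    where = np.flatnonzero((mask == obs).all(axis=1))[0]
    if where != 0:
        mask[[0, where]] = mask[[where, 0]]
    return mask


_NULL_CACHE: dict[int, np.ndarray] = {}


def spearman_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank permutations for tie-free vectors.

    The exact two-sided permutation p-value of an observed tie-free pair
    is then ``1 - searchsorted(null, |rho| - eps) / n!``. Cached per n.
    """
    if n not in _NULL_CACHE:
        perms = all_permutations(n)
        base = np.arange(1, n + 1, dtype=float)
        rho = rowwise_pearson(base[perms], base)
        _NULL_CACHE[n] = np.sort(np.abs(rho))
    return _NULL_CACHE[n]


def exact_p_from_null(null_abs: np.ndarray, abs_rho: float | np.ndarray) -> np.ndarray:
    """Two-sided exact p from a sorted null of |rho| values."""
    abs_rho = np.asarray(abs_rho, dtype=float)
    idx = np.searchsorted(null_abs, abs_rho - 1e-12, side="left")
    return (null_abs.size - idx) / null_abs.size


def binom_ci(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Normal-approximation binomial confidence interval for a proportion."""
    p = k / n
    half = z * math.sqrt(p * (1 - p) / n)
    return p - half, p + half
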