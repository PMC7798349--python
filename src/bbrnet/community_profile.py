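"""Community diversity statistics for the consortium taxon table.

Implements the downstream 16S statistics: rarefaction without
replacement to a fixed depth (default 23,900 reads), Shannon alpha
diversity, Bray–Curtis dissimilarity, non-metric multidimensional
scaling (Kruskal stress-1, SMACOF with isotonic regression), and the
ANOSIM permutation test on the rank-transformed distance matrix.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from ._util import midrank

DEFAULT_RAREFACTION_DEPTH = 23_900


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        if not np.isfinite(v).all():
            raise ValueError("non-finite distance")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distance")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float  # Kruskal stress-1
    iterations: int
    converged: bool
    stress_history: list[float] | None = None  # winning restart's trajectory


# -- rarefaction --------------------------------------------------------


def rarefy(
    counts: pd.DataFrame,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Subsample each sample column to exactly ``depth`` reads without replacement.

    ``counts`` is taxon x sample (the on-disk orientation). Samples whose
    library is below the depth are dropped with a warning naming them.
    """
    rng = np.random.default_rng(seed)
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("rarefaction requires integer counts")
        arr = arr.astype(np.int64)
    sums = arr.sum(axis=0)
    keep = sums >= depth
    if not keep.all():
        dropped = counts.columns[~keep].tolist()
        warnings.warn(
            f"samples below rarefaction depth {depth} dropped: {dropped}", stacklevel=2
        )
    out = np.empty((arr.shape[0], int(keep.sum())), dtype=np.int64)
    for j, col in enumerate(np.flatnonzero(keep)):
        out[:, j] = rng.multivariate_hypergeometric(arr[:, col], depth)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns[keep])


# -- alpha diversity ----------------------------------------------------


def shannon(counts, base: str = "e") -> float:
    """Shannon index H = -sum p_i log p_i over taxa with positive counts."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative count")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count vector has no diversity")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base == "2":
        base = 2
    if base in (2, "two"):
        return h / math.log(2)
    if base != "e":
        raise ValueError("base must be 'e' or 2")
    return h


# -- beta diversity -----------------------------------------------------


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity 1 - 2*sum(min)/(sum x + sum y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundance")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError("both vectors all-zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def bray_curtis_matrix(counts: pd.DataFrame) -> DistanceMatrix:
    """All-pairs Bray–Curtis over sample columns of a taxon x sample table."""
    ids = list(counts.columns)
    n = len(ids)
    d = np.zeros((n, n))
    arr = counts.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(arr[:, i], arr[:, j])
    return DistanceMatrix(d, ids)


# -- NMDS ---------------------------------------------------------------


def _stress1(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom == 0:
        return 0.0
    return math.sqrt(((dist - dhat) ** 2).sum() / denom)


def _nmds_single(
    d: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, float, int, bool]:
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    diss = d[iu]
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression(increasing=True)
    x = rng.normal(size=(n, k)) if init is None else init.copy()
    history: list[float] = []
    converged = False
    it = 0
    stress = np.inf
    for it in range(1, max_iter + 1):
        delta = x[:, None, :] - x[None, :, :]
        dist_full = np.sqrt((delta**2).sum(-1))
        dist = dist_full[iu]
        # monotone regression of configuration distances on dissimilarity
        # ranks (primary approach: tied dissimilarities get one fitted value)
        dhat = np.empty_like(dist)
        dhat[order] = iso.fit_transform(diss[order], dist[order])
        stress = _stress1(dist, dhat)
        history.append(stress)
        if len(history) > 1 and history[-2] - stress < tol:
            converged = True
            break
        # Guttman transform with the fitted disparities
        b = np.zeros((n, n))
        ratio = np.zeros_like(dist)
        np.divide(dhat, dist, out=ratio, where=dist > 0)
        b[iu] = -ratio
        b += b.T
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
    return x, stress, it, converged, history


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    SMACOF iterations alternate a Guttman update with isotonic regression
    of configuration distances on the dissimilarity ranks; the best of
    ``n_restarts`` random starts (plus one classical-scaling start) wins.
    """
    if d.n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, have {d.n}")
    rng = np.random.default_rng(seed)
    # classical (Torgerson) start as restart 0
    j = np.eye(d.n) - 1.0 / d.n
    bmat = -0.5 * j @ (d.values**2) @ j
    w, v = np.linalg.eigh(bmat)
    idx = np.argsort(w)[::-1][:k]
    init = v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))
    best = None
    for r in range(n_restarts + 1):
        x, stress, it, conv, hist = _nmds_single(
            d.values, k, rng, max_iter, tol, init=init if r == 0 else None
        )
        if best is None or stress < best[1]:
            best = (x, stress, it, conv, hist)
    x, stress, it, conv, hist = best
    coords = pd.DataFrame(
        x - x.mean(axis=0), index=d.ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coords, float(stress), it, conv, hist)


# -- ANOSIM -------------------------------------------------------------


def _anosim_r(ranked: np.ndarray, within: np.ndarray) -> float:
    m = ranked.size
    rw = ranked[within].mean()
    rb = ranked[~within].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    exact: bool | None = None,
) -> tuple[float, float]:
    """ANOSIM test of group separation on a dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise distances ranked with midranks; R is in [-1, 1].
    p is the fraction of label permutations with R* >= R. When the number
    of distinct labelings is small (<= max(n_perm, 1000)) the null is
    enumerated exhaustively; otherwise ``n_perm`` random permutations are
    drawn and the (+1)/(+1) convention guards p > 0.
    """
    labels = np.asarray(groups)
    if labels.size != d.n:
        raise ValueError("group labels do not match matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValueError(f"group(s) of size 1: {small}")
    iu = np.triu_indices(d.n, 1)
    ranked = midrank(d.condensed())
    same = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranked, same)

    n_distinct = math.factorial(d.n)
    for c in counts:
        n_distinct //= math.factorial(int(c))
    if exact is None:
        exact = n_distinct <= max(n_perm, 1000)

    if exact:
        ge = total = 0
        for perm in _distinct_label_orders(labels):
            same_p = perm[iu[0]] == perm[iu[1]]
            if _anosim_r(ranked, same_p) >= r_obs - 1e-12:
                ge += 1
            total += 1
        return r_obs, ge / total
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        same_p = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranked, same_p) >= r_obs - 1e-12:
            ge += 1
    return r_obs, (ge + 1) / (n_perm + 1)


def _distinct_label_orders(labels: np.ndarray):
    """Yield every distinct arrangement of a label multiset, once each."""
    n = labels.size
    uniq = list(dict.fromkeys(labels.tolist()))
    positions = list(range(n))

    def rec(remaining_positions, remaining_labels):
        if not remaining_labels:
            yield {}
            return
        lab = remaining_labels[0]
        k = int((labels == lab).sum())
        for combo in itertools.combinations(remaining_positions, k):
            rest = [p for p in remaining_positions if p not in combo]
            for assignment in rec(rest, remaining_labels[1:]):
                out = dict(assignment)
                for p in combo:
                    out[p] = lab
                yield out

    for assignment in rec(positions, uniq):
        arr = np.array([assignment[p] for p in positions])
        yield arr
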