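"""Per-species differential expression from transcript count matrices.

The stage owns its statistics end to end: TMM between-library scaling
(trimmed mean of M-values: 30% M trim, 5% A trim, precision weights),
log2-CPM with a prior count, treatment-vs-control log2 fold change, a
permutation t test (full enumeration of all C(12,6) = 924 label splits
at the study's 6+6 design) with a Welch t fallback, and Benjamini–
Hochberg FDR. Selection mirrors the study's heat-map gate:
|log2FC| > 0.58 and raw P < 0.05, with FDR reported alongside.

Each organism's transcriptome is normalised independently — counts come
from per-genome read assignment, so each species is its own composition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._util import group_splits

DEFAULT_LFC_MIN = 0.58
DEFAULT_P_MAX = 0.05


# -- TMM normalisation --------------------------------------------------


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray) -> float:
    """TMM scaling factor of library ``obs`` against ``ref`` (log2 scale -> 2**f)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 1.0
    o = obs[keep] / n_obs
    r = ref[keep] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic (delta-method) variance of M as precision weight
    w = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (
        n_ref * ref[keep]
    )
    if np.allclose(m, m[0]):
        return float(2 ** m[0])
    lo_m, hi_m = np.quantile(m, [0.30, 0.70])
    lo_a, hi_a = np.quantile(a, [0.05, 0.95])
    trim = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if trim.sum() == 0:
        trim = np.ones_like(m, dtype=bool)
    f = (m[trim] / w[trim]).sum() / (1.0 / w[trim]).sum()
    return float(2**f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """TMM normalisation factors per sample column, re-centred to geometric mean 1.

    Reference library: the sample whose 75th-percentile count fraction is
    closest to the mean of those fractions across samples.
    """
    arr = counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[lib == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    f75 = np.array([np.quantile(arr[:, j] / lib[j], 0.75) for j in range(arr.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [_tmm_pair_factor(arr[:, j], arr[:, ref]) for j in range(arr.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize_counts(
    counts: pd.DataFrame, prior_count: float = 0.5
) -> tuple[pd.DataFrame, pd.Series]:
    """log2-CPM on TMM-scaled effective library sizes.

    Returns (log2cpm genes x samples, tmm factors). The prior count is
    scaled per sample with its effective library size (as edgeR-style
    log-CPM does), so identical libraries give identical output.
    """
    factors = tmm_factors(counts)
    arr = counts.to_numpy(dtype=float)
    eff_lib = arr.sum(axis=0) * factors.to_numpy()
    prior = prior_count * eff_lib / eff_lib.mean()
    log2cpm = np.log2((arr + prior) / (eff_lib + 2 * prior) * 1e6)
    return pd.DataFrame(log2cpm, index=counts.index, columns=counts.columns), factors


# -- effect size and tests ----------------------------------------------


def _group_masks(columns, groups) -> tuple[np.ndarray, np.ndarray]:
    g = pd.Series(list(groups), index=columns) if not isinstance(groups, pd.Series) else groups
    g = g.reindex(columns)
    if g.isna().any():
        raise ValueError(f"samples without group: {g.index[g.isna()].tolist()}")
    treat = (g == "berberine").to_numpy()
    ctrl = (g == "control").to_numpy()
    if treat.sum() == 0 or ctrl.sum() == 0:
        raise ValueError("both groups must be non-empty")
    return treat, ctrl


def log2_fold_change(
    values: pd.DataFrame,
    groups,
    prior: float = 0.5,
    values_are_log2: bool = True,
) -> pd.Series:
    """Treatment-minus-control difference of group means on the log2 scale.

    With ``values_are_log2=False`` the matrix is linear-scale expression
    and log2(value + prior) is taken first.
    """
    treat, ctrl = _group_masks(values.columns, groups)
    v = values.to_numpy(dtype=float)
    if not values_are_log2:
        v = np.log2(v + prior)
    lfc = v[:, treat].mean(axis=1) - v[:, ctrl].mean(axis=1)
    return pd.Series(lfc, index=values.index, name="log2fc")


def _welch_t_rows(v: np.ndarray, m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    x1, x2 = v[:, m1], v[:, m2]
    n1, n2 = x1.shape[1], x2.shape[1]
    s1 = x1.var(axis=1, ddof=1) / n1
    s2 = x2.var(axis=1, ddof=1) / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (x1.mean(axis=1) - x2.mean(axis=1)) / np.sqrt(s1 + s2)
    return t


def de_test(
    norm: pd.DataFrame,
    groups,
    method: str = "perm_t",
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    max_enumerate: int = 20_000,
) -> tuple[pd.Series, pd.Series]:
    """Per-gene two-sided p-values on the normalised expression matrix.

    ``perm_t`` permutes group labels and compares |t*| with the observed
    Welch t; when the number of label splits C(n, n1) is at most
    ``max_enumerate`` every split is enumerated and p = #{|t*| >= |t|}/N
    (the observed split is one of them, so p > 0); otherwise ``n_perm``
    random splits are drawn with the (+1)/(+1) correction. Genes constant
    across all samples get p = 1 and a flag. Returns (p, constant_flag).
    """
    treat, ctrl = _group_masks(norm.columns, groups)
    v = norm.to_numpy(dtype=float)
    constant = v.std(axis=1) == 0
    t_obs = _welch_t_rows(v, treat, ctrl)

    if method == "welch_t":
        n1, n2 = int(treat.sum()), int(ctrl.sum())
        s1 = v[:, treat].var(axis=1, ddof=1) / n1
        s2 = v[:, ctrl].var(axis=1, ddof=1) / n2
        with np.errstate(invalid="ignore", divide="ignore"):
            df = (s1 + s2) ** 2 / (s1**2 / (n1 - 1) + s2**2 / (n2 - 1))
        p = 2 * stats.t.sf(np.abs(t_obs), df)
    elif method == "perm_t":
        if treat.sum() < 3 or ctrl.sum() < 3:
            raise ValueError("perm_t needs at least 3 samples per group")
        # reorder columns: treatment block first, control second
        order = np.concatenate([np.flatnonzero(treat), np.flatnonzero(ctrl)])
        vv = v[:, order]
        n1, n2 = int(treat.sum()), int(ctrl.sum())
        from math import comb

        if comb(n1 + n2, n1) <= max_enumerate:
            splits = group_splits(n1, n2)  # row 0 = observed
            exact = True
        else:
            rng = np.random.default_rng(seed)
            splits = np.zeros((n_perm, n1 + n2), dtype=bool)
            for i in range(n_perm):
                splits[i, rng.choice(n1 + n2, n1, replace=False)] = True
            exact = False
        # moment matrices: group sums / sums of squares for every split at once
        s = vv @ splits.T.astype(float)  # genes x splits
        sq = (vv**2) @ splits.T.astype(float)
        tot = vv.sum(axis=1, keepdims=True)
        tot_sq = (vv**2).sum(axis=1, keepdims=True)
        mean1 = s / n1
        mean2 = (tot - s) / n2
        var1 = (sq - n1 * mean1**2) / (n1 - 1)
        var2 = (tot_sq - sq - n2 * mean2**2) / (n2 - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_star = (mean1 - mean2) / np.sqrt(var1 / n1 + var2 / n2)
        t_star = np.abs(np.nan_to_num(t_star, nan=0.0, posinf=np.inf, neginf=np.inf))
        thresh = np.abs(np.nan_to_num(t_obs, nan=0.0))[:, None]
        ge = (t_star >= thresh - 1e-12).sum(axis=1)
        if exact:
            p = ge / splits.shape[0]
        else:
            p = (ge + 1) / (splits.shape[0] + 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    p = np.where(constant | ~np.isfinite(p), 1.0, p)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return (
        pd.Series(p, index=norm.index, name="p"),
        pd.Series(constant, index=norm.index, name="constant"),
    )


def bh_fdr(p) -> np.ndarray | pd.Series:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, in (0, 1])."""
    arr = np.asarray(p, dtype=float)
    if ((arr <= 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    n = arr.size
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index, name="fdr")
    return q


# -- assembly -----------------------------------------------------------


def de_analysis(
    counts: pd.DataFrame,
    groups,
    species: str | None = None,
    method: str = "perm_t",
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Full per-species DE table: log2fc, p, fdr, mean_expr (log2 CPM)."""
    norm, _ = normalize_counts(counts)
    lfc = log2_fold_change(norm, groups)
    p, constant = de_test(norm, groups, method=method, n_perm=n_perm, seed=seed)
    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "species": species or "",
            "log2fc": lfc.to_numpy(),
            "p": p.to_numpy(),
            "fdr": bh_fdr(p).to_numpy(),
            "mean_expr": norm.mean(axis=1).to_numpy(),
            "constant": constant.to_numpy(),
        }
    ).set_index("gene_id")
    return out


def filter_de(
    results: pd.DataFrame,
    lfc_min: float = DEFAULT_LFC_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> pd.DataFrame:
    """The heat-map gate: keep genes with |log2fc| > lfc_min and p < p_max."""
    if results.empty:
        return results
    keep = (results["log2fc"].abs() > lfc_min) & (results["p"] < p_max)
    return results.loc[keep]
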