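"""Correlation Difference Network: pairs whose association changed.

For every feature pair testable in both treatment groups, the change in
Spearman rho between control and berberine is tested two ways:

* Fisher-z two-sample test (default): z = atanh(rho), statistic
  (z1 - z2)/sqrt(1/(n1-3) + 1/(n2-3)) against the standard normal.
  Cheap and standard, but approximate at n = 6.
* Label-permutation test: sample-to-group assignment is permuted with
  each sample's (x, y) pair kept intact, |delta rho| is recomputed per
  split, and all C(12, 6) = 924 splits are enumerated at the study's
  6+6 design. Exact, recommended at small n.

Pairs whose rho is exactly +/-1 in either group (possible at n = 6 with
ties) are routed to the permutation test automatically because the
Fisher transform diverges there. Edges pass at p <= 0.01.
"""

from __future__ import annotations

import math
from math import comb
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._util import group_splits, midrank, rowwise_pearson
from .core_tables import FeatureAnnotation, FeatureTable

DEFAULT_DIFF_ALPHA = 0.01
RHO_CLAMP = 1.0 - 1e-6


def fisher_z(rho: float, clamp: float = RHO_CLAMP) -> float:
    """Fisher variance-stabilising transform z = atanh(rho).

    |rho| >= 1 is clamped to ``clamp`` (the caller flags such records);
    |rho| > 1 is a caller error.
    """
    if abs(rho) > 1 + 1e-12:
        raise ValueError(f"|rho| > 1: {rho}")
    return float(math.atanh(np.clip(rho, -clamp, clamp)))


def diff_test_fisher(
    rho1: float, n1: int, rho2: float, n2: int
) -> tuple[float, float]:
    """Two-sample Fisher-z test for a difference of correlations.

    stat = (z1 - z2)/sqrt(1/(n1-3) + 1/(n2-3)); two-sided normal p.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher-z difference test needs n > 3 in each group")
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    stat = (fisher_z(rho1) - fisher_z(rho2)) / se
    p = float(2 * stats.norm.sf(abs(stat)))
    return stat, max(p, np.nextafter(0, 1))


# -- permutation difference test ----------------------------------------


def _split_rhos(x: np.ndarray, y: np.ndarray, member1: np.ndarray) -> np.ndarray:
    """|paired| Spearman rho within the group-1 / group-2 halves of each split.

    ``member1`` is (n_splits, n) boolean. Returns delta = rho1 - rho2 per
    split; constant halves contribute rho = 0 (flagged by the caller).
    """
    n1 = int(member1[0].sum())
    n = member1.shape[1]
    idx1 = np.argsort(~member1, axis=1, kind="stable")[:, :n1]
    idx2 = np.argsort(member1, axis=1, kind="stable")[:, : n - n1]
    r1 = rowwise_pearson(midrank(x[idx1]), midrank(y[idx1]))
    r2 = rowwise_pearson(midrank(x[idx2]), midrank(y[idx2]))
    return np.nan_to_num(r1, nan=0.0) - np.nan_to_num(r2, nan=0.0)


def diff_test_permutation(
    x1, y1, x2, y2,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    max_enumerate: int = 20_000,
) -> float:
    """Permutation p for the change in Spearman rho between two groups.

    The null regenerates group membership: each sample keeps its (x, y)
    pair and the n1+n2 samples are re-split into groups of the original
    sizes. All C(n1+n2, n1) splits are enumerated when feasible (924 at
    6+6) and p = #{|delta*| >= |delta|}/N; otherwise random splits with
    the (+1)/(+1) convention. Constant features within a permuted half
    contribute rho = 0 for that replicate.
    """
    x1, y1, x2, y2 = (np.asarray(a, dtype=float) for a in (x1, y1, x2, y2))
    n1, n2 = x1.size, x2.size
    if n1 < 4 or n2 < 4:
        raise ValueError("permutation difference test needs n >= 4 per group")
    x = np.concatenate([x1, x2])
    y = np.concatenate([y1, y2])
    if comb(n1 + n2, n1) <= max_enumerate:
        member1 = group_splits(n1, n2)  # row 0 = observed
        delta = _split_rhos(x, y, member1)
        return float((np.abs(delta) >= abs(delta[0]) - 1e-12).mean())
    rng = np.random.default_rng(seed)
    obs = np.zeros((1, n1 + n2), dtype=bool)
    obs[0, :n1] = True
    d_obs = abs(_split_rhos(x, y, obs)[0])
    member1 = np.zeros((n_perm, n1 + n2), dtype=bool)
    for i in range(n_perm):
        member1[i, rng.choice(n1 + n2, n1, replace=False)] = True
    delta = _split_rhos(x, y, member1)
    return float(((np.abs(delta) >= d_obs - 1e-12).sum() + 1) / (n_perm + 1))


def diff_pvalues_permutation_batch(
    x1: np.ndarray, y1: np.ndarray, x2: np.ndarray, y2: np.ndarray,
    chunk: int = 512,
) -> np.ndarray:
    """Enumerated permutation difference p for many pairs at once.

    Inputs are (n_pairs, n_group) arrays; every C(n1+n2, n1) split is
    enumerated (so n1+n2 must keep that count modest, e.g. 924 at 6+6).
    Semantics match :func:`diff_test_permutation` with full enumeration.
    """
    x1, y1, x2, y2 = (np.asarray(a, dtype=float) for a in (x1, y1, x2, y2))
    n1, n2 = x1.shape[1], x2.shape[1]
    member1 = group_splits(n1, n2)
    n1_idx = np.argsort(~member1, axis=1, kind="stable")[:, :n1]
    n2_idx = np.argsort(member1, axis=1, kind="stable")[:, :n2]
    x = np.concatenate([x1, x2], axis=1)
    y = np.concatenate([y1, y2], axis=1)
    out = np.empty(x.shape[0])
    for s in range(0, x.shape[0], chunk):
        xs, ys = x[s : s + chunk], y[s : s + chunk]
        r1 = rowwise_pearson(midrank(xs[:, n1_idx]), midrank(ys[:, n1_idx]))
        r2 = rowwise_pearson(midrank(xs[:, n2_idx]), midrank(ys[:, n2_idx]))
        delta = np.nan_to_num(r1, nan=0.0) - np.nan_to_num(r2, nan=0.0)
        obs = np.abs(delta[:, 0])[:, None]
        out[s : s + chunk] = (np.abs(delta) >= obs - 1e-12).mean(axis=1)
    return out


# -- the difference network ---------------------------------------------


def difference_table(
    records_control: pd.DataFrame,
    records_treatment: pd.DataFrame,
    method: str = "fisher_z",
    table: FeatureTable | None = None,
    seed: int | np.random.Generator = 0,
    n_perm: int = 10_000,
) -> pd.DataFrame:
    """Per-pair difference statistics over the shared feature universe.

    Joins the two groups' correlation records on the canonical pair key;
    pairs skipped in either group (constant features) are excluded. With
    ``method='permutation'`` (or for |rho| = 1 pairs under Fisher-z,
    which route to the permutation test) the original ``table`` must be
    supplied so group samples can be re-split.
    """
    key = ["feature_i", "feature_j"]
    uni_c = set(map(tuple, records_control[key].to_numpy()))
    uni_t = set(map(tuple, records_treatment[key].to_numpy()))
    if uni_c != uni_t:
        diff = sorted(uni_c.symmetric_difference(uni_t))
        raise ValueError(
            f"feature-pair universes differ between groups ({len(diff)} pairs), "
            f"e.g. {diff[:5]}"
        )
    merged = records_control.merge(
        records_treatment, on=key, suffixes=("_control", "_treatment")
    )
    rho_c = merged["rho_control"].to_numpy()
    rho_t = merged["rho_treatment"].to_numpy()
    n_c = merged["n_control"].to_numpy()
    n_t = merged["n_treatment"].to_numpy()

    needs_perm = np.zeros(len(merged), dtype=bool)
    if method == "fisher_z":
        needs_perm = (np.abs(rho_c) >= 1 - 1e-12) | (np.abs(rho_t) >= 1 - 1e-12)
    elif method == "permutation":
        needs_perm[:] = True
    else:
        raise ValueError(f"unknown method {method!r}")

    stat = np.full(len(merged), np.nan)
    p = np.empty(len(merged))
    used = np.where(needs_perm, "permutation", "fisher_z")
    if (~needs_perm).any():
        z_c = np.arctanh(np.clip(rho_c, -RHO_CLAMP, RHO_CLAMP))
        z_t = np.arctanh(np.clip(rho_t, -RHO_CLAMP, RHO_CLAMP))
        se = np.sqrt(1.0 / (n_t - 3) + 1.0 / (n_c - 3))
        s = (z_t - z_c) / se
        stat[~needs_perm] = s[~needs_perm]
        p[~needs_perm] = np.maximum(
            2 * stats.norm.sf(np.abs(s[~needs_perm])), np.nextafter(0, 1)
        )
    if needs_perm.any():
        if table is None:
            raise ValueError(
                "permutation difference test requires the combined FeatureTable"
            )
        vt = table.group_values("berberine")
        vc = table.group_values("control")
        rows = np.flatnonzero(needs_perm)
        fi = merged.loc[rows, "feature_i"].to_numpy()
        fj = merged.loc[rows, "feature_j"].to_numpy()
        n1, n2 = vt.shape[0], vc.shape[0]
        if comb(n1 + n2, n1) <= 20_000:
            p[rows] = diff_pvalues_permutation_batch(
                vt[fi].to_numpy().T, vt[fj].to_numpy().T,
                vc[fi].to_numpy().T, vc[fj].to_numpy().T,
            )
        else:
            for k, a, b_ in zip(rows, fi, fj):
                p[k] = diff_test_permutation(
                    vt[a].to_numpy(), vt[b_].to_numpy(),
                    vc[a].to_numpy(), vc[b_].to_numpy(),
                    n_perm=n_perm, seed=seed,
                )
    out = pd.DataFrame(
        {
            "feature_i": merged["feature_i"],
            "feature_j": merged["feature_j"],
            "rho_control": rho_c,
            "rho_treatment": rho_t,
            "delta": rho_t - rho_c,
            "stat": stat,
            "p": p,
            "method": used,
        }
    )
    return out


def difference_network(
    records_control: pd.DataFrame,
    records_treatment: pd.DataFrame,
    alpha: float = DEFAULT_DIFF_ALPHA,
    method: str = "fisher_z",
    table: FeatureTable | None = None,
    annotations: Sequence[FeatureAnnotation] | None = None,
    seed: int | np.random.Generator = 0,
    n_perm: int = 10_000,
) -> nx.Graph:
    """Graph of feature pairs whose correlation changed at p <= alpha.

    Edge attributes carry rho in both groups, delta, the test statistic
    (Fisher-z path) and p.
    """
    diffs = difference_table(
        records_control, records_treatment, method=method, table=table,
        seed=seed, n_perm=n_perm,
    )
    g = nx.Graph(diff_alpha=float(alpha), method=method)
    ann = {a.feature_id: a for a in annotations} if annotations is not None else {}
    for row in diffs.loc[diffs["p"] <= alpha].itertuples(index=False):
        for fid in (row.feature_i, row.feature_j):
            a = ann.get(fid)
            if a is not None:
                g.add_node(
                    fid,
                    feature_type=a.feature_type,
                    compartment=a.compartment,
                    species=a.species or "",
                )
            else:
                g.add_node(fid)
        g.add_edge(
            row.feature_i,
            row.feature_j,
            rho_control=float(row.rho_control),
            rho_treatment=float(row.rho_treatment),
            delta=float(row.delta),
            p=float(row.p),
            method=row.method,
        )
    return g


def write_difference_table(diffs: pd.DataFrame, path: str | Path) -> None:
    diffs.to_csv(path, sep="\t", index=False)
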