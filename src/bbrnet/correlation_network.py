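"""All-pairs Spearman correlation networks over the combined feature table.

This is the analytical core: within each treatment group, Spearman's rho
is computed for every feature pair of the combined transcript /
bile-acid / taxon table; p-values use the exact permutation null (all n!
rank permutations — 720 at the study's n = 6) with the tie structure of
the observed vectors preserved, or the t approximation for larger n.
Edges pass at |rho| >= 0.7 and p <= 0.05 (negative correlations are kept,
the sign is an edge attribute), and typed graphs are exported as edge
lists, GraphML and SIF for Cytoscape.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._util import (
    all_permutations,
    exact_p_from_null,
    midrank,
    rowwise_pearson,
    spearman_null_abs_rho,
)
from .core_tables import FeatureAnnotation, FeatureTable

DEFAULT_RHO_MIN = 0.7
DEFAULT_P_MAX = 0.05
EXACT_N_MAX = 9


@dataclass(frozen=True)
class CorrelationRecord:
    feature_i: str
    feature_j: str
    rho: float
    n: int
    p: float
    group: str

    def __post_init__(self):
        if self.feature_i >= self.feature_j:
            raise ValueError("records are canonically ordered with feature_i < feature_j")


# -- rho ---------------------------------------------------------------


def spearman_rho(x, y) -> float:
    """Tie-aware Spearman rho: Pearson correlation of midranks.

    Equals 1 - 6*sum(d^2)/(n(n^2-1)) when there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho undefined for a constant vector")
    r = rowwise_pearson(midrank(x), midrank(y))
    return float(r)


def spearman_pvalue(x, y, method: str = "exact") -> float:
    """Two-sided p for Spearman rho.

    ``exact`` enumerates all n! permutations of the observed y (its tie
    structure travels with it, since midranks permute with values):
    p = #{perm : |rho*| >= |rho_obs|} / n!, never smaller than 1/n!.
    ``t_approx`` uses t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = spearman_rho(x, y)
    n = x.size
    if method == "exact":
        if n > EXACT_N_MAX:
            raise ValueError(
                f"exact enumeration limited to n <= {EXACT_N_MAX} (n={n}); use t_approx"
            )
        ry = midrank(y)
        rho_star = rowwise_pearson(midrank(x), ry[all_permutations(n)])
        return float((np.abs(rho_star) >= abs(rho) - 1e-12).mean())
    if method == "t_approx":
        if abs(rho) >= 1.0:
            return float(2.0 / math.factorial(n)) if n <= 12 else 0.0
        t = rho * math.sqrt((n - 2) / (1 - rho**2))
        return float(2 * stats.t.sf(abs(t), n - 2))
    raise ValueError(f"unknown method {method!r}")


# -- all pairs ----------------------------------------------------------


def all_pairs(
    table: FeatureTable,
    group: str,
    method: str = "auto",
) -> pd.DataFrame:
    """Spearman rho and p for every feature pair within one group's samples.

    Constant features are skipped (logged via warning). ``method='auto'``
    uses the exact permutation null when the group has n <= 9 samples
    and the t approximation otherwise. Tie-free pairs share one
    precomputed exact null; pairs with ties get their own enumeration.

    Returns a DataFrame with columns feature_i, feature_j, rho, n, p,
    group, canonically ordered (feature_i < feature_j).
    """
    values = table.group_values(group)
    n = values.shape[0]
    if n < 4:
        raise ValueError(f"group {group!r} has n={n} < 4 samples")
    if method == "auto":
        method = "exact" if n <= EXACT_N_MAX else "t_approx"

    arr = values.to_numpy(dtype=float)
    constant = arr.std(axis=0) == 0
    if constant.any():
        skipped = values.columns[constant].tolist()
        warnings.warn(f"constant features skipped in group {group!r}: {skipped}")
    cols = values.columns[~constant]
    ranks = midrank(arr[:, ~constant], axis=0)
    rc = ranks - ranks.mean(axis=0)
    norms = np.sqrt((rc**2).sum(axis=0))
    rho_mat = (rc / norms).T @ (rc / norms)

    has_ties = np.array(
        [np.unique(ranks[:, j]).size < n for j in range(ranks.shape[1])]
    )
    iu, ju = np.triu_indices(len(cols), 1)
    rho = rho_mat[iu, ju]

    if method == "exact":
        null_abs = spearman_null_abs_rho(n)
        p = exact_p_from_null(null_abs, np.abs(rho))
        tie_pair = has_ties[iu] | has_ties[ju]
        if tie_pair.any():
            perms = all_permutations(n)
            for k in np.flatnonzero(tie_pair):
                ry = ranks[:, ju[k]]
                rho_star = rowwise_pearson(ranks[:, iu[k]], ry[perms])
                p[k] = (np.abs(rho_star) >= abs(rho[k]) - 1e-12).mean()
    elif method == "t_approx":
        r = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        p = np.clip(p, np.nextafter(0, 1), 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    fi = np.asarray(cols)[iu]
    fj = np.asarray(cols)[ju]
    swap = fi > fj
    fi2 = np.where(swap, fj, fi)
    fj2 = np.where(swap, fi, fj)
    out = pd.DataFrame(
        {
            "feature_i": fi2,
            "feature_j": fj2,
            "rho": rho,
            "n": n,
            "p": p,
            "group": group,
        }
    )
    return out.sort_values(["feature_i", "feature_j"], ignore_index=True)


# -- graphs -------------------------------------------------------------


def build_network(
    records: pd.DataFrame,
    rho_min: float = DEFAULT_RHO_MIN,
    p_max: float = DEFAULT_P_MAX,
    annotations: Iterable[FeatureAnnotation] | None = None,
    include_isolated: bool = False,
) -> nx.Graph:
    """Filter correlation records into a typed undirected graph.

    An edge survives iff |rho| >= rho_min and p <= p_max. Node attributes
    carry the feature annotations when given; edge attributes carry rho,
    p, n and sign. Isolated (edge-less) features are included only on
    request.
    """
    g = nx.Graph(rho_min=float(rho_min), p_max=float(p_max))
    ann = {a.feature_id: a for a in annotations} if annotations is not None else {}

    def _add_node(fid):
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

    if include_isolated:
        for fid in ann:
            _add_node(fid)
    if len(records):
        keep = (records["rho"].abs() >= rho_min) & (records["p"] <= p_max)
        for row in records.loc[keep].itertuples(index=False):
            _add_node(row.feature_i)
            _add_node(row.feature_j)
            g.add_edge(
                row.feature_i,
                row.feature_j,
                rho=float(row.rho),
                p=float(row.p),
                n=int(row.n),
                sign=1 if row.rho >= 0 else -1,
            )
    return g


def topology_metrics(g: nx.Graph) -> dict:
    """Node/edge counts, density, components, degrees, cross-type edges."""
    degrees = dict(g.degree())
    cross = 0
    for u, v in g.edges():
        tu = g.nodes[u].get("feature_type")
        tv = g.nodes[v].get("feature_type")
        if tu is not None and tv is not None and tu != tv:
            cross += 1
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "density": nx.density(g) if g.number_of_nodes() > 1 else 0.0,
        "n_components": nx.number_connected_components(g) if g.number_of_nodes() else 0,
        "degree": degrees,
        "cross_type_edges": cross,
    }


def subnetwork(g: nx.Graph, focal: str, radius: int = 1) -> nx.Graph:
    """Induced subgraph of nodes within graph distance ``radius`` of ``focal``."""
    if focal not in g:
        raise KeyError(f"focal feature {focal!r} not in network")
    return nx.ego_graph(g, focal, radius=radius)


# -- export -------------------------------------------------------------


def write_edge_list(records_or_graph, path: str | Path) -> None:
    """Edge TSV (feature_i, feature_j, rho, p, n[, group])."""
    if isinstance(records_or_graph, nx.Graph):
        rows = [
            {"feature_i": u, "feature_j": v, **d}
            for u, v, d in records_or_graph.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        records_or_graph.to_csv(path, sep="\t", index=False)


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)


def write_sif(g: nx.Graph, path: str | Path) -> None:
    """Cytoscape SIF: source <interaction> target, with pos/neg edge types."""
    with open(path, "w") as fh:
        for u, v, d in g.edges(data=True):
            kind = "pos" if d.get("sign", 1) >= 0 else "neg"
            fh.write(f"{u}\t{kind}\t{v}\n")
        for node in nx.isolates(g):
            fh.write(f"{node}\n")
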