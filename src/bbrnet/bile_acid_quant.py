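"""Internal-standard bile-acid quantitation and compositional summaries.

Quantitation follows single-point stable-isotope-dilution arithmetic:
deuterated standards (d4-CA, d4-GCA, d4-TCA) are spiked at a known amount
(default 100 nmol/ml of extract) and each analyte's concentration is the
analyte/IS peak-area ratio scaled by the IS amount and normalised per gram
of dry matter (cecum, liver) or per litre (serum). A response factor of 1
is assumed unless a per-analyte factor is supplied.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_tables import (
    FeatureAnnotation,
    FeatureTable,
    TableValidationError,
)

CONJUGATIONS = ("unconjugated", "taurine", "glycine")
ORIGINS = ("primary", "secondary")

#: conjugation class -> default deuterated internal standard
DEFAULT_IS_MAP = {
    "unconjugated": "d4-CA",
    "glycine": "d4-GCA",
    "taurine": "d4-TCA",
}


@dataclass(frozen=True)
class AnalyteRecord:
    analyte_id: str
    conjugation: str  # unconjugated | taurine | glycine
    origin: str  # primary | secondary
    sulfated: bool = False

    def __post_init__(self):
        if self.conjugation not in CONJUGATIONS:
            raise ValueError(f"{self.analyte_id}: conjugation {self.conjugation!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"{self.analyte_id}: origin {self.origin!r}")


class BileAcidPanel:
    """Samples x analytes concentration matrix for one compartment.

    Units are μmol per g dry matter for cecum and liver, μmol per L for
    serum; a panel never mixes compartments.
    """

    def __init__(
        self,
        concentrations: pd.DataFrame,
        compartment: str,
        analytes: Sequence[AnalyteRecord],
        units: str | None = None,
    ):
        if compartment not in ("cecum", "liver", "serum"):
            raise ValueError(f"compartment {compartment!r}")
        ids = [a.analyte_id for a in analytes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate analyte ids in panel")
        if list(concentrations.columns) != ids:
            raise ValueError("analyte records not aligned with columns")
        arr = concentrations.to_numpy(dtype=float)
        if (arr < 0).any() or not np.isfinite(arr).all():
            raise ValueError("concentrations must be finite and non-negative")
        self.concentrations = concentrations.loc[sorted(concentrations.index)].copy()
        self.compartment = compartment
        self.analytes = list(analytes)
        self.units = units or ("umol/L" if compartment == "serum" else "umol/g")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.concentrations.index)

    def to_feature_table(self) -> FeatureTable:
        feats = [
            FeatureAnnotation(a.analyte_id, "bile_acid", self.compartment)
            for a in self.analytes
        ]
        return FeatureTable(self.concentrations, feats)

    def __repr__(self):
        n, k = self.concentrations.shape
        return f"BileAcidPanel({self.compartment}, {n} samples x {k} analytes, {self.units})"


# -- quantitation -------------------------------------------------------


def quantify_from_is(
    analyte_area: float,
    is_area: float,
    is_amount_nmol: float,
    sample_mass: float,
    response_factor: float = 1.0,
) -> float:
    """Concentration from a peak-area ratio against a deuterated standard.

    concentration = (analyte_area / is_area) * is_amount / sample_mass,
    with the nmol -> μmol conversion folded in, so the result is μmol/g
    (or μmol/L when ``sample_mass`` is a volume in litres).
    """
    if analyte_area < 0:
        raise ValueError(f"negative analyte peak area: {analyte_area}")
    if is_area <= 0:
        raise ValueError("internal standard not detected (IS area <= 0)")
    if sample_mass <= 0:
        raise ValueError(f"sample mass/volume must be positive, got {sample_mass}")
    nmol = (analyte_area / is_area) * is_amount_nmol * response_factor
    return nmol / 1000.0 / sample_mass


def quantify_panel(
    areas: pd.DataFrame,
    is_areas: pd.DataFrame,
    sample_mass: Mapping[str, float] | pd.Series,
    analytes: Sequence[AnalyteRecord],
    compartment: str,
    is_amount_nmol: float = 100.0,
    is_map: Mapping[str, str] = DEFAULT_IS_MAP,
    response_factors: Mapping[str, float] | None = None,
) -> BileAcidPanel:
    """Quantify a whole panel from peak-area tables.

    ``areas`` is samples x analytes; ``is_areas`` is samples x internal
    standards. Each analyte is quantified against the standard matching
    its conjugation class (d4-CA for unconjugated, d4-GCA for glyco-,
    d4-TCA for tauro-conjugates) unless ``is_map`` overrides this.
    """
    by_id = {a.analyte_id: a for a in analytes}
    missing = [c for c in areas.columns if c not in by_id]
    if missing:
        raise ValueError(f"analytes without registry entry: {missing}")
    mass = pd.Series(sample_mass, dtype=float).reindex(areas.index)
    if mass.isna().any():
        raise ValueError(f"missing sample mass for {mass.index[mass.isna()].tolist()}")
    out = pd.DataFrame(index=areas.index, columns=areas.columns, dtype=float)
    for col in areas.columns:
        std = is_map[by_id[col].conjugation]
        if std not in is_areas.columns:
            raise ValueError(f"internal standard {std!r} missing from IS area table")
        rf = 1.0 if response_factors is None else response_factors.get(col, 1.0)
        for sid in areas.index:
            out.loc[sid, col] = quantify_from_is(
                float(areas.loc[sid, col]),
                float(is_areas.loc[sid, std]),
                is_amount_nmol,
                float(mass.loc[sid]),
                rf,
            )
    return BileAcidPanel(out, compartment, [by_id[c] for c in areas.columns])


# -- summaries ----------------------------------------------------------


def total_bile_acids(panel: BileAcidPanel) -> pd.Series:
    """Per-sample total bile-acid pool (row sums, same units as the panel)."""
    if panel.concentrations.shape[1] == 0:
        raise ValueError("empty panel")
    return panel.concentrations.sum(axis=1)


def class_summary(panel: BileAcidPanel, by: str) -> pd.DataFrame:
    """Per-sample totals by analyte class (conjugation, origin or sulfated).

    Class totals conserve mass: they sum to ``total_bile_acids`` exactly.
    """
    if by == "conjugation":
        keys = {a.analyte_id: a.conjugation for a in panel.analytes}
        levels = list(CONJUGATIONS)
    elif by == "origin":
        keys = {a.analyte_id: a.origin for a in panel.analytes}
        levels = list(ORIGINS)
    elif by == "sulfated":
        keys = {a.analyte_id: "sulfated" if a.sulfated else "unsulfated" for a in panel.analytes}
        levels = ["unsulfated", "sulfated"]
    else:
        raise ValueError(f"unknown class key {by!r}; use conjugation|origin|sulfated")
    grouped = panel.concentrations.T.groupby(
        panel.concentrations.columns.map(keys)
    ).sum().T
    return grouped.reindex(columns=levels, fill_value=0.0)


# -- two-group comparisons ----------------------------------------------


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-aware U statistic for group x: #(x_i > y_j) + 0.5 #(x_i == y_j)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def compare_groups(x, y, test: str = "mann_whitney_exact") -> tuple[float, float]:
    """Two-sided comparison of two independent groups.

    ``mann_whitney_exact`` enumerates every C(n1+n2, n1) group assignment
    (intended for the study's n <= 12) and counts assignments whose U is
    at least as far from its null mean n1*n2/2 as the observed U.
    ``welch_t`` is the unequal-variance t test (Welch–Satterthwaite df).
    Returns (statistic, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if test == "welch_t":
        if np.var(x) == 0 and np.var(y) == 0:
            warnings.warn("both groups constant; Welch t undefined, returning p=1")
            return 0.0, 1.0
        stat, p = stats.ttest_ind(x, y, equal_var=False)
        return float(stat), float(p)
    if test != "mann_whitney_exact":
        raise ValueError(f"unknown test {test!r}")
    n1, n2 = x.size, y.size
    if n1 + n2 > 16:
        raise ValueError("exact enumeration supported up to n1+n2=16; use welch_t")
    pooled = np.concatenate([x, y])
    u_obs = _mann_whitney_u(x, y)
    mean_u = n1 * n2 / 2.0
    d_obs = abs(u_obs - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[list(idx)] = True
        u = _mann_whitney_u(pooled[mask], pooled[~mask])
        if abs(u - mean_u) >= d_obs - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


# -- registry / panel I/O ------------------------------------------------


def read_analyte_registry(path: str | Path) -> list[AnalyteRecord]:
    """Analyte registry TSV: analyte_id, conjugation, origin, sulfated."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"analyte_id", "conjugation", "origin", "sulfated"}
    if not need.issubset(df.columns):
        raise TableValidationError(f"{path}: registry needs columns {sorted(need)}")
    return [
        AnalyteRecord(
            r.analyte_id,
            r.conjugation,
            r.origin,
            str(r.sulfated).strip().lower() in ("1", "true", "yes"),
        )
        for r in df.itertuples(index=False)
    ]


def write_analyte_registry(analytes: Sequence[AnalyteRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "analyte_id": [a.analyte_id for a in analytes],
            "conjugation": [a.conjugation for a in analytes],
            "origin": [a.origin for a in analytes],
            "sulfated": [str(a.sulfated).lower() for a in analytes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_panel(
    path: str | Path, registry: Sequence[AnalyteRecord], compartment: str
) -> BileAcidPanel:
    """Read an analyte x sample concentration TSV into a panel."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    by_id = {a.analyte_id: a for a in registry}
    missing = [a for a in df.index if a not in by_id]
    if missing:
        raise TableValidationError(f"{path}: analytes not in registry: {missing}")
    return BileAcidPanel(df.T, compartment, [by_id[a] for a in df.index])


def write_panel(panel: BileAcidPanel, path: str | Path) -> None:
    out = panel.concentrations.T
    out.index.name = "analyte_id"
    out.to_csv(path, sep="\t")
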