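"""Data model and I/O for the tabular inputs shared by all pipeline stages.

The on-disk dialect is the bioinformatics convention: tab-separated,
features as rows, samples as columns, first column holding feature IDs.
In memory the canonical orientation is samples x features (a pandas
DataFrame), which is what the correlation machinery consumes.

Sample order is canonicalised (sorted by sample_id) in every constructed
table so that same-input runs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("control", "berberine")
SEXES = ("M", "F")
FEATURE_TYPES = ("transcript", "bile_acid", "taxon")
COMPARTMENTS = ("cecum", "liver", "serum", "none")

#: The seven members of the defined gut consortium.
B4PC2_SPECIES = (
    "Bacteroides uniformis",
    "Bacteroides vulgatus",
    "Parabacteroides distasonis",
    "Bilophila wadsworthia",
    "Clostridium hylemonae",
    "Clostridium hiranonis",
    "Blautia producta",
)


class TableValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    group: str  # control | berberine
    sex: str  # M | F

    def __post_init__(self):
        if self.group not in GROUPS:
            raise TableValidationError(
                f"sample {self.sample_id!r}: group {self.group!r} not in {GROUPS}"
            )
        if self.sex not in SEXES:
            raise TableValidationError(
                f"sample {self.sample_id!r}: sex {self.sex!r} not in {SEXES}"
            )


@dataclass(frozen=True)
class FeatureAnnotation:
    feature_id: str
    feature_type: str  # transcript | bile_acid | taxon
    compartment: str = "none"
    species: str | None = None

    def __post_init__(self):
        if self.feature_type not in FEATURE_TYPES:
            raise TableValidationError(
                f"feature {self.feature_id!r}: type {self.feature_type!r} not in {FEATURE_TYPES}"
            )
        if self.compartment not in COMPARTMENTS:
            raise TableValidationError(
                f"feature {self.feature_id!r}: compartment {self.compartment!r}"
            )
        if self.feature_type == "transcript":
            if self.species is None:
                raise TableValidationError(
                    f"transcript {self.feature_id!r} must carry a species"
                )
            if self.compartment != "cecum":
                raise TableValidationError(
                    f"transcript {self.feature_id!r}: transcripts are cecal"
                )
        if self.feature_type == "bile_acid" and self.compartment not in (
            "cecum",
            "liver",
            "serum",
        ):
            raise TableValidationError(
                f"bile acid {self.feature_id!r} needs compartment cecum/liver/serum"
            )
        if self.feature_type == "taxon" and self.compartment != "cecum":
            raise TableValidationError(f"taxon {self.feature_id!r}: taxa are cecal")


class FeatureTable:
    """Samples x features numeric matrix with per-feature annotations.

    ``values`` is a DataFrame indexed by sample_id with feature_id columns;
    ``samples`` optionally carries group/sex metadata (required before any
    per-group computation).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        features: Sequence[FeatureAnnotation],
        samples: Sequence[SampleMetadata] | None = None,
    ):
        values = values.copy()
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()].tolist()
            raise TableValidationError(f"duplicate sample id(s): {dup}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()].tolist()
            raise TableValidationError(f"duplicate feature id(s): {dup}")
        feat_ids = [f.feature_id for f in features]
        if list(values.columns) != feat_ids:
            raise TableValidationError("feature annotations not aligned with columns")
        if not np.isfinite(values.to_numpy(dtype=float)).all():
            raise TableValidationError("non-finite value in table")
        if (values.to_numpy(dtype=float) < 0).any():
            r, c = np.argwhere(values.to_numpy(dtype=float) < 0)[0]
            raise TableValidationError(
                f"negative value at sample {values.index[r]!r}, feature {values.columns[c]!r}"
            )
        # canonical sample order
        order = sorted(values.index)
        self.values = values.loc[order]
        self.features = list(features)
        self._samples: list[SampleMetadata] | None = None
        if samples is not None:
            self.attach_metadata(samples)

    # -- metadata -------------------------------------------------------
    def attach_metadata(self, samples: Iterable[SampleMetadata]) -> "FeatureTable":
        by_id = {}
        for s in samples:
            if s.sample_id in by_id:
                raise TableValidationError(f"duplicate sample metadata: {s.sample_id!r}")
            by_id[s.sample_id] = s
        missing = [sid for sid in self.values.index if sid not in by_id]
        if missing:
            raise TableValidationError(f"samples without metadata: {missing}")
        self._samples = [by_id[sid] for sid in self.values.index]
        return self

    @property
    def samples(self) -> list[SampleMetadata]:
        if self._samples is None:
            raise TableValidationError("sample metadata not attached")
        return self._samples

    @property
    def has_metadata(self) -> bool:
        return self._samples is not None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def annotation(self, feature_id: str) -> FeatureAnnotation:
        return self.features[self.values.columns.get_loc(feature_id)]

    def group_values(self, group: str) -> pd.DataFrame:
        if group not in GROUPS:
            raise TableValidationError(f"unknown group {group!r}")
        keep = [s.sample_id for s in self.samples if s.group == group]
        return self.values.loc[keep]

    def __repr__(self):
        n, f = self.values.shape
        return f"FeatureTable({n} samples x {f} features)"


# -- readers / writers --------------------------------------------------


def _parse_numeric(df: pd.DataFrame, path, kind: str) -> pd.DataFrame:
    for col in df.columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise TableValidationError(
                f"{path}: non-numeric cell at feature {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        if parsed.isna().any():
            row = df.index[parsed.isna()][0]
            raise TableValidationError(f"{path}: missing value at feature {row!r}, sample {col!r}")
        df[col] = parsed
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise TableValidationError(
            f"{path}: negative value at feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if kind == "counts":
        if not np.allclose(arr, np.round(arr)):
            r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise TableValidationError(
                f"{path}: non-integer count at feature {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )
        df = df.round().astype(np.int64)
    return df


def read_table(
    path: str | Path,
    kind: str = "counts",
    features: Sequence[FeatureAnnotation] | None = None,
    feature_type: str = "taxon",
    compartment: str = "cecum",
    species: str | None = None,
) -> FeatureTable:
    """Read a feature x sample TSV into a FeatureTable.

    ``kind`` is ``counts`` (non-negative integers) or ``concentrations``
    (non-negative reals). If explicit annotations are not supplied, every
    feature receives the (feature_type, compartment, species) given.
    """
    if kind not in ("counts", "concentrations"):
        raise ValueError(f"kind must be counts|concentrations, got {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise TableValidationError(f"{path}: duplicated feature id(s): {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise TableValidationError(f"{path}: duplicated sample id(s): {dup}")
    df = _parse_numeric(df, path, kind)
    if features is None:
        features = [
            FeatureAnnotation(fid, feature_type, compartment, species) for fid in df.index
        ]
    return FeatureTable(df.T, features)


def write_table(table: FeatureTable, path: str | Path) -> None:
    """Write a FeatureTable as a feature x sample TSV (inverse of read_table)."""
    out = table.values.T
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample-metadata TSV (columns sample_id, group, sex)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "sex"}
    if not required.issubset(df.columns):
        raise TableValidationError(
            f"{path}: metadata needs columns {sorted(required)}, has {list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise TableValidationError(f"{path}: duplicate sample_id(s): {dup}")
    return [
        SampleMetadata(r.sample_id, r.group, r.sex) for r in df.itertuples(index=False)
    ]


def write_metadata(samples: Sequence[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in samples]).to_csv(
        path, sep="\t", index=False
    )


# -- combination --------------------------------------------------------


def _prefixed(ann: FeatureAnnotation) -> str:
    if "|" in ann.feature_id:  # already prefixed; combining is idempotent
        return ann.feature_id
    if ann.feature_type == "transcript":
        short = ann.species.split()[-1] if ann.species else "sp"
        return f"{short}|{ann.feature_id}"
    if ann.feature_type == "bile_acid":
        return f"{ann.compartment}|{ann.feature_id}"
    return f"taxon|{ann.feature_id}"


def combine_features(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Column-wise concatenation of tables sharing one sample set.

    Mice are the observational units; compartment and species live in the
    feature annotations, so feature IDs are prefixed (``cecum|DCA``,
    ``wadsworthia|geneX``, ``taxon|...``) to guarantee uniqueness in the
    single combined feature table the correlation stages run on.
    """
    if not tables:
        raise ValueError("no tables to combine")
    ref = set(tables[0].sample_ids)
    for t in tables[1:]:
        other = set(t.sample_ids)
        if other != ref:
            diff = sorted(ref.symmetric_difference(other))
            raise TableValidationError(f"sample sets differ; symmetric difference: {diff}")
    order = sorted(ref)
    blocks, feats = [], []
    for t in tables:
        renamed = {a.feature_id: _prefixed(a) for a in t.features}
        blocks.append(t.values.loc[order].rename(columns=renamed))
        feats.extend(dataclasses.replace(a, feature_id=renamed[a.feature_id]) for a in t.features)
    values = pd.concat(blocks, axis=1)
    out = FeatureTable(values, feats)
    meta = next((t._samples for t in tables if t.has_metadata), None)
    if meta is not None:
        out.attach_metadata(meta)
    return out
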