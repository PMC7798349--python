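"""Load a study directory (as written by `bbrnet simulate` or assembled by
hand in the same layout) into the combined feature table."""

from __future__ import annotations

from pathlib import Path

from .bile_acid_quant import read_analyte_registry, read_panel
from .core_tables import (
    B4PC2_SPECIES,
    FeatureTable,
    combine_features,
    read_metadata,
    read_table,
)
from .differential_expression import normalize_counts

_SHORT_TO_SPECIES = {sp.split()[-1]: sp for sp in B4PC2_SPECIES}


def load_study_dir(indir: Path) -> FeatureTable:
    """Combined transcript (CPM) / taxon (relative) / bile-acid feature table."""
    metadata = read_metadata(indir / "metadata.tsv")
    parts = []
    for path in sorted(indir.glob("transcripts_*.tsv")):
        short = path.stem.removeprefix("transcripts_")
        species = _SHORT_TO_SPECIES.get(short, short)
        t = read_table(path, kind="counts", feature_type="transcript", species=species)
        log2cpm, _ = normalize_counts(t.values.T)
        parts.append(FeatureTable((2.0**log2cpm).T, t.features))
    taxa_path = indir / "taxon_counts.tsv"
    if taxa_path.exists():
        t = read_table(taxa_path, kind="counts", feature_type="taxon")
        rel = t.values.div(t.values.sum(axis=1), axis=0)
        parts.append(FeatureTable(rel, t.features))
    registry_path = indir / "analyte_registry.tsv"
    if registry_path.exists():
        registry = read_analyte_registry(registry_path)
        for path in sorted(indir.glob("bile_acids_*.tsv")):
            comp = path.stem.removeprefix("bile_acids_")
            parts.append(read_panel(path, registry, comp).to_feature_table())
    if not parts:
        raise FileNotFoundError(f"no study tables found in {indir}")
    combined = combine_features(parts)
    combined.attach_metadata(metadata)
    return combined
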