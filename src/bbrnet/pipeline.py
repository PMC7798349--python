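"""End-to-end orchestration: quantify -> diversity -> DE -> networks -> report.

A run executes the stages in the order the analysis was designed:
bile-acid summaries per compartment, community diversity on the taxon
table, per-species differential expression, per-group correlation
networks over the combined feature table, and the correlation-difference
network — writing every artifact under one run directory together with a
JSON manifest (parameters, seed, package version).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bile_acid_quant import (
    class_summary,
    compare_groups,
    read_analyte_registry,
    read_panel,
    total_bile_acids,
)
from .community_profile import (
    DEFAULT_RAREFACTION_DEPTH,
    anosim,
    bray_curtis_matrix,
    nmds,
    rarefy,
    shannon,
)
from .core_tables import (
    FeatureAnnotation,
    FeatureTable,
    combine_features,
    read_metadata,
    read_table,
)
from .correlation_difference import (
    difference_network,
    difference_table,
)
from .correlation_network import (
    all_pairs,
    build_network,
    topology_metrics,
    write_edge_list,
    write_graphml,
    write_sif,
)
from .differential_expression import de_analysis, filter_de, normalize_counts

log = logging.getLogger("bbrnet")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run (defaults = study values)."""

    metadata: str = "metadata.tsv"
    taxon_counts: str = "taxon_counts.tsv"
    transcript_tables: dict[str, str] = field(default_factory=dict)  # species -> path
    bile_acid_tables: dict[str, str] = field(default_factory=dict)  # compartment -> path
    analyte_registry: str = "analyte_registry.tsv"

    rho_min: float = 0.7
    p_max: float = 0.05
    diff_alpha: float = 0.01
    lfc_min: float = 0.58
    de_p: float = 0.05
    rarefaction_depth: int = DEFAULT_RAREFACTION_DEPTH
    anosim_perms: int = 999

    de_method: str = "perm_t"
    corr_p_method: str = "auto"
    diff_method: str = "fisher_z"
    seed: int = 0

    def validate(self):
        if not (0 <= self.rho_min <= 1):
            raise ValueError("rho_min must be in [0, 1]")
        for name in ("p_max", "diff_alpha", "de_p"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if self.rarefaction_depth < 1 or self.anosim_perms < 1:
            raise ValueError("rarefaction_depth and anosim_perms must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_inputs(config: RunConfig, indir: Path):
    metadata = read_metadata(indir / config.metadata)
    taxa = read_table(indir / config.taxon_counts, kind="counts", feature_type="taxon")
    registry = read_analyte_registry(indir / config.analyte_registry)
    panels = {
        comp: read_panel(indir / path, registry, comp)
        for comp, path in config.bile_acid_tables.items()
    }
    transcripts = {
        sp: read_table(
            indir / path, kind="counts", feature_type="transcript", species=sp
        )
        for sp, path in config.transcript_tables.items()
    }
    return metadata, taxa, panels, transcripts


def run_pipeline(config: RunConfig, indir: str | Path, outdir: str | Path) -> Path:
    """Execute the full analysis; returns the run directory."""
    config.validate()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest = {
        "parameters": dataclasses.asdict(config),
        "seed": config.seed,
        "version": __version__,
        "complete": False,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    stage = "load_inputs"
    try:
        metadata, taxa_table, panels, transcripts = _load_inputs(config, indir)
        meta_groups = pd.Series(
            {m.sample_id: m.group for m in metadata}, name="group"
        )

        # -- bile acids --------------------------------------------------
        stage = "quantify"
        ba_summary = {}
        for comp, panel in panels.items():
            totals = total_bile_acids(panel)
            totals.to_frame("total").to_csv(outdir / f"ba_totals_{comp}.tsv", sep="\t")
            for by in ("conjugation", "origin", "sulfated"):
                class_summary(panel, by).to_csv(
                    outdir / f"ba_{by}_{comp}.tsv", sep="\t"
                )
            grp = meta_groups.reindex(totals.index)
            x = totals[grp == "berberine"]
            y = totals[grp == "control"]
            stat, p = compare_groups(x, y, "mann_whitney_exact")
            ba_summary[comp] = {
                "total_mean_control": float(y.mean()),
                "total_mean_berberine": float(x.mean()),
                "mann_whitney_U": stat,
                "p": p,
            }
        (outdir / "ba_summary.json").write_text(
            json.dumps(ba_summary, indent=2, sort_keys=True)
        )

        # -- diversity ---------------------------------------------------
        stage = "diversity"
        taxa_counts = taxa_table.values.T  # taxa x samples
        rare = rarefy(taxa_counts, config.rarefaction_depth, seed=config.seed)
        rare.to_csv(outdir / "rarefied_taxa.tsv", sep="\t")
        sh = rare.apply(lambda c: shannon(c.to_numpy()), axis=0)
        sh.to_frame("shannon").to_csv(outdir / "shannon.tsv", sep="\t")
        grp = meta_groups.reindex(rare.columns)
        stat_sh, p_sh = compare_groups(
            sh[grp == "berberine"], sh[grp == "control"], "mann_whitney_exact"
        )
        dm = bray_curtis_matrix(rare)
        dm.to_frame().to_csv(outdir / "bray_curtis.tsv", sep="\t")
        ords = nmds(dm, k=2, seed=config.seed)
        ords.coordinates.to_csv(outdir / "nmds.tsv", sep="\t")
        r_anosim, p_anosim = anosim(
            dm, grp.loc[dm.ids].to_numpy(), n_perm=config.anosim_perms, seed=config.seed
        )
        (outdir / "diversity.json").write_text(
            json.dumps(
                {
                    "anosim_R": r_anosim,
                    "anosim_p": p_anosim,
                    "n_perm": config.anosim_perms,
                    "nmds_stress": ords.stress,
                    "shannon_mw_p": p_sh,
                    "seed": config.seed,
                },
                indent=2,
                sort_keys=True,
            )
        )

        # -- differential expression -------------------------------------
        stage = "differential_expression"
        de_tables = {}
        for sp, table in transcripts.items():
            counts = table.values.T  # genes x samples
            de = de_analysis(
                counts,
                meta_groups.reindex(counts.columns),
                species=sp,
                method=config.de_method,
                seed=config.seed,
            )
            safe = sp.replace(" ", "_")
            de.to_csv(outdir / f"de_{safe}.tsv", sep="\t")
            selected = filter_de(de, config.lfc_min, config.de_p)
            selected.to_csv(outdir / f"de_selected_{safe}.tsv", sep="\t")
            de_tables[sp] = (de, selected)

        # -- per-group correlation networks ------------------------------
        stage = "correlation_network"
        # transcripts enter the combined table as TMM-normalised CPM,
        # taxa as relative abundances, bile acids as concentrations
        parts = []
        for sp, table in transcripts.items():
            counts = table.values.T
            log2cpm, _ = normalize_counts(counts)
            parts.append(FeatureTable((2.0**log2cpm).T, table.features))
        rel = taxa_table.values.div(taxa_table.values.sum(axis=1), axis=0)
        parts.append(FeatureTable(rel, taxa_table.features))
        parts += [p.to_feature_table() for p in panels.values()]
        combined = combine_features(parts).attach_metadata(metadata)
        networks = {}
        records = {}
        for group in ("control", "berberine"):
            rec = all_pairs(combined, group, method=config.corr_p_method)
            records[group] = rec
            write_edge_list(rec, outdir / f"correlations_{group}.tsv")
            g = build_network(rec, config.rho_min, config.p_max, combined.features)
            networks[group] = g
            write_graphml(g, outdir / f"network_{group}.graphml")
            write_sif(g, outdir / f"network_{group}.sif")

        # -- difference network ------------------------------------------
        stage = "difference_network"
        diffs = difference_table(
            records["control"],
            records["berberine"],
            method=config.diff_method,
            table=combined,
            seed=config.seed,
        )
        diffs.to_csv(outdir / "correlation_differences.tsv", sep="\t", index=False)
        gdiff = difference_network(
            records["control"],
            records["berberine"],
            alpha=config.diff_alpha,
            method=config.diff_method,
            table=combined,
            annotations=combined.features,
            seed=config.seed,
        )
        write_graphml(gdiff, outdir / "difference_network.graphml")
        write_sif(gdiff, outdir / "difference_network.sif")

        # -- topology report ---------------------------------------------
        stage = "topology"
        topo = {
            group: {
                k: v for k, v in topology_metrics(g).items() if k != "degree"
            }
            for group, g in networks.items()
        }
        topo["difference"] = {
            k: v for k, v in topology_metrics(gdiff).items() if k != "degree"
        }
        de_counts = {sp: int(len(sel)) for sp, (_, sel) in de_tables.items()}
        (outdir / "summary.json").write_text(
            json.dumps(
                {
                    "topology": topo,
                    "de_selected_per_species": de_counts,
                    "de_selected_total": int(sum(de_counts.values())),
                },
                indent=2,
                sort_keys=True,
            )
        )
    except Exception as exc:  # mark partial output, re-raise with stage
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        log.removeHandler(handler)
        handler.close()
        raise StageError(stage, exc) from exc
    manifest["complete"] = True
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.removeHandler(handler)
    return outdir


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run (markdown)."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    if not manifest.get("complete"):
        raise ValueError(f"run in {run_dir} is incomplete (failed stage: "
                         f"{manifest.get('failed_stage', 'unknown')})")
    summary = json.loads((run_dir / "summary.json").read_text())
    diversity = json.loads((run_dir / "diversity.json").read_text())
    ba = json.loads((run_dir / "ba_summary.json").read_text())
    lines = ["# bbrnet run report", ""]
    lines.append("## Bile acids")
    for comp, s in sorted(ba.items()):
        lines.append(
            f"- {comp}: total control {s['total_mean_control']:.3f}, "
            f"berberine {s['total_mean_berberine']:.3f} "
            f"(Mann-Whitney p = {s['p']:.4g})"
        )
    lines.append("")
    lines.append("## Community diversity")
    lines.append(
        f"- ANOSIM R = {diversity['anosim_R']:.3f}, p = {diversity['anosim_p']:.3g} "
        f"({diversity['n_perm']} permutations); NMDS stress = "
        f"{diversity['nmds_stress']:.3f}; Shannon Mann-Whitney p = "
        f"{diversity['shannon_mw_p']:.3g}"
    )
    lines.append("")
    lines.append("## Differential expression (|log2FC| > threshold, P < threshold)")
    for sp, n in sorted(summary["de_selected_per_species"].items()):
        lines.append(f"- {sp}: {n} genes")
    lines.append(f"- total: {summary['de_selected_total']} genes")
    lines.append("")
    lines.append("## Network topology")
    for name, t in sorted(summary["topology"].items()):
        lines.append(
            f"- {name}: {t['n_nodes']} nodes, {t['n_edges']} edges, "
            f"{t['n_components']} components, density {t['density']:.4f}, "
            f"{t['cross_type_edges']} cross-type edges"
        )
    text = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(text)
    return text
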