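"""Synthetic study generator with planted, recoverable truth.

Emulates the statistical structure of the gnotobiotic experiment the
pipeline analyses: two isolators (control / berberine), 6 mice each
(3 male, 3 female), a 7-member defined consortium profiled by 16S
counts (~53k reads per sample), per-species transcript counts (negative
binomial), and bile-acid panels for cecum, liver and serum. Berberine
raises the cecal bile-acid pool (control ~1.29, treated ~4.57 μmol/g
dry matter) while liver and serum pools stay group-invariant.

Planted truth:

* differentially expressed genes with known log2 fold change;
* group-specific gene-bile-acid rank correlations, induced by a shared
  per-sample Gaussian latent factor entering both the NB log-mean of the
  gene and the log-concentration of the analyte, only in the configured
  group. The coupling strength is calibrated numerically per pair so the
  large-sample Spearman rho hits the target.

Sex is carried in the metadata but has no simulated effect.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bile_acid_quant import AnalyteRecord, BileAcidPanel, write_analyte_registry, write_panel
from .core_tables import (
    B4PC2_SPECIES,
    FeatureAnnotation,
    FeatureTable,
    SampleMetadata,
    combine_features,
    write_metadata,
    write_table,
)
from .correlation_network import spearman_rho
from .differential_expression import normalize_counts

# -- default study conditions -------------------------------------------

#: reported read depth (mean +/- sd) for the 16S libraries
DEFAULT_READS_MEAN = 53_456.0
DEFAULT_READS_SD = 3_743.0

#: baseline relative abundances of the consortium members
DEFAULT_TAXON_PROPORTIONS = {
    "Bacteroides vulgatus": 0.35,
    "Bacteroides uniformis": 0.25,
    "Parabacteroides distasonis": 0.15,
    "Blautia producta": 0.10,
    "Bilophila wadsworthia": 0.06,
    "Clostridium hiranonis": 0.05,
    "Clostridium hylemonae": 0.04,
}

#: analyte registry: id -> (conjugation, origin, sulfated)
DEFAULT_ANALYTES = {
    "CA": ("unconjugated", "primary", False),
    "CDCA": ("unconjugated", "primary", False),
    "bMCA": ("unconjugated", "primary", False),
    "TCA": ("taurine", "primary", False),
    "TbMCA": ("taurine", "primary", False),
    "TCDCA": ("taurine", "primary", False),
    "GCA": ("glycine", "primary", False),
    "DCA": ("unconjugated", "secondary", False),
    "LCA": ("unconjugated", "secondary", False),
    "wMCA": ("unconjugated", "secondary", False),
    "UCA": ("unconjugated", "secondary", False),
    "7-oxo-CA": ("unconjugated", "secondary", False),
    "TDCA": ("taurine", "secondary", False),
    "TLCA": ("taurine", "secondary", False),
    "DCA-3S": ("unconjugated", "secondary", True),
}

#: control-group mean concentrations per compartment. Cecum sums to the
#: reported control total 1.29 μmol/g (deconjugation by the consortium is
#: nearly complete, DCA dominant); liver/serum are conjugated-primary
#: dominated and group-invariant.
DEFAULT_PANEL_MEANS = {
    "cecum": {
        "DCA": 0.55, "CA": 0.28, "bMCA": 0.12, "LCA": 0.10, "wMCA": 0.08,
        "7-oxo-CA": 0.04, "TCA": 0.03, "CDCA": 0.025, "DCA-3S": 0.025,
        "UCA": 0.02, "TDCA": 0.015, "TLCA": 0.005,
    },
    "liver": {
        "TCA": 0.15, "TbMCA": 0.08, "TDCA": 0.02, "CA": 0.02,
        "TCDCA": 0.015, "bMCA": 0.01, "TLCA": 0.005,
    },
    "serum": {
        "TCA": 1.8, "TbMCA": 1.2, "CA": 0.6, "DCA": 0.5, "bMCA": 0.4,
        "TDCA": 0.3, "GCA": 0.1, "DCA-3S": 0.1,
    },
}

_SHORT = {sp: sp.split()[-1] for sp in B4PC2_SPECIES}
_LONG = {v: k for k, v in _SHORT.items()}


@dataclass(frozen=True)
class PlantedDE:
    gene: str
    species: str
    log2fc: float


@dataclass(frozen=True)
class PlantedCorrelation:
    """A gene-analyte pair coupled through a latent factor in one group.

    ``feature_a`` is a combined-table transcript id (``wadsworthia|g0101``),
    ``feature_b`` a combined-table bile-acid id (``cecum|DCA``).
    """

    feature_a: str
    feature_b: str
    group: str
    target_rho: float
    beta: float | None = None  # calibrated coupling strength


def _default_planted_de(n_genes: int) -> list[PlantedDE]:
    species = [
        "Bilophila wadsworthia",
        "Bacteroides uniformis",
        "Bacteroides vulgatus",
        "Parabacteroides distasonis",
        "Clostridium hylemonae",
    ]
    out = []
    for si, sp in enumerate(species):
        for gi, lfc in enumerate([2.0, -2.0, 1.0, -1.0]):
            gene_no = si * 4 + gi + 1
            if gene_no <= n_genes:
                out.append(PlantedDE(f"g{gene_no:04d}", sp, lfc))
    return out


def _default_planted_corr(n_genes: int) -> list[PlantedCorrelation]:
    shorts = [
        "wadsworthia", "wadsworthia", "uniformis", "uniformis", "vulgatus",
        "vulgatus", "distasonis", "hylemonae", "hiranonis", "producta",
    ]
    analytes = ["DCA", "CA", "LCA", "bMCA", "TCA", "DCA-3S", "7-oxo-CA", "wMCA", "UCA", "TDCA"]
    # planted-correlation genes count down from the top of each genome,
    # skipping that genome's planted-DE block; pairs that would not fit in
    # a small genome are dropped
    de_block = {"wadsworthia": (1, 4), "uniformis": (5, 8), "vulgatus": (9, 12),
                "distasonis": (13, 16), "hylemonae": (17, 20)}
    counters = {sp: n_genes for sp in set(shorts)}
    out = []
    for sp, a in zip(shorts, analytes):
        g = counters[sp]
        lo, hi = de_block.get(sp, (0, -1))
        while g >= 1 and lo <= g <= hi:
            g -= 1
        if g < 1:
            continue
        counters[sp] = g - 1
        out.append(
            PlantedCorrelation(f"{sp}|g{g:04d}", f"cecum|{a}", "berberine", 0.9)
        )
    return out


@dataclass
class SimulationConfig:
    n_per_group: int = 6
    taxa: tuple[str, ...] = tuple(DEFAULT_TAXON_PROPORTIONS)
    taxon_proportions: dict = field(default_factory=lambda: dict(DEFAULT_TAXON_PROPORTIONS))
    reads_mean: float = DEFAULT_READS_MEAN
    reads_sd: float = DEFAULT_READS_SD
    n_genes_per_species: int = 150
    nb_dispersion: float = 0.1
    gene_mean_range: tuple[float, float] = (10.0, 2000.0)
    #: planted-correlation genes are drawn from the well-expressed end of
    #: the genome: a strong rank correlation (|rho| ~ 0.9) is physically
    #: unattainable for a gene whose counts are mostly zero, so the floor
    #: keeps the planted condition expressible under NB noise
    planted_corr_min_mean: float = 300.0
    library_sigma: float = 0.1
    taxon_sigma: float = 0.3
    planted_de: list[PlantedDE] | None = None
    panel_means: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PANEL_MEANS.items()})
    cecal_total_control: float = 1.29
    cecal_total_treatment: float = 4.57
    ba_shared_sigma_control: float = 0.08
    ba_shared_sigma_treatment: float = 0.30
    ba_analyte_sigma: float = 0.15
    planted_corr: list[PlantedCorrelation] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("need at least 2 mice per group")
        if self.planted_de is None:
            self.planted_de = _default_planted_de(self.n_genes_per_species)
        if self.planted_corr is None:
            self.planted_corr = _default_planted_corr(self.n_genes_per_species)
        for pc in self.planted_corr:
            if abs(pc.target_rho) >= 1:
                raise ValueError(f"|target_rho| must be < 1: {pc}")
        for comp, means in self.panel_means.items():
            for a, m in means.items():
                if m <= 0:
                    raise ValueError(f"{comp}/{a}: analyte mean must be > 0")
        total = sum(self.panel_means["cecum"].values())
        if abs(total - self.cecal_total_control) > 1e-9:
            raise ValueError(
                f"cecal analyte means sum to {total}, not cecal_total_control="
                f"{self.cecal_total_control}"
            )


@dataclass
class SyntheticTruth:
    planted_de: list[PlantedDE]
    planted_corr: list[PlantedCorrelation]
    latent_factors: pd.DataFrame  # samples x planted pairs

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_de": [dataclasses.asdict(p) for p in self.planted_de],
                "planted_corr": [dataclasses.asdict(p) for p in self.planted_corr],
                "latent_factors": self.latent_factors.round(10).to_dict(),
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SyntheticStudy:
    metadata: list[SampleMetadata]
    taxon_counts: pd.DataFrame  # taxa x samples
    transcripts: dict[str, pd.DataFrame]  # species -> genes x samples
    panels: dict[str, BileAcidPanel]
    truth: SyntheticTruth

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.metadata]


# -- coupling calibration ------------------------------------------------

_BETA_CACHE: dict[tuple, float] = {}


def _simulate_pair(
    beta: float,
    mu: float,
    dispersion: float,
    analyte_sigma: float,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n (gene count, analyte concentration) samples at coupling beta."""
    z = rng.normal(size=n)
    gene_mu = mu * np.exp(beta * z - beta**2 / 2)
    counts = _nb_draw(rng, gene_mu, dispersion)
    conc = np.exp(analyte_sigma * rng.normal(size=n) + beta * z - beta**2 / 2)
    return counts, conc


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def calibrate_beta(
    target_rho: float,
    mu: float,
    dispersion: float,
    analyte_sigma: float,
    n_large: int = 4000,
    tol: float = 0.01,
    beta_max: float = 3.0,
    seed: int = 20_170_523,
) -> float:
    """Monotone bisection of the coupling strength to hit a target Spearman rho.

    The empirical rho at a candidate beta is measured on a large common-
    random-number sample; rho is monotone in beta, so bisection converges.
    Raises if the target exceeds what the count noise allows at beta_max.
    """
    # the coupling needed depends on mu only through the count noise
    # ~ dispersion + 1/mu, so calibrate per log10-mu bucket (0.1 decades)
    bucket = round(float(np.log10(mu)), 1)
    mu = 10.0**bucket
    key = (round(target_rho, 4), bucket, dispersion, analyte_sigma, n_large)
    if key in _BETA_CACHE:
        return _BETA_CACHE[key]
    sign = 1.0 if target_rho >= 0 else -1.0
    tgt = abs(target_rho)
    if tgt < 1e-9:
        return 0.0

    def rho_at(beta: float) -> float:
        rng = np.random.default_rng(seed)
        c, a = _simulate_pair(beta, mu, dispersion, analyte_sigma, n_large, rng)
        return spearman_rho(c, a)

    # rho rises with beta until count noise (zeros under the lognormal
    # mean correction) takes over, so scan a grid for the first crossing
    # and refine locally rather than bisect blindly.
    grid = np.linspace(0.0, beta_max, 16)
    rhos = [0.0] + [rho_at(float(g)) for g in grid[1:]]
    crossing = next((i for i, r in enumerate(rhos) if r >= tgt), None)
    if crossing is None:
        raise ValueError(
            f"target rho {target_rho} unattainable under NB noise; "
            f"maximum achievable ~{sign * max(rhos):.3f}"
        )
    lo, hi = float(grid[crossing - 1]), float(grid[crossing])
    for _ in range(20):
        mid = (lo + hi) / 2
        r = rho_at(mid)
        if abs(r - tgt) < tol or hi - lo < 1e-3:
            lo = hi = mid
            break
        if r < tgt:
            lo = mid
        else:
            hi = mid
    beta = sign * (lo + hi) / 2
    _BETA_CACHE[key] = beta
    return beta


def empirical_rho(
    config: SimulationConfig,
    pair: PlantedCorrelation,
    group: str,
    n_large: int = 10_000,
) -> float:
    """Large-sample Spearman rho of a planted pair's coupling mechanism."""
    planted = {
        (p.feature_a, p.feature_b, p.group): p for p in config.planted_corr
    }
    if (pair.feature_a, pair.feature_b, pair.group) not in planted:
        raise ValueError("pair is not planted in this config")
    mu = _planted_gene_mu(config, pair)
    beta = pair.beta
    if beta is None:
        beta = calibrate_beta(
            pair.target_rho, mu, config.nb_dispersion, config.ba_analyte_sigma
        )
    if group != pair.group:
        beta = 0.0
    rng = np.random.default_rng(config.seed + 777)
    counts, conc = _simulate_pair(
        beta, mu, config.nb_dispersion, config.ba_analyte_sigma, n_large, rng
    )
    return spearman_rho(counts, conc)


def _planted_gene_mu(config: SimulationConfig, pair: PlantedCorrelation) -> float:
    """The gene's baseline NB mean, reproduced from the config seed."""
    mus = _gene_means(config)
    short, gene = pair.feature_a.split("|", 1)
    return float(mus[_LONG[short]][gene])


def _gene_means(config: SimulationConfig) -> dict[str, pd.Series]:
    """Deterministic per-species baseline gene means (log-uniform)."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_mean_range
    out = {}
    for sp in B4PC2_SPECIES:
        genes = [f"g{i + 1:04d}" for i in range(config.n_genes_per_species)]
        mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes_per_species))
        out[sp] = pd.Series(mu, index=genes)
    for pc in config.planted_corr:
        short, gene = pc.feature_a.split("|", 1)
        sp = _LONG.get(short)
        if sp is not None and gene in out[sp].index:
            out[sp][gene] = max(out[sp][gene], config.planted_corr_min_mean)
    return out


# -- the generator -------------------------------------------------------


def generate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Generate one complete synthetic study from the configuration.

    Deterministic given ``config.seed``: the same config yields byte-
    identical tables.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_per_group
    sexes = ["M" if i < (n + 1) // 2 else "F" for i in range(n)]
    metadata = [
        SampleMetadata(f"C{i + 1}", "control", sexes[i]) for i in range(n)
    ] + [SampleMetadata(f"B{i + 1}", "berberine", sexes[i]) for i in range(n)]
    sample_ids = [m.sample_id for m in metadata]
    group = np.array([m.group for m in metadata])

    # planted bookkeeping -------------------------------------------------
    mus = _gene_means(config)
    de_by_species: dict[str, dict[str, float]] = {}
    for p in config.planted_de:
        if p.species not in mus or p.gene not in mus[p.species].index:
            raise ValueError(f"planted DE gene not in genome: {p}")
        de_by_species.setdefault(p.species, {})[p.gene] = p.log2fc

    calibrated: list[PlantedCorrelation] = []
    latent = {}
    gene_coupling: dict[str, dict[str, tuple[float, np.ndarray]]] = {}
    analyte_coupling: dict[str, dict[str, tuple[float, np.ndarray]]] = {}
    for idx, pc in enumerate(config.planted_corr):
        short, gene = pc.feature_a.split("|", 1)
        comp, analyte = pc.feature_b.split("|", 1)
        if short not in _LONG or gene not in mus[_LONG[short]].index:
            raise ValueError(f"planted correlation gene not in genome: {pc}")
        if comp not in config.panel_means or analyte not in config.panel_means[comp]:
            raise ValueError(f"planted correlation analyte not in panel: {pc}")
        beta = pc.beta
        if beta is None:
            beta = calibrate_beta(
                pc.target_rho,
                _planted_gene_mu(config, pc),
                config.nb_dispersion,
                config.ba_analyte_sigma,
            )
        z = rng.normal(size=len(sample_ids))
        mask = (group == pc.group).astype(float)
        latent[f"pair{idx + 1}"] = z
        gene_coupling.setdefault(_LONG[short], {})[gene] = (beta, z * mask)
        analyte_coupling.setdefault(comp, {})[analyte] = (beta, z * mask)
        calibrated.append(dataclasses.replace(pc, beta=beta))

    # 16S taxon counts ----------------------------------------------------
    taxa = list(config.taxa)
    base = np.array([config.taxon_proportions[t] for t in taxa], dtype=float)
    base = base / base.sum()
    depths = np.maximum(
        rng.normal(config.reads_mean, config.reads_sd, size=len(sample_ids)), 1000.0
    ).astype(np.int64)
    taxon_counts = np.zeros((len(taxa), len(sample_ids)), dtype=np.int64)
    for j in range(len(sample_ids)):
        logit = np.log(base) + rng.normal(0, config.taxon_sigma, size=len(taxa))
        p = np.exp(logit)
        taxon_counts[:, j] = rng.multinomial(depths[j], p / p.sum())
    taxon_df = pd.DataFrame(taxon_counts, index=taxa, columns=sample_ids)

    # per-species transcript counts --------------------------------------
    treated = (group == "berberine").astype(float)
    transcripts = {}
    for sp in B4PC2_SPECIES:
        mu = mus[sp]
        lib = np.exp(rng.normal(0, config.library_sigma, size=len(sample_ids)))
        lfc = np.zeros(len(mu))
        for gene, val in de_by_species.get(sp, {}).items():
            lfc[mu.index.get_loc(gene)] = val
        logmean = (
            np.log(mu.to_numpy())[:, None]
            + np.log(lib)[None, :]
            + np.log(2.0) * lfc[:, None] * treated[None, :]
        )
        for gene, (beta, zmask) in gene_coupling.get(sp, {}).items():
            gi = mu.index.get_loc(gene)
            logmean[gi] += beta * zmask - beta**2 / 2 * (zmask != 0)
        counts = _nb_draw(rng, np.exp(logmean), config.nb_dispersion)
        transcripts[sp] = pd.DataFrame(counts, index=mu.index, columns=sample_ids)

    # bile-acid panels ----------------------------------------------------
    registry = {
        aid: AnalyteRecord(aid, *DEFAULT_ANALYTES[aid]) for aid in DEFAULT_ANALYTES
    }
    scale_treat = config.cecal_total_treatment / config.cecal_total_control
    panels = {}
    for comp, means in config.panel_means.items():
        analytes = [registry[a] for a in means]
        conc = np.zeros((len(sample_ids), len(means)))
        for j, m in enumerate(metadata):
            if comp == "cecum":
                ss = (
                    config.ba_shared_sigma_treatment
                    if m.group == "berberine"
                    else config.ba_shared_sigma_control
                )
                mult = scale_treat if m.group == "berberine" else 1.0
            else:
                ss = config.ba_analyte_sigma
                mult = 1.0
            shared = rng.normal(0, ss)
            eps = rng.normal(0, config.ba_analyte_sigma, size=len(means))
            sa = config.ba_analyte_sigma
            conc[j] = [
                means[a] * mult * np.exp(shared + eps[k] - (ss**2 + sa**2) / 2)
                for k, a in enumerate(means)
            ]
        df = pd.DataFrame(conc, index=sample_ids, columns=list(means))
        for analyte, (beta, zmask) in analyte_coupling.get(comp, {}).items():
            adj = np.exp(beta * zmask - beta**2 / 2 * (zmask != 0))
            df[analyte] = df[analyte].to_numpy() * adj
        panels[comp] = BileAcidPanel(df, comp, analytes)

    truth = SyntheticTruth(
        planted_de=list(config.planted_de),
        planted_corr=calibrated,
        latent_factors=pd.DataFrame(latent, index=sample_ids),
    )
    return SyntheticStudy(metadata, taxon_df, transcripts, panels, truth)


# -- assembling the combined feature table -------------------------------


def combined_feature_table(
    study: SyntheticStudy, transcript_scale: str = "cpm"
) -> FeatureTable:
    """Build the single combined feature table the correlation stages use.

    Transcripts enter as TMM-normalised CPM (Spearman only needs a
    common per-sample scale), taxa as relative abundances, bile acids as
    concentrations; feature ids get compartment/species prefixes.
    """
    parts = []
    for sp, counts in study.transcripts.items():
        if transcript_scale == "cpm":
            log2cpm, _ = normalize_counts(counts)
            mat = (2.0**log2cpm).T
        elif transcript_scale == "counts":
            mat = counts.T.astype(float)
        else:
            raise ValueError(f"unknown transcript_scale {transcript_scale!r}")
        feats = [FeatureAnnotation(g, "transcript", "cecum", sp) for g in counts.index]
        parts.append(FeatureTable(mat, feats))
    rel = study.taxon_counts / study.taxon_counts.sum(axis=0)
    parts.append(
        FeatureTable(
            rel.T, [FeatureAnnotation(t, "taxon", "cecum") for t in rel.index]
        )
    )
    for comp, panel in study.panels.items():
        parts.append(panel.to_feature_table())
    combined = combine_features(parts)
    combined.attach_metadata(study.metadata)
    return combined


# -- writers -------------------------------------------------------------


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write the study in the TSV dialects the readers consume + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_metadata(study.metadata, outdir / "metadata.tsv")
    tx = study.taxon_counts.copy()
    tx.index.name = "feature_id"
    tx.to_csv(outdir / "taxon_counts.tsv", sep="\t")
    for sp, counts in study.transcripts.items():
        short = _SHORT[sp]
        c = counts.copy()
        c.index.name = "feature_id"
        c.to_csv(outdir / f"transcripts_{short}.tsv", sep="\t")
    registry = [AnalyteRecord(aid, *DEFAULT_ANALYTES[aid]) for aid in DEFAULT_ANALYTES]
    write_analyte_registry(registry, outdir / "analyte_registry.tsv")
    for comp, panel in study.panels.items():
        write_panel(panel, outdir / f"bile_acids_{comp}.tsv")
    (outdir / "truth.json").write_text(study.truth.to_json())
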