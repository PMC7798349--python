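# Methods

This note documents the statistical models behind `bbrnet`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Study design assumptions

The pipeline assumes the two-isolator gnotobiotic design: two groups
(control, berberine) of six mice each (3 male / 3 female), with cecal
transcriptomes, cecal 16S profiles, and bile-acid panels from cecum,
liver and serum measured on the *same* mice. Cross-compartment
correlations at n = 6 are only meaningful if measurements are matched
by mouse, so matched-by-mouse is a hard requirement of the data model:
all tables entering `combine_features` must share one sample set, and
compartment/species are feature attributes, not observational units.

Missing values are not permitted; an analyte below detection is a 0.
Sex is carried in metadata but used by no stage (no sex effect is
simulated either; the design found none).

## Bile-acid quantitation

Single-point stable-isotope dilution with response factor 1:

    c = (A_analyte / A_IS) · n_IS / m,

with the deuterated standard (default 100 nmol spike) matched to the
analyte's conjugation class (d4-CA → unconjugated, d4-GCA → glyco-,
d4-TCA → tauro-), both overridable. Units are μmol/g dry matter for
cecum and liver and μmol/L for serum; panels never mix compartments,
and the serum normalisation basis is explicit in the panel rather than
guessed. Per-analyte response factors are accepted as optional
configuration but default to 1 — the method description gives no
calibration-curve detail, so pretending to one would be false
precision. Class summaries (conjugation / origin / sulfation) are plain
partitions of the row sum, so they conserve the total by construction.

Group comparisons use an exact Mann–Whitney test that enumerates all
C(n₁+n₂, n₁) group assignments (feasible through n = 16; the study has
12) with a tie-aware U and two-sided counting by distance from the null
mean, or Welch's t for larger or clearly metric data.

## Community diversity

* **Rarefaction**: multivariate-hypergeometric subsampling (without
  replacement) of each library to a fixed depth, default 23,900 reads;
  libraries below depth are dropped with a warning.
* **Shannon** H = −Σ pᵢ ln pᵢ over positive proportions (natural log by
  default; base 2 available — rank-based group comparisons are
  base-invariant).
* **Bray–Curtis** d = 1 − 2Σmin(xᵢ,yᵢ)/(Σx+Σy).
* **NMDS**: Kruskal stress-1 minimised by SMACOF iterations — isotonic
  regression of configuration distances on the dissimilarity order
  (primary/averaged handling of ties) followed by a Guttman transform —
  with 20 random restarts plus one classical-scaling start, tolerance
  1e-6, ≤ 300 iterations, k = 2 by default.
* **ANOSIM**: R = (r̄_between − r̄_within)/(M/2) on midranks of all
  M = n(n−1)/2 distances, so R ∈ [−1, 1] and fully separated clusters
  score exactly 1. When the number of distinct relabelings is small the
  null is enumerated exhaustively (p = #{R* ≥ R}/N, observed labeling
  included); otherwise 999 random permutations with the (+1)/(+1)
  convention.

## Differential expression

Each organism's transcriptome is normalised independently (counts come
from per-genome read assignment, so each species is its own
composition): TMM factors with 30% M-trim, 5% A-trim,
inverse-asymptotic-variance weights, reference library chosen by
upper-quartile proximity to the mean, re-centred to geometric mean 1;
expression is log₂ CPM with a library-scaled prior count of 0.5. The
log₂ fold change is the treatment-minus-control difference of group
means on that scale.

Significance comes from a permutation t test: the Welch t is
recomputed for every label split (all 924 at 6+6; Monte Carlo with the
(+1)/(+1) correction beyond ~20,000 splits), p = #{|t*| ≥ |t|}/N for
full enumeration. Constant genes get p = 1 and a flag. BH FDR is
reported per gene; the selection gate follows the figure convention —
raw P < 0.05 and |log₂FC| > 0.58 — with FDR carried alongside rather
than filtered on, because the per-gene FDR values in this design are
large and the original heat maps gate on raw P.

This stage deliberately re-implements the normalisation/test chain
rather than calling an external DE fitter; reproducing any specific
tool's p-values is a non-goal, threshold semantics are the contract.

## Correlation networks

Spearman ρ is the Pearson correlation of midranks (tie-aware; equal to
1 − 6Σd²/(n(n²−1)) without ties). For n ≤ 9 the two-sided p-value is
exact: all n! permutations of the observed vector are enumerated —
midranks permute with values, so the tie structure is preserved — and
p = #{|ρ*| ≥ |ρ|}/n!, floored at 1/n! (a reported p of 0 is impossible
under a finite permutation null). Tie-free pairs share one precomputed
null per n; tied pairs get their own enumeration. For n > 9 the t
approximation t = ρ√((n−2)/(1−ρ²)) is used.

Within each group, every feature pair of the combined table is tested
(constant features skipped and logged). Transcripts enter as
TMM-normalised CPM, taxa as relative abundances, bile acids as
concentrations — Spearman only needs a common per-sample scale. Edges
pass at |ρ| ≥ 0.7 and p ≤ 0.05; the threshold applies to |ρ| so
negative associations are retained with their sign as an edge
attribute. No multiple-testing correction is applied to network edges
by default (the filter is a per-pair raw-P gate); a BH-adjusted variant
is available by adjusting the records before `build_network`.

## Correlation-difference network

For each pair testable in both groups, two tests of Δρ are provided:

* **Fisher-z** (default): (z₁−z₂)/√(1/(n₁−3)+1/(n₂−3)) against the
  standard normal; ρ clamped to |ρ| ≤ 1−10⁻⁶. Fast and standard, but an
  approximation at n = 6.
* **Permutation**: sample-to-group assignment is re-drawn with each
  mouse's (x, y) pair intact, |Δρ| recomputed per split, all 924 splits
  enumerated at 6+6. Pairs with |ρ| = 1 in either group (possible at
  n = 6 with ties) route here automatically since atanh diverges.

Edges pass at p ≤ 0.01. All pairs testable in both groups are tested
by default, not just pairs passing the single-group filters.

**Known property — small-n conservatism.** At n = 6, Spearman ρ takes
only a few dozen distinct values, so |Δρ*| ties heavily across splits:
the smallest attainable permutation p is 2/924 (the mirror split always
ties), and the realised rejection rate at α = 0.01 under an
exchangeable null is ≈ 0.004–0.007, not 0.01. The test is exact in the
guarantee that matters (never anti-conservative) but cannot hit nominal
from below; even a near-perfect planted difference (ρ ≈ 0.95 vs 0)
typically lands at p ≈ 0.1. Detecting rewired pairs at P ≤ 0.01 with
six mice per group is, bluntly, underpowered — the difference network
should be read as a high-specificity shortlist.

## Synthetic data generator

The generator reproduces the statistical structure the pipeline
assumes, with planted truth for recovery testing:

* **Design**: 12 mice (6+6, 3M/3F per group), sample IDs C1–C6/B1–B6.
* **16S**: per-sample depth ~ Normal(53,456, 3,743²) (the reported
  sequencing depth), taxon composition = fixed consortium baseline
  (Bacteroides-dominated) perturbed by log-normal noise (σ = 0.3),
  counts multinomial at depth. Rarefaction depth 23,900 is always
  reachable.
* **Transcripts**: NB counts with gene means log-uniform on
  [10, 2000], dispersion 0.1, per-sample library factor log-normal
  (σ = 0.1). Planted DE genes multiply the treated mean by 2^log₂FC
  (defaults: four genes in each of five species at log₂FC ±1, ±2).
* **Bile acids**: log-normal around control means that sum to exactly
  1.29 μmol/g in cecum (DCA-dominant, deconjugation nearly complete;
  liver and serum conjugated-primary-dominated at 0.30 μmol/g and
  5.0 μmol/L — plausible magnitudes chosen once, since only the cecal
  totals are pinned by the design). Treatment multiplies every cecal
  mean by 4.57/1.29 and leaves liver/serum untouched. A shared
  per-sample factor sets the total's CV (control σ = 0.08, treated
  σ = 0.30, matching the reported total SDs) on top of per-analyte
  noise (σ = 0.15); all log-normals are mean-corrected so expectations
  hit the configured means exactly.
* **Planted correlations**: each planted gene–analyte pair shares a
  per-sample Gaussian latent factor entering the NB log-mean and the
  log-concentration *only in the configured group*; the coupling
  strength β is calibrated by monotone search so the large-sample
  Spearman ρ hits the target (±0.01 at n = 4000, verified at
  n = 10,000 by `empirical_rho`). A latent factor was chosen over a
  copula on observed values because it respects count noise at n = 6.
  Planted genes get a baseline-mean floor (default 300) — a rank
  correlation of 0.9 is unattainable for a gene whose counts are mostly
  zeros (the NB ceiling at mean 10, dispersion 0.1 is ρ ≈ 0.88), so the
  floor keeps the planted condition expressible.

What the generator does **not** emulate: sequencing error and chimeras,
OTU-calling artefacts, compositional coupling between transcripts and
taxa, inter-analyte correlation structure beyond the shared total,
batch effects, and any sex effect. Passing recovery tests therefore
demonstrates the pipeline's statistical behaviour under the design's
noise model, not robustness to real-data pathologies upstream of the
count/concentration tables.

## Numerical conventions

* Exact permutation p-values from full enumeration are #{as extreme}/N
  with the observed arrangement included (never 0); Monte Carlo
  p-values use (r+1)/(N+1).
* Extremeness comparisons use a 1e-12 absolute tolerance so float
  noise cannot drop true ties.
* Constant vectors: Spearman ρ is undefined → records skipped and
  flagged; within a permuted split of the difference test the
  replicate's ρ is 0 with a flag; constant genes get p = 1.
* Sample order is canonicalised (sorted by ID) in every table, and all
  randomness flows from explicit seeds, so same-seed runs are
  byte-identical.

## Problem sizes in the checks

The acceptance measurements use 200 random vectors for the Spearman
oracle, 30 matrices plus 200 null replicates for ANOSIM, 5,000 pairs
for difference-test calibration, 2,000 genes for DE calibration, and 50
simulated studies of ~230 features for planted-network recovery —
sizes chosen so each guarantee is measured with useful precision while
the whole suite stays a few-minute run on one core.

## Known limitations

* The exact Spearman p is limited to n ≤ 9 (factorial enumeration);
  the t approximation takes over beyond that.
* The difference network at n = 6+6 is conservative (see above); its
  recall of genuinely rewired pairs at P ≤ 0.01 is low by construction.
* A per-group network built from ~20k feature pairs at a per-pair raw
  P < 0.05 gate necessarily contains hundreds of chance edges; the
  smallest achievable exact p at n = 6 (2/720) rules out
  family-wise-tight per-pair thresholds. Networks are hypothesis
  generators, not significance statements.
* NMDS is a local optimiser; restarts make the stress reported the best
  of 21 starts, not a certified global minimum.
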