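# bbrnet

Multi-omic correlation and correlation-difference network analysis for a
defined gut bacterial consortium under berberine (BBR) treatment.

## The problem

Berberine is a plant alkaloid that lowers blood cholesterol by driving
bile-acid excretion into the large intestine. In gnotobiotic mice
colonised with a seven-member, bile-acid-metabolising consortium
(*Bacteroides uniformis*, *B. vulgatus*, *Parabacteroides distasonis*,
*Bilophila wadsworthia*, *Clostridium hylemonae*, *C. hiranonis*,
*Blautia producta*), BBR raises the cecal bile-acid pool several-fold
while community composition barely moves. The interesting biology is in
the *interactions*: which bacterial transcripts track which bile acids,
and which of those relationships are rewired by treatment.

`bbrnet` implements that analysis end to end, starting from count and
concentration tables:

1. **Bile-acid quantitation** — stable-isotope-dilution arithmetic
   (analyte/IS peak-area ratio × IS amount, per gram dry matter or per
   litre) and compositional summaries by conjugation, origin
   (primary/secondary) and sulfation.
2. **Community diversity** — rarefaction without replacement (default
   23,900 reads), Shannon index with exact Mann–Whitney comparison,
   Bray–Curtis dissimilarity, non-metric multidimensional scaling
   (Kruskal stress-1) and ANOSIM with permutation p-values. All owned
   implementations.
3. **Differential expression** — per-species TMM normalisation, log₂
   fold changes, a permutation *t* test (all C(12,6) = 924 label splits
   enumerated at the 6+6 design), BH FDR, and the heat-map gate
   |log₂FC| > 0.58, P < 0.05.
4. **Correlation networks** — all-pairs Spearman ρ over the combined
   transcript × bile-acid × taxon feature table, per treatment group.
   At the study's n = 6 the two-sided p-value is an *exact* permutation
   p over all 6! = 720 rank permutations, preserving tie structure.
   Edges pass at |ρ| ≥ 0.7 and p ≤ 0.05; export to edge-list TSV,
   GraphML and Cytoscape SIF.
5. **Correlation-difference network** — feature pairs whose correlation
   changed between treatments at P ≤ 0.01, tested either by the
   two-sample Fisher-z statistic
   (z₁ − z₂)/√(1/(n₁−3) + 1/(n₂−3)), z = atanh ρ, or by an exact
   label-permutation test that re-splits mice into groups (all 924
   splits enumerated).
6. **Synthetic study generator** — negative-binomial transcriptomes,
   multinomial 16S profiles (~53k reads/sample) and log-normal
   bile-acid panels that reproduce the study design (2 × 6 mice, 3M/3F;
   cecal totals 1.29 vs 4.57 μmol/g) with *planted* differential
   expression and planted group-specific gene–bile-acid correlations,
   so every stage is testable against known truth.

## Worked example

```python
import bbrnet as b

study = b.generate_study(b.SimulationConfig(seed=42, n_genes_per_species=40))
b.write_study(study, "study_input")

cfg = b.RunConfig(
    transcript_tables={sp: f"transcripts_{sp.split()[-1]}.tsv" for sp in b.B4PC2_SPECIES},
    bile_acid_tables={c: f"bile_acids_{c}.tsv" for c in ("cecum", "liver", "serum")},
    seed=7,
)
run_dir = b.run_pipeline(cfg, "study_input", "run")
print(b.report(run_dir))
```

prints

```
# bbrnet run report

## Bile acids
- cecum: total control 1.279, berberine 4.040 (Mann-Whitney p = 0.002165)
- liver: total control 0.317, berberine 0.339 (Mann-Whitney p = 0.6991)
- serum: total control 5.249, berberine 4.868 (Mann-Whitney p = 1)

## Community diversity
- ANOSIM R = -0.017, p = 0.468 (999 permutations); NMDS stress = 0.067; Shannon Mann-Whitney p = 0.394

## Differential expression (|log2FC| > threshold, P < threshold)
- Bacteroides uniformis: 4 genes
- Bacteroides vulgatus: 4 genes
- Bilophila wadsworthia: 4 genes
- Blautia producta: 2 genes
- Clostridium hiranonis: 0 genes
- Clostridium hylemonae: 4 genes
- Parabacteroides distasonis: 4 genes
- total: 22 genes

## Network topology
- berberine: 314 nodes, 1637 edges, 1 components, density 0.0333, 327 cross-type edges
- control: 314 nodes, 1654 edges, 1 components, density 0.0337, 312 cross-type edges
- difference: 308 nodes, 571 edges, 2 components, density 0.0121, 122 cross-type edges
```

Reading the output: the cecal bile-acid pool rises roughly three-fold
under treatment while liver and serum pools do not move (exactly the
planted design); community diversity shows no group separation (ANOSIM
R ≈ 0); the planted differentially expressed genes are recovered per
species (plus a few raw-p false positives, as expected when filtering
at P < 0.05 without FDR); and the per-group networks and the
correlation-difference network summarise how transcript–bile-acid
coupling changes with treatment.

The same stages are available as a CLI
(`bbrnet simulate|quantify|diversity|de|network|diffnet|run|report`).

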