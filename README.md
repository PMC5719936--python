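# emtdyn

Comparative gene co-expression network analysis of epithelial-to-mesenchymal
transition (EMT) time courses, for systems biologists who want to go from two
cell-line RNA-seq time series and a reference TF→target network to (1) a
cross-dataset *EMT-dynamic* gene signature, (2) candidate transcription-factor
regulators of each temporal expression program, and (3) a correlation-based
pseudotemporal staging of bulk tumor cohorts ("personalized EMT period", PEP)
with survival stratification.

## The analysis

Given a gene × stage log-expression matrix $X$ for one cell line:

1. **Co-expression network.** Edge weights are Pearson correlations $r_{ij}$
   of time-course profiles, soft-thresholded into an adjacency
   $a_{ij} = |r_{ij}|^\beta$ (unsigned) or $a_{ij} = ((1+r_{ij})/2)^\beta$
   (signed), with $\beta$ chosen as the smallest power whose connectivity
   distribution achieves a scale-free fit $R^2 > 0.8$ (or fixed by config).
2. **Modules and eigengenes.** The topological overlap measure
   $\mathrm{TOM}_{ij} = (\sum_u a_{iu}a_{uj} + a_{ij}) / (\min(k_i,k_j) + 1 - a_{ij})$
   feeds average-linkage hierarchical clustering of $1-\mathrm{TOM}$; a
   constant-height cut (plus a kME membership pruning step) yields modules of
   a minimum size, each summarized by its *eigengene* — the first principal
   component of the standardized member profiles, sign-oriented toward the
   modular mean.
3. **EMT-dynamic signature.** Modules whose eigengene correlates with at
   least one seed EMT gene at $r > 0.9$ are *EMT modules*; the top-50 genes
   by module membership ($\mathrm{kME}_{gm} = r(x_g, e_m)$) of every EMT
   module form a per-dataset candidate set, and genes in both datasets'
   candidate sets are the EMT-dynamic signature.
4. **Regulators and hubs.** A TF regulates a module if its reference targets
   are over-represented among module genes (hypergeometric $p < 0.05$),
   classified positive/negative by eigengene correlation at $|r| > 0.7$;
   retained TFs' mutual reference edges form a TF–TF network scored by
   Kleinberg HITS hub centrality (max-normalized to 1).
5. **PEP staging and survival.** Each cohort sample is assigned the
   time-course stage whose signature-gene profile maximizes the Pearson
   correlation with the sample's expression; pooled PEP clusters with more
   than 10 patients are compared by Kaplan–Meier curves, the k-sample
   log-rank test, and Cox proportional-hazards ratios against the earliest
   (0–8 h) cluster.

A synthetic-data generator plants all of this structure — four canonical
temporal archetypes in both orientations, module-targeted TFs plus uniform
decoys, and patients that are noisy copies of stage profiles with
stage-dependent exponential hazards — so every claim above is testable
without any external download.

## Worked example

`examples/staging_and_survival.py` simulates the default study (8 planted
modules × 120 genes + 240 background genes, 500 patients) and stages the
cohort:

```
staged 500 patients over 960 signature genes; exact stage recovery = 100.0%

cluster sizes:
cluster
h0-8      306
h16-24     99
h168       48
h72        47

mean silhouette in signature space: 0.389 vs all-gene space: 0.363

log-rank over 4 PEP clusters: chi2 = 70.61 (df 3), p = 3.16e-15
hazard ratios vs the h0-8 reference cluster:
 group    hr  ci_low  ci_high  pvalue
h16-24 1.750   1.335    2.293     0.0
  h168 3.538   2.463    5.082     0.0
   h72 2.631   1.846    3.748     0.0
```

Every patient is assigned its true simulated stage; the fitted hazard ratios
(1.75, 2.63, 3.54) recover the planted per-stage log hazard ratios
(0.3, 0.7, 1.1 → HR 1.35, 2.01, 3.00 at stage level; cluster pooling mixes
reference-hazard stages into later bins, shifting the estimates upward), and
later EMT periods carry worse survival. The other example scripts
(`module_detection.py`, `signature_extraction.py`, `regulators_and_hubs.py`)
walk through module recovery (ARI ≈ 0.96 vs the planted partition),
signature extraction (≈99% recall, 0% background contamination), and TF
inference (100% planted-TF recall) the same way.

There is also a thin CLI mirroring the library:

```bash
emtdyn simulate --seed 0 --outdir study/
emtdyn all --config pipeline.yaml --outdir run/
```

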