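# Methods

This note documents the models, numerical choices and known limitations of
`emtdyn`, in the spirit of the model-documentation pages of simulation and
statistics packages.

## The synthetic study

The generator (`emtdyn.simulate`) emulates a two-cell-line EMT induction
experiment plus a downstream bulk cohort. It is the package's study design:
its defaults define the conditions under which every recovery claim in the
test suite and `scripts/acceptance.py` is made.

### Temporal archetypes

Module expression follows four canonical temporal archetypes, modelled as
piecewise-linear functions of `log2(hours + 1)` with knots at 0, 2, 8, 16,
24, 72 and 168 h:

1. high early, down-regulated after 8 h (the cell-cycle-like pattern),
2. transient up-regulation between 8 and 16 h, decaying late,
3. up-regulation from 72 h after an early dip,
4. up-regulation only after 168 h.

Each archetype also exists sign-flipped, so the default study plants eight
distinct module profiles (`archetype_ids = (1, 2, 3, 4, -1, -2, -3, -4)`),
mirroring the empirical split between down-regulated (cell cycle, metabolic)
and up-regulated (immune) temporal programs. Two constraints shaped the knot
values, and both were verified numerically before they were frozen:

- **Mutual separability.** Pairwise |Pearson r| among the eight signed
  profiles stays ≤ 0.53 on both default stage grids (10 stages at
  0–168 h; 8 stages at 0–96 h). With only smooth monotone shapes this is
  impossible — any two monotone profiles on ≤ 10 points correlate at
  |r| > 0.8 — hence the transient/rebound character of the archetypes.
- **Stage identifiability.** Every linear segment has nonzero slope, so no
  two stage columns of the expected-expression matrix are collinear
  (adjacent-stage correlation ≤ 0.87). This is what makes *exact* stage
  recovery from noisy patient profiles possible; with flat early segments,
  the 0–8 h stages would be mutually indistinguishable in principle.

Profiles are standardized to unit SD per grid, so `noise_sd` (default 0.3)
and `patient_noise_sd` (default 0.5) are expressed relative to unit signal.
Hours beyond the last knot extrapolate flat (the 8-stage grid ends at 96 h).

### Study conditions (defaults)

- **Module recovery study** (`default_config`): 8 modules × 120 genes +
  240 background genes (1200 total), noise SD 0.3, minimum module size 30 —
  a desk-scale stand-in for the ~18k-gene, minimum-size-100 setting of real
  transcriptomes.
- **Signature study** (`signature_config`): module size 50 matches the
  top-50 membership rule so every planted dynamic gene is eligible for
  selection; 200 background genes.
- **Staging study** (`staging_config`): 8 × 30 signature genes inside 1000
  unstructured genes, 150 patients — a small planted signature inside a
  large background, as a few hundred signature genes sit inside ~18k
  measured genes.
- **Seed EMT genes**: 3 member genes per module (24 total), playing the role
  of a previously known EMT signature list.
- **Regulatory network**: one planted TF per module (a member gene, so its
  expression tracks the module), drawing 30 targets from its module; decoy
  TFs (background genes) draw targets uniformly; independent background
  edges at rate 0.01.
- **Cohort**: each patient is a uniformly drawn stage column plus Gaussian
  noise, shifted by +5 log2 units and exponentiated (`2**(5+x)`) to an
  FPKM-like scale, so `log2(FPKM + 1) ≈ 5 + x` and the log/raw distinction
  stays testable. Survival is exponential with hazard
  `0.02/month × exp(loghr[stage])`, per-stage log-HRs
  (0,0,0,0,0,0, 0.3, 0.3, 0.7, 1.1) — later EMT periods carry higher
  mortality — with uniform censoring on [0, 120] months.

### What the generator does *not* emulate

No read-level sequencing noise, library-size or batch effects, no
mesenchymal-to-epithelial reversal, no replicate structure (one profile per
time point, as in the source time courses), no tumor-purity or covariate
structure in the cohort, and linear (archetype + Gaussian) gene behavior
only. Passing tests therefore demonstrate that the pipeline's machinery
recovers planted linear co-expression structure at realistic noise — not
that it is robust to the full failure modes of real RNA-seq.

## Network construction and module detection

- **Network mode.** `adjacency` defaults to unsigned (`|r|^β`), the
  conventional default. The synthetic pipeline and all benchmarks use the
  **signed** mode: because planted modules come in anti-correlated pairs, an
  unsigned network merges each pair into one cluster by construction. Real
  analyses choosing between modes face exactly this trade-off; both are one
  config switch.
- **Soft power.** `pick_soft_power` bins connectivities into 10 equal-width
  bins, drops empty bins, and scores `R²` of `log10 p(k)` against
  `log10 mean(k)` per bin. The chosen power is the smallest candidate with
  fit strictly above the 0.8 target; if none passes, the best-fitting power
  is used and the report carries a `fallback` flag. Small planted networks
  rarely look scale-free, so the pipeline fixes β = 6 by default
  (`soft_power: 6`), the customary unsigned-network default; set
  `soft_power: null` to select by fit.
- **Tree cut.** Average-linkage clustering of `1 − TOM`, cut at a constant
  height chosen from a quantile grid (0.02…0.98) of the merge heights by
  maximizing, in order: the number of clusters ≥ `min_size`, the number of
  genes in such clusters, and (tie-break) the lower height. A constant-height
  cut alone cannot tell "module plus absorbed background" from "module":
  on planted data every completing cut also sweeps in unstructured genes.
- **kME pruning.** Therefore `detect_modules(..., expr=X)` refines the cut:
  each provisional module's eigengene is computed and members whose
  membership falls below the one-sided 99% null quantile of a Pearson
  correlation at the grid's stage count (r ≈ 0.79 at 10 stages, ≈ 0.84 at 8)
  are released; modules that drop below `min_size` dissolve. This is the
  standard membership-cleanup step of weighted correlation network practice.
  On the default study it lifts ARI against the planted partition from
  ≈ 0.72 (best achievable by any constant-height cut) to ≈ 0.95.
- **Determinism.** Genes are processed in lexicographic ID order, so the
  partition is invariant (equivariant) under row permutations; module labels
  are "M1, M2, …" by decreasing size with lexicographic tie-break.
- **Eigengenes** are the first right-singular vector of the standardized
  member × stage block (unit L2 norm), sign-oriented so the correlation with
  the modular mean profile is nonnegative; the explained-variance fraction
  is `s₁²/Σs²`. Single-gene modules degenerate to the gene's standardized
  profile and are flagged.

## Signature extraction

- EMT-module flagging uses the **signed** correlation `r > 0.9` (strict),
  matching the printed threshold; an `absolute=True` switch exists because
  anti-correlated seed genes are biologically plausible.
- "Top 50 by membership" ranks by signed kME descending (ties by gene ID);
  modules smaller than k contribute all members. The cross-dataset
  signature is the intersection of the two candidate sets; a gene selected
  through several modules keeps its best-kME provenance per dataset.
- Temporal grouping (the PCA + K-means view of a gene set) clusters on the
  first two principal components with 10 K-means restarts at a fixed seed,
  mirroring how such groupings are plotted.

## Regulator inference

- The hypergeometric universe defaults to the intersection of expression
  genes and reference-network targets; an explicit `universe=` override
  exists. The tail `P(X ≥ overlap)` is scipy's exact survival function.
- Raw p-values are thresholded at 0.05 (strict) with no multiplicity
  correction by default, as in the original analysis; `bh_correct=True`
  applies Benjamini–Hochberg per module.
- TFs absent from the expression matrix are retained but `unclassified`
  (their r is NaN), rather than dropped.
- HITS hub scores come from power iteration with alternating hub/authority
  normalization (tolerance 1e-10, ≤ 10000 iterations), then max-normalized
  to 1; an edgeless network yields all-zero scores with a warning.

## Staging and survival

- PEP correlations are computed on `log2(FPKM + 1)` for the cohort against
  the log-scale stage profiles; `log_transform=False` reproduces the
  raw-scale behavior (and makes the assignment exactly invariant to
  per-sample positive affine transforms). Ties go to the earliest stage —
  conservative with respect to progression. Zero-variance samples are left
  unassigned with a warning.
- PEP hours pool into named clusters (h0-8, h16-24, h72, h168, >h500); the
  bin edges are configurable.
- Silhouettes are computed with Euclidean distances in each gene set's
  (log) expression space — the comparison is between gene sets, so adding a
  PC-space projection would introduce a second arbitrary choice; singleton
  clusters score 0 (scikit-learn convention).
- Cluster filtering keeps groups with **strictly** more than `min_n = 10`
  samples, always retaining the nonempty reference cluster. Kaplan–Meier,
  log-rank and Cox fits are lifelines; Cox uses Breslow tie handling (the
  only handling lifelines implements) with group indicators against the
  h0-8 reference. Monotone-likelihood fits (a group with no events) are
  retried with a tiny ridge penalty and flagged `converged=False`.

## Benchmark sizes and tolerances

`scripts/acceptance.py` (and the mirror tests in
`tests/test_acceptance.py`) use: the default 1200-gene study for module
recovery, eigengene fidelity (|r| ≥ 0.95 against the planted profile), TF
recall (5 replicate studies, 40 planted TFs) and PEP recovery
(500 patients); 100 null replicates × 16 decoys × 8 modules for the decoy
false-positive rate; exhaustive combinatorial enumeration (universes ≤ 15)
for the hypergeometric tail at 1e-12; 50 random 8-node digraphs against a
dense eigendecomposition at 1e-8 for HITS; 100 staging-study replicates for
the silhouette contrast; and 100 replicates of n = 500 (Cox, true HR 2) plus
500 replicates of n = 200 (log-rank null at α = 0.05) for survival
calibration. The whole script completes in well under a minute on one CPU.

## Known limitations

- The constant-height cut plus kME pruning is deterministic and
  dependency-light but is not the dynamic hybrid tree cut; very unequal
  module sizes or nested module structure may be split differently.
- No merging of similar modules by eigengene correlation, no block-wise
  decomposition for very large gene sets (the dense TOM is O(n²) memory),
  and no consensus-module variant across datasets.
- The scale-free fit on small simulated networks is noisy; β is therefore
  fixed in the pipeline presets rather than fitted.
- Survival modelling is single-covariate (PEP cluster); no age/stage
  adjustment or time-varying effects.
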