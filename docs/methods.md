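# Methods

This note documents the statistical models, numerical choices and known
limitations of the `secretome` package, in the spirit of a model/methods
appendix.

## Data model

The unit of analysis is a `SecretomeMatrix`: a cells × 32 matrix of
nonnegative mean fluorescence intensities (MFI, arbitrary units) from the
single-cell antibody-barcode secretome assay, with per-cell metadata
(sample, patient, tissue PB/BM, timepoint baseline/post-treatment, subset
CD4/CD8) and per-sample metadata (response CR/NR, age, history flags).
Tissue, timepoint and subset are constant within a sample; a "sample" is
one patient × tissue × timepoint × subset measurement.

The 32-plex panel is partitioned into five functional groups of sizes
4/6/6/9/7 (chemoattractive, effector, inflammatory, stimulatory,
regulatory). The chemoattractive token "IP-20" follows the panel
definition used by the assay vendor's grouping; "IP-10", the conventional
chemokine name, is registered as an alias of the same analyte. Cytokine
name matching is case-, hyphen- and Greek-letter-insensitive because the
literature mixes spellings freely.

## Secretion calling and PSI

A cytokine is called secreted when its MFI **strictly exceeds** a
per-cytokine threshold; the default threshold is 0, i.e. any nonzero
signal counts. This matches the synthetic generator's exact-zero
background; for instrument data with a continuous background, per-cytokine
gates are supplied explicitly. A cell is *polyfunctional* if it has ≥ 2
positive calls across the **full panel** (not per group; a per-group
variant exists behind a flag for sensitivity analysis).

For each sample × subset and group *g* (the five groups, "overall", and
optionally each single cytokine):

* `polyfunctional_pct` = 100 · #polyfunctional / #cells (0–100 scale —
  "percentage" is taken literally; only relative comparisons matter),
* `mfi_sum` = Σ over polyfunctional cells of the MFI of their positive
  cytokines restricted to *g* (a *sum*, not an average; an averaging flag
  exists),
* `psi` = `polyfunctional_pct` × `mfi_sum`.

Because polyfunctionality is decided panel-wide and only the MFI sum is
group-restricted, the five group-level `mfi_sum` values add up exactly to
the overall one. PSI is linear in MFI: scaling all MFI of polyfunctional
cells by c scales PSI by c. Samples with zero cells yield missing (not
zero) PSI. The vectorized implementation is checked against an
independent nested-loop reference on a thousand random instances; the two
agree to float summation order.

## Pseudobulk statistics

PB-vs-BM and pre-vs-post contrasts are paired within patient and use the
two-sided paired t test (signed-rank variant behind a flag); CR-vs-NR is
unpaired and uses the two-sided rank-sum test. BH adjustment is applied
within each subset's family; raw p and q are both reported, with
significance read at 0.05 on either scale. All-zero paired differences
are reported as degenerate with p = 1 rather than NaN. Fewer than 3
complete pairs (or 2 samples per arm) flags the row untestable instead of
dropping it. Age associations use Spearman correlation per tissue ×
subset stratum with BH within stratum.

## Single-cell pipeline

* **Outlier filter** — a cell is removed when any single channel exceeds
  3,000 MFI (strict inequality). The alternative reading — total MFI over
  channels — is available as `outlier_mode="total"`; the per-channel rule
  is the default because extreme single measurements are what skew
  downstream statistics. The filter is idempotent.
* **Normalization** — per cell, `x → ln(1 + x / cell_total · 10,000)`, the
  standard global-scaling log transform; zero-total cells map to zero rows
  and are flagged.
* **Variable features** — cytokines ranked by variance standardized
  against a quadratic log-variance-on-log-mean trend across the 32
  features. With only 32 channels the default keeps all of them; the
  ranking exists for workflow fidelity.
* **PCA** — feature-centered, full SVD, 10 components by default, with the
  sign convention that each component's largest-|loading| entry is
  positive (bit-reproducibility).
* **Batch correction** — an iterative soft-clustering correction in PC
  space. Each round: (a) soft k-means assignment computed in *batch-
  centered* coordinates (each batch's global mean removed), so a residual
  global shift cannot be absorbed into cluster boundaries; a diversity
  penalty `((E+1)/(O+1))^θ` on observed vs expected batch mass shapes the
  centroids toward spanning batches; (b) per cluster × batch, the
  responsibility-weighted mean offset from the cluster mean is removed
  from that batch's cells — but only when the offset is statistically
  distinguishable from within-cluster sampling noise (a χ² gate at
  d + 2√(2d)); offsets are further shrunk by `tot/(tot+ridge)`. The
  penalty is deliberately kept out of the offset estimates: penalized
  weights drag batches apart when their population mix genuinely differs.
  Defaults: K = min(10, n/200) clusters, θ = 1, σ = 0.1, ridge = 10, up to
  50 rounds. Contracts verified by tests: identity on a single batch; a
  planted constant shift is removed to < 10% (when the shift is well above
  the noise-floor the gate protects); kNN batch-mixing entropy does not
  decrease under a pure shift; and populations shared across batches are
  not blurred (ARI degradation < 0.1). Known limitations: batches that are
  fully confounded with biology (a population present in only one batch)
  are left uncorrected rather than merged, and shifts below the sampling
  noise floor are deliberately not removed. An escape hatch accepts
  externally corrected PCs.
* **kNN graph** — undirected union of k-nearest-neighbor lists (k = 20 by
  default), Euclidean metric in corrected PC space, ties broken by cell
  index.
* **Clustering** — Leiden (RB-configuration) at resolution 0.8 by default,
  labels relabeled by decreasing size, deterministic given seed. The
  `sweep_resolution` utility reports cluster counts and plain modularity
  over a grid, since the appropriate resolution depends on the granularity
  of interest: benchmarks that target coarse planted structure use
  0.1–0.4. Clustering always consumes corrected PCs, never UMAP
  coordinates; UMAP is exported for visualization only.

## Neighborhood differential abundance

Index cells are a uniform 10% sample of cells, each refined to the member
of its kNN closest to the neighborhood mean (a density-seeking step) and
deduplicated; a neighborhood is the refined index cell plus its k nearest
neighbors, so neighborhoods partially overlap. Counts are member cells
per sample.

Each neighborhood's counts follow a negative-binomial log-linear model
`log μ = β₀ + β₁·[post] + log N_s` with N_s the sample's total cells. For
this saturated binary design the MLE of β₁ is the closed-form log rate
ratio `log[(T_post/M_post)/(T_base/M_base)]` of group totals over group
offsets, which is what the package computes (natural-log scale).
Dispersion is estimated per neighborhood by the method of moments — the
Pearson scale φ = X²/(S−2) at the fitted means, the NB variance inflation
1 + α·μ — and shrunk halfway toward the cross-neighborhood median. The
Wald statistic `β̂₁ / sqrt(φ·(1/T_base + 1/T_post))` is referred to the
standard normal. Neighborhoods empty in one arm get a 0.5 continuity
correction on both group totals and a `zero_group` flag; all-zero rows
are untestable. Under permutations of sample timepoint labels the test's
type-I error at α = 0.05 sits within [0.03, 0.07] at the benchmark scale
(12 samples × 1,000 cells, k = 75).

Spatial FDR is weighted Benjamini–Hochberg with weights equal to the
reciprocal kth-NN distance of each index cell; with equal distances it is
exactly BH (verified against `statsmodels`); zero distances have their
weight capped at the largest finite weight.

Exclusivity (baseline-only / post-only / mixed) depends only on membership
and member timepoints — never on the tests; the summary reports
percentages of all neighborhoods (one decimal, two decimals below 1%) and,
separately, counts restricted to spatial FDR < 0.1. Differential
abundance is run within each subset (CD4, CD8) separately. The design
contains timepoint only, mirroring the framework's standard use; a patient
covariate is out of scope of the count model (its effect is absorbed by
the dispersion).

## De novo functional groups

Cluster signatures are per-cluster means of normalized values. For
display and clustering the matrix is standardized per cytokine with the
denominator floored at 0.2 × the pooled within-cluster SD: with few
clusters the raw between-cluster SD is a standard error and would amplify
noise for cytokines that do not differ. Ward linkage on Euclidean
distance gives the cluster and cytokine dendrograms; the cluster
dendrogram is cut into k groups (defaults 5 for CD4, 6 for CD8; the
benchmark constructions use 3, matching their planted populations). A
group's signature cytokines must pass two conditions: group-mean
standardized score > 0.5 **and** group-mean excess over the cross-cluster
mean > 4 standard errors of that group mean — the second condition keeps
sampling noise out of signatures when clusters are small. Group labels
are ordered by the smallest member cluster id, making the assignment
invariant to cluster relabeling.

Per-sample group proportions (rows summing to 1) are compared CR-vs-NR
per tissue at baseline with the two-sided rank-sum test; the paired
signed-rank variant exists for matched designs (the literature's "paired
Wilcoxon rank-sum" phrasing is internally ambiguous, so both are exposed
and the unpaired rank-sum is the default for independent response arms).

## Synthetic data generator

Each cell draws a latent subpopulation from condition-specific weights
(tissue × timepoint × response overrides on a base weight, renormalized
per condition). Per cytokine, the cell secretes with the population's
probability; a secreting channel draws
`exp(N(log_mu + patient_offset + age_term, log_sigma))` MFI; a
nonsecreting channel is exactly zero by default (a half-normal background
is opt-in), so threshold-0 secretion calling is unambiguous. Defaults,
chosen once as a realistic regime for this assay: median secreting MFI
~60 a.u. (signature cytokines 150–300), log-SD 0.5, patient batch effects
additive on the log-MFI scale with SD 0.25 shared across a patient's
samples, 1% of cells given one uniformly drawn channel in (3,000, 8,000]
to exercise the outlier gate (the honest-secretion scale keeps natural
exceedance of 3,000 negligible, so the planted flag is exact truth), and
an age effect of −0.02 per year on IL2 log-mean centered at 68 years.
The default cohort mirrors the study arms: 21 patients (10 CR / 11 NR),
baseline PB/BM from 20/16 patients, post-treatment PB/BM from 10/6,
~1,000 cells per sample and subset, ages ~N(68, 10) clipped to 47–90.

What the generator does **not** emulate: correlated cosecretion beyond
population structure (within a population, channels are independent given
secretion), MFI saturation and spectral spillover, cell-size effects, or
longitudinal within-patient drift beyond the planted shifts. Passing the
recovery benchmarks therefore shows the algorithms recover the structure
this model plants — not that real instrument data satisfy the model.

## Benchmark constructions and problem sizes

The planted-truth benchmarks (`secretome.benchmarks`) fix their own
conditions: three subpopulations with disjoint signatures (the
response-associated IFNγ/TNFα/MIP-1β/IL8 "quad", a cytotoxic and a
regulatory-like population) at background secretion 0.2 so the per-cell
geometry is high-dimensional. Clustering recovery uses deterministic
signatures (probability 1, no background, no batch noise) — a clean
planted partition. DA recovery plants a 4-fold post-treatment shift on
the quad population (base weight 0.1; the realized abundance log
fold-change after mixture renormalization is ln(4/1.3) ≈ 1.12) across 6 +
6 samples of 1,000 cells, k = 75, neighborhood proportion 0.1, without
batch noise; the null calibration keeps the default patient noise on.
Response power uses 16 patients (8 CR / 8 NR), PB and BM at baseline, 150
cells per sample, CR BM quad weight 0.30 vs NR 0.10, over 100 seeds.
These sizes keep the whole benchmark suite within a few minutes on one
CPU while leaving comfortable statistical margins.

## Reproducibility

Every stochastic step takes an explicit seed (generator, PCA, batch
correction, Leiden, UMAP, neighborhood sampling); the full pipeline is
bit-reproducible for a fixed seed and cohort. The CLI writes a manifest
JSON with the effective configuration (every default echoed) and SHA-256
checksums of all artifacts.
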