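# Methods

This note documents the models, estimators, and design choices behind
`pmsig`, and what the synthetic cohorts do and do not establish about real
data.

## The synthetic cohort generator

The generator (`pmsig.simulate`) emulates the data structure of a paired
tumor/normal TMT proteomics study of gastric cancer with PM annotation.

**Abundance model.** Per-protein baseline log2 intensity is drawn from
Normal(25, 3); each sample adds independent Normal(0, `tech_noise_sd`)
noise; raw abundance is `2^x`. Mass-spectrometry reporter intensities are
well described as log-normal, and the wide (SD 3) baseline spread
reproduces the dynamic range that makes fraction-of-total values span
several orders of magnitude. Real TMT data additionally carry batch/plex
structure and intensity-dependent missingness; neither is modeled, so
passing tests say nothing about batch robustness.

**Planted structure.** `n_dep` proteins (default 300 of 2000) receive a
tumor shift of Uniform(0.8, 2.0) log2 units with a random sign. A
`module_size` subset (default 20) is the PM module: it is planted as a
coherent co-regulated block — shifted up in tumors and further up in PM
tumors by `δ = target_snr · 2 · tech_noise_sd`, which makes the
per-protein population signal-to-noise `|μ_PM − μ_PMfree| / (σ_PM +
σ_PMfree)` equal `target_snr` (default 1.2). Coherence is a modeling
decision, not a convenience: a "module" in phenotype-profile clustering is
by definition a set of proteins moving together, and with independent
random signs no centroid method could (or should) recover the set as one
module. The empirical SNR measured from generated cohorts runs slightly
above target (≈1.31 at target 1.2) because of Jensen-type bias in the
ratio of sample moments at n = 14 vs 6; tests use the 0.15 tolerance this
implies.

**Survival.** The planted risk score is a weighted sum of standardized
module expression in tumors, with weights |w| ~ Uniform(0.5, 1.5) signed
to match each protein's PM direction, so PM-like tumors score high and the
score carries the planted hazard. (With independently random weight signs
the PM-classification axis and the survival axis would be unrelated, and a
score fit to classify PM could not correlate with the planted hazard —
contradicting what a PM risk score is meant to be.) Event times are
exponential with rate `λ0 · exp(β · score)` (`λ0` set for a 24-month
baseline median, `β` default 0.7 per standardized unit); censoring is
Uniform(0, c) with c tuned by bisection to a target censored fraction
(default 0.3). Age and ordinal stage are annotated covariates; the
synchronous/metachronous label is annotation only.

**External cohort.** An ACRG-like transcriptome cohort (default n = 300,
balanced PM labels) reproduces the module effects with the same sign,
shrunk by `external_attenuation` (default 0.6), on unit-variance noise —
the attenuation encodes imperfect mRNA–protein correlation. Non-module
genes are pure noise, which is the idealization that makes the external
filter's type-I behavior testable (~α/2 of null genes survive the
sign-plus-significance rule).

## Preprocessing

FOT normalization divides each sample column by its total; the filter
keeps proteins with ≥ 2 unique peptides and max-over-samples FOT > 1e-5
("quantified above threshold somewhere" — the permissive reading; a
per-sample reading would discard proteins absent from a single channel).
Zeros are floored at 1e-8 (configurable) before log2. Z-scoring is
per-sample by default, treating "each subject's SD" as the spread of that
sample's log2 profile; a per-protein axis is available
(`log2_zscore(..., axis="protein")`) for users who read the convention the
other way. The state tag on `ExpressionMatrix` enforces the order
raw → fot → filter → log2z.

## Differential calling

**SAM-style test (a).** The moderated statistic is `d = r / (s + s0)`
with `r` the paired mean difference (or unpaired group difference) and `s`
its standard error. `s0` is chosen Tusher-style from the percentile grid
{0, 5, …, 95} of {s}, minimizing the coefficient of variation of the MAD
of `d` across five s-quantile bins. The null is built from label
permutations — sign flips for the paired design — enumerated exhaustively
whenever the number of distinct permutations is at most `n_perm` (e.g.,
all 20 splits of 3 vs 3, all 2^n sign vectors for n ≤ 6 pairs at the
default `n_perm` = 100). The identity permutation is computed through the
same vectorized path as the rest and supplies the observed statistics, so
ties at observed cutoffs count consistently; |d| is compared at 1e-12
resolution for the same reason (mirror permutations are exact-arithmetic
ties).

The FDR at a cutoff Δ is `π0 · E_false(Δ) / observed(Δ)` with
`E_false = (Σ_perm tail counts + 1) / (n_perm + 1)` — the pooled
permutation tail with a pseudocount, so a permutation tail is never
estimated as exactly zero. This choice is load-bearing in both directions:
a zero-able estimate (e.g., the median permuted count alone) lets a single
extreme observed statistic be called at "FDR 0" under a global null,
inflating the null false-call rate to ~10% of cohorts, while a median+1
rule cannot resolve FDR below 1/observed and silences true call sets
smaller than 20 at the 0.05 level (exactly the size of the second-level
PM comparison here). The pooled estimator measured: global-null mean false
discovery proportion 0.02 over 50 cohorts, and 15–19 of the 17–19 planted
module proteins recalled at group level at SNR 1.5. Δ is the smallest
cutoff meeting the nominal FDR (no calls if none does); q-values are the
running minimum of the FDR curve; calls additionally require linear fold
change ≥ 1.5 or ≤ 1/1.5. π0 defaults to 1 (conservative); an IQR-based
estimate from the permuted statistics is available. Fold changes are
computed from the unstandardized log2 FOT matrix when supplied
(`fc_matrix`): per-sample z-scoring divides log2 differences by the
cohort-wide spread (~3 here), which would make a 1.5-fold threshold in
z-units mean a ~3.4-fold change in abundance.

**Per-pair test (b).** Within each pair, the per-protein log2 fold
changes are fit by a location–scale t: location = median, scale =
1.4826·MAD, df fixed at 4 (full ML fit by flag); `p = 2·(1 −
F_t(|lfc − loc| / scale))`. A single pair can only flag proteins in the
far tail of its own fold-change distribution (|lfc| ≳ 2.8 robust SDs at
df 4), so cross-pair aggregation demands directional consistency rather
than ubiquitous significance: a protein is called if it is significant in
at least one pair, all significant pairs agree in sign, and that direction
holds in at least `min_frac` (default 0.5) of all pairs. Requiring
significance itself in half the pairs would restrict calls to ~4-fold
effects and reduce the intersection with (a) to a handful of proteins.

**Intersection and second level.** Final DEPs are the intersection of (a)
and (b) over a shared universe. The PM-vs-PM-free comparison (unpaired
SAM on tumors restricted to the DEP set, same thresholds) is computed and
reported; the module-clustering stage takes the first-level DEP set as
input, so low second-level power at n = 14 vs 6 cannot starve module
discovery.

## Module selection

Each DEP is represented by its phenotype profile (mean z in PM tumors,
PM-free tumors, paired normals). Profiles are centered per protein —
sample-wise z-scores still carry absolute abundance, which otherwise
dominates the partition — and PCA-whitened, which balances the dominant
tumor-vs-normal axis against the weaker PM-contrast axis; without
whitening, k-means splits the PM module along effect magnitude in ~3 of 10
cohorts. KMeans (k = 8 default, `n_init` = 10, seeded) partitions the
profiles; modules are ranked by mean member SNR (ε = 1e-8 in the
denominator; median aggregation by flag) and the argmax module is the PM
module, ties to the smaller index. The external filter keeps module
proteins with a Welch p < 0.05 in the external cohort and an external
mean-difference sign matching the proteomic direction; proteins absent
externally are dropped with a warning. The candidate pool entering panel
selection is the filtered module (the pool definition is configurable in
principle; this default is the narrowest faithful reading).

## Panel selection

`cv_auc` scores a protein subset by mean out-of-fold AUC under stratified,
seeded 5-fold cross-validation; backends are gradient-boosted trees
(shallow: 60 rounds, depth 2, η 0.3, single-threaded, seeded) and an
L2 logistic model that is cheap and fully deterministic. AUC itself is the
rank-based Mann–Whitney form with half-credit ties. Combination
enumeration over sizes [3, 10] is exhaustive while the total count fits
the budget, otherwise that many distinct combinations are sampled
uniformly (sizes weighted by their counts) with the mode recorded. The
workflow default budget is 2000 sampled combinations with the logistic
backend — a desk-scale setting chosen so a full ten-seed recovery study
runs in minutes; literal exhaustive enumeration over a 32-protein pool
(2^32 subsets) is not a computation anyone runs, and the budgeted scheme
is the reconstruction. Ranking ties break toward smaller, lexicographically
earlier combinations; protein-frequency ties break by marginal univariate
AUC, then lexicographically. `best_panel_size` ranks the pool by full-fit
tree importance (marginal-AUC fallback) and scores nested prefixes,
preferring smaller sizes on ties.

## Risk model and strata

`fit_weights` fits an xgboost linear booster (coordinate-descent updater
for determinism, L2 λ = 1, 100 rounds, η 0.5) to PM status on the panel
and extracts the coefficients; the intercept is dropped because the score
is used only for ranking and quartile cuts. The PM risk score is the
weighted sum of panel z-scores. `stratify` uses linear-interpolation 25th
and 75th percentiles of the evaluation cohort's own scores (per-cohort
cutpoints; a fixed-cutpoint mode exists), with boundary ties assigned to
the extreme strata; all-equal scores raise an error rather than returning
a degenerate split. Stratification is rank-based and therefore invariant
under strictly increasing score transforms.

## Survival evaluation

`km_estimate` implements the product-limit estimator with Greenwood
variance; `logrank_test` delegates to lifelines' multivariate log-rank.
`cox_fit` maximizes the partial likelihood by Newton iterations with step
halving (Breslow ties by default, Efron by flag), converging on gradient
norm < 1e-8 or a likelihood plateau at floating-point resolution; Wald CIs
and p-values come from the inverse information. Monotone likelihood
(perfect separation) raises an explicit error, detected both by divergence
during iteration and by an implausibly large coefficient (>10 in absolute
value ≈ HR 22000) at the optimum. `validate_signature` scores and
stratifies a cohort, excludes the moderate stratum, and compares high vs
low by log-rank and by univariate and covariate-adjusted Cox with
high-vs-low as the exposure — the extreme-quartile design. At the internal
cohort's size (5 vs 5 subjects) the adjusted fit can legitimately separate;
the workflow records that outcome in the survival report instead of
halting.

## Problem sizes and determinism

Defaults mirror the cohort the pipeline targets: 2000 proteins, 14 PM + 6
PM-free subjects (20 tumor/normal pairs), a 20-protein module at SNR 1.2,
100 permutations, an external cohort of 300. A full `run-all` takes ~25 s
on one CPU; the test suite (including ten full pipeline runs and 50
global-null cohorts) ~7 minutes. Every stochastic step — simulation,
permutations, folds, sampling, boosters, k-means — is seeded from the one
pipeline seed, and two runs with the same config are byte-identical
(verified by hashing every artifact).

## Known limitations

- The generator has no batch structure, no intensity-dependent
  missingness, and Gaussian technical noise only; recovery results bound
  what the pipeline can do under its own assumptions, not under real TMT
  artifacts.
- The module-clustering stage is a faithful-to-contract reimplementation
  of phenotype-differential module selection (profiles → centroid clusters
  → SNR ranking), not a port of any particular published clustering tool.
- With 14 vs 6 tumors the classifier CV-AUC saturates at 1.0 on synthetic
  modules; it is a selection metric here, not an estimate of real-world
  discrimination.
- Panels selected from synthetic cohorts are generator identifiers. The
  clinically derived ten-protein PM signature this pipeline's design
  targets comprises DUOXA2, ITGA7, LIMS1, MSRB3, PLCB1, RAB6B, SEMA3C,
  SMTN, TADA1 and TBC1D14; reproducing its fitted weights would require
  the original (non-public) cohort.
- External validations at clinical scale (independent proteomic cohorts
  with adjusted high-vs-low hazard ratios in the 3–7 range) require
  non-public data; the survival machinery is instead validated by
  parameter recovery and calibration on simulated cohorts.
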