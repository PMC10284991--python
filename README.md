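# pmsig

Proteomic signature discovery for peritoneal-metastasis (PM) risk in
gastric cancer, as a tested, reusable pipeline.

PM is the most frequent — and most lethal — spread pattern of gastric
cancer, and deciding who should receive prophylactic intraperitoneal
treatment needs a risk stratification that clinicopathological staging
alone does not provide. `pmsig` implements a complete discovery pipeline
that goes from a TMT-style tumor/normal protein abundance matrix to a
weighted protein panel, a per-patient **PM risk score**, and a survival
validation of the resulting risk strata. Because cohorts of paired primary
tumors with PM annotation are rarely public, the package ships a
first-class synthetic cohort generator that plants every structure the
analysis assumes, so each stage is testable end to end with no download.

## The method

1. **Preprocessing.** Raw intensities are normalized to fraction of total
   (FOT): `FOT[p, s] = raw[p, s] / Σ_p raw[p, s]`. Proteins need at least
   2 unique peptides and a maximum FOT above 1e-5 to be retained; retained
   values are floored, log2-transformed, and z-scored within each sample.
2. **Differential proteins, two ways.** (a) A SAM-style moderated
   statistic `d_p = r_p / (s_p + s0)` (paired mean difference over its
   standard error, plus a fudge constant chosen from the percentile grid of
   `{s_p}`), with a permutation null (sign flips of the paired differences,
   exhaustive when feasible) and a symmetric cutoff Δ chosen as the
   smallest value whose estimated FDR `π0 · E[false calls] / observed
   calls` is below 0.05, plus a 1.5-fold-change requirement. (b) A per-pair
   test: within each tumor/normal pair, per-protein log2 fold changes are
   fit by a location–scale t distribution and two-tail p-values computed;
   calls need a consistent direction across pairs. The final DEP set is the
   intersection of (a) and (b).
3. **PM module.** DEPs are clustered (k-means on phenotype-conditioned
   profiles: mean z in PM tumors, PM-free tumors, normals) and each module
   is scored by its mean signal-to-noise ratio
   `SNR_p = |μ_PM − μ_PMfree| / (σ_PM + σ_PMfree)`; the top-SNR module is
   the PM-associated module. An external transcriptome cohort filters the
   module for sign-concordant, significant group effects.
4. **Panel selection.** Protein combinations from the filtered module are
   scored by mean AUC under stratified five-fold cross-validation
   (gradient-boosted trees or a logistic backend), exhaustively up to a
   budget and by uniform sampling beyond it. Each protein's frequency in
   the top 500 combinations is ranked and the ten most frequent proteins
   form the panel.
5. **Risk score and strata.** A gradient-boosted linear classifier fit on
   the panel supplies per-protein weights `w_j`; the PM risk score of a
   subject is `Σ_j w_j · z_js`. Cohorts are split into high (top quartile),
   moderate, and low (bottom quartile) risk.
6. **Survival validation.** Kaplan–Meier curves with Greenwood variance,
   the log-rank test, and univariate plus covariate-adjusted Cox
   proportional-hazards regression (Breslow ties, Newton solver, Wald CIs)
   compare the high and low strata.

## Worked example

Run the whole pipeline on a simulated cohort (2000 proteins; 14 PM and 6
PM-free subjects, one tumor/normal pair each; a planted 20-protein PM
module at signal-to-noise 1.2):

```bash
pmsig run-all --out demo --seed 0
```

or equivalently from Python:

```python
from pmsig import PipelineConfig, run_all
report = run_all(PipelineConfig(seed=0, outdir="demo"))
```

The final report (`demo/report.json`) for seed 0:

```json
{
 "n_proteins_quantified": 2000,
 "n_proteins_retained": 1699,
 "n_deps_tumor_normal": 208,
 "n_deps_pm_group": 19,
 "module_size": 14,
 "module_snr": 1.4498394760758202,
 "pool_size": 14,
 "panel": ["P0055", "P0078", "P0163", "P0478", "P0813",
           "P1150", "P1375", "P1409", "P1497", "P1563"],
 "enumeration_mode": "sampled",
 "panel_cv_auc": 1.0,
 "risk_group_sizes": {"high": 5, "moderate": 10, "low": 5},
 "logrank_p_high_vs_low": 0.0196697362919745,
 "panel_planted_overlap": 10
}
```

Reading it: 1699 of 2000 proteins survive the peptide/FOT filters; the
intersected differential tests call 208 tumor-vs-normal DEPs (300 were
planted; the rest fall below the fold-change or FDR bar); 19 of them also
differ between PM and PM-free tumors; the top-SNR module contains 14
proteins, all of which survive external filtering; the selected 10-protein
panel consists entirely of planted module members
(`panel_planted_overlap: 10`); the fitted risk score separates the cohort
into 5 high / 10 moderate / 5 low subjects, and the high stratum has
significantly worse overall survival than the low stratum (log-rank
p ≈ 0.02). Every artifact (expression tables, DEP table, module JSON,
panel selection, model weights, scores, survival report, provenance with
input checksums) is written to `demo/`.

Each stage is also exposed on its own (`pmsig simulate`, `pmsig
preprocess`, `pmsig survival`, …) and as plain library functions
(`sam_test`, `pairfc_test`, `cluster_deps`, `cv_auc`, `fit_weights`,
`cox_fit`, …).

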