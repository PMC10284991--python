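"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a paired tumor/normal TMT-style proteomic cohort of
gastric-cancer patients, a subset of whom develop peritoneal metastasis (PM):

* per-protein baseline log2 intensities ~ Normal(25, 3), log-normal raw
  abundances — the standard shape of MS reporter intensities;
* a planted set of tumor-vs-normal differential proteins (DEPs), shifted in
  tumors by a random-sign log2 effect;
* a planted PM-associated module (a subset of the DEPs) additionally shifted
  between PM and PM-free tumors so that the per-protein signal-to-noise
  |mu_PM - mu_PMfree| / (sigma_PM + sigma_PMfree) hits a target value;
* overall survival driven by a planted weighted module score through a
  proportional-hazards (exponential baseline) model with uniform censoring;
* an external transcriptome cohort (ACRG-like) in which the module effects
  reappear with the same sign but attenuated magnitude, used downstream for
  concordance filtering.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the offending field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design the pipeline targets: 14 PM and 6
    PM-free subjects, one tumor/normal pair each, ~2000 quantified proteins,
    300 planted tumor-vs-normal DEPs containing a 20-protein PM module.
    """

    n_proteins: int = 2000
    n_pm_subjects: int = 14
    n_pmfree_subjects: int = 6
    n_dep: int = 300
    module_size: int = 20
    target_snr: float = 1.2
    tumor_effect_low: float = 0.8   # log2 units
    tumor_effect_high: float = 2.0  # log2 units
    tech_noise_sd: float = 0.5      # log2 units
    beta_hazard: float = 0.7        # log-hazard per unit standardized score
    censor_frac: float = 0.3
    external_n: int = 300
    external_attenuation: float = 0.6
    external_noise_sd: float = 1.0
    low_peptide_frac: float = 0.05  # fraction of proteins given <2 unique peptides
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_proteins", "n_pm_subjects", "n_pmfree_subjects", "external_n"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("n_dep", "module_size"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if not (self.module_size <= self.n_dep <= self.n_proteins):
            raise ConfigError(
                "module_size <= n_dep <= n_proteins violated: "
                f"module_size={self.module_size}, n_dep={self.n_dep}, n_proteins={self.n_proteins}"
            )
        if self.target_snr <= 0:
            raise ConfigError(f"target_snr must be > 0, got {self.target_snr}")
        if not (0 <= self.censor_frac < 1):
            raise ConfigError(f"censor_frac must be in [0, 1), got {self.censor_frac}")
        if self.tumor_effect_low > self.tumor_effect_high:
            raise ConfigError("tumor_effect_low exceeds tumor_effect_high")
        if self.tech_noise_sd <= 0:
            raise ConfigError(f"tech_noise_sd must be > 0, got {self.tech_noise_sd}")
        if not (0 <= self.external_attenuation <= 1):
            raise ConfigError(
                f"external_attenuation must be in [0, 1], got {self.external_attenuation}"
            )
        if not (0 <= self.low_peptide_frac < 1):
            raise ConfigError(f"low_peptide_frac must be in [0, 1), got {self.low_peptide_frac}")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort, for recovery checks."""

    dep_ids: set
    module_ids: set
    true_weights: dict          # module protein -> hazard weight
    beta_hazard: float
    group_labels: dict          # subject -> "PM" | "PM-free"
    pm_effects: dict = field(default_factory=dict)   # module protein -> signed log2 PM shift
    true_score: dict = field(default_factory=dict)   # subject -> standardized planted score

    def __post_init__(self) -> None:
        if not self.module_ids <= self.dep_ids:
            raise ValueError("module_ids must be a subset of dep_ids")
        if set(self.true_weights) != set(self.module_ids):
            raise ValueError("true_weights must be keyed exactly by module_ids")

    def to_json(self, path) -> None:
        obj = {
            "dep_ids": sorted(self.dep_ids),
            "module_ids": sorted(self.module_ids),
            "true_weights": {k: self.true_weights[k] for k in sorted(self.true_weights)},
            "beta_hazard": self.beta_hazard,
            "group_labels": {k: self.group_labels[k] for k in sorted(self.group_labels)},
            "pm_effects": {k: self.pm_effects[k] for k in sorted(self.pm_effects)},
            "true_score": {k: self.true_score[k] for k in sorted(self.true_score)},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            dep_ids=set(obj["dep_ids"]),
            module_ids=set(obj["module_ids"]),
            true_weights=obj["true_weights"],
            beta_hazard=obj["beta_hazard"],
            group_labels=obj["group_labels"],
            pm_effects=obj.get("pm_effects", {}),
            true_score=obj.get("true_score", {}),
        )


def _tune_censor_scale(times: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting an expected censored fraction.

    P(C < T_i) with C ~ U(0, c) is E[min(T_i, c)] / c, decreasing in c;
    solved by bisection on the empirical event times.
    """
    if target <= 0:
        return float(times.max() * 1e6)

    def frac(c: float) -> float:
        return float(np.mean(np.minimum(times, c) / c))

    lo, hi = 1e-6, float(times.max()) * 2
    while frac(hi) > target:
        hi *= 2
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(config: SimulationConfig):
    """Generate one paired tumor/normal cohort.

    Returns
    -------
    (ExpressionMatrix, pandas.DataFrame, pandas.DataFrame, GroundTruth)
        Raw abundance matrix (one T and one N column per subject), the
        unique-peptide count table, the sample annotation table and the
        planted ground truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_proteins
    n_pm, n_free = config.n_pm_subjects, config.n_pmfree_subjects
    n_sub = n_pm + n_free

    width = max(4, len(str(p)))
    proteins = np.array([f"P{i + 1:0{width}d}" for i in range(p)])
    subjects = [f"PM{i + 1:02d}" for i in range(n_pm)] + [f"NF{i + 1:02d}" for i in range(n_free)]
    pm_status = np.array([1] * n_pm + [0] * n_free)

    # planted structure; the module is a coherent co-regulated block --
    # shifted up in tumors and further up in PM tumors -- as a module found
    # by phenotype-profile clustering is by construction
    dep_idx = rng.choice(p, size=config.n_dep, replace=False)
    module_idx = rng.choice(dep_idx, size=config.module_size, replace=False) if config.module_size else np.array([], dtype=int)
    dep_sign = rng.choice([-1.0, 1.0], size=config.n_dep)
    dep_sign[np.isin(dep_idx, module_idx)] = 1.0
    dep_effect = rng.uniform(config.tumor_effect_low, config.tumor_effect_high, size=config.n_dep)
    module_sign = np.ones(config.module_size)
    # within-group per-sample spread is tech_noise_sd, so this shift yields the target SNR
    delta = config.target_snr * 2.0 * config.tech_noise_sd

    base = rng.normal(25.0, 3.0, size=p)

    # log2 intensities: [tumors | normals], subject order fixed
    x_t = base[:, None] + rng.normal(0.0, config.tech_noise_sd, size=(p, n_sub))
    x_n = base[:, None] + rng.normal(0.0, config.tech_noise_sd, size=(p, n_sub))
    x_t[dep_idx, :] += (dep_sign * dep_effect)[:, None]
    if config.module_size:
        x_t[np.ix_(module_idx, np.where(pm_status == 1)[0])] += (module_sign * delta)[:, None]

    # planted hazard score from module expression in tumors, weights signed
    # with the PM direction so PM-like tumors score high
    weights_abs = rng.uniform(0.5, 1.5, size=config.module_size)
    weights = weights_abs * module_sign
    if config.module_size:
        zt = x_t[module_idx, :]
        zt = (zt - zt.mean(axis=1, keepdims=True)) / zt.std(axis=1, ddof=1, keepdims=True)
        raw_score = weights @ zt
    else:
        raw_score = np.zeros(n_sub)
    sd = raw_score.std(ddof=1)
    score = (raw_score - raw_score.mean()) / sd if sd > 0 else np.zeros(n_sub)

    lam0 = np.log(2.0) / 24.0  # baseline median OS 24 months at score 0
    t_event = rng.exponential(1.0 / (lam0 * np.exp(config.beta_hazard * score)))
    if config.censor_frac > 0:
        c = _tune_censor_scale(t_event, config.censor_frac)
        t_cens = rng.uniform(0.0, c, size=n_sub)
    else:
        t_cens = np.full(n_sub, np.inf)
    os_months = np.maximum(np.minimum(t_event, t_cens), 0.01)
    os_event = (t_event <= t_cens).astype(int)

    # clinical annotation; Syn/Meta split is a label only, unused by models
    n_syn = int(round(n_pm * 13 / 19))
    group = np.array(
        ["Syn"] * n_syn + ["Meta"] * (n_pm - n_syn) + ["Con"] * n_free
    )
    age = rng.integers(40, 80, size=n_sub)
    stage = np.where(pm_status == 1, rng.choice([3, 4], size=n_sub), rng.choice([2, 3], size=n_sub))

    sample_rows = []
    for i, sub in enumerate(subjects):
        for tissue in ("T", "N"):
            sample_rows.append(
                {
                    "sample_id": f"{sub}_{tissue}",
                    "subject_id": sub,
                    "tissue": tissue,
                    "group": group[i],
                    "pm_status": int(pm_status[i]),
                    "os_months": round(float(os_months[i]), 4),
                    "os_event": int(os_event[i]),
                    "age": int(age[i]),
                    "stage": int(stage[i]),
                }
            )
    samples = pd.DataFrame(sample_rows)

    cols = [f"{s}_T" for s in subjects] + [f"{s}_N" for s in subjects]
    raw = pd.DataFrame(
        np.power(2.0, np.hstack([x_t, x_n])), index=proteins, columns=cols
    )
    expr = ExpressionMatrix(raw, "raw")

    peptides = pd.DataFrame(
        {
            "protein_id": proteins,
            "unique_peptides": 2 + rng.poisson(5, size=p),
        }
    )
    n_low = int(round(config.low_peptide_frac * p))
    if n_low:
        low_idx = rng.choice(p, size=n_low, replace=False)
        peptides.loc[low_idx, "unique_peptides"] = 1

    module_ids = set(proteins[module_idx])
    truth = GroundTruth(
        dep_ids=set(proteins[dep_idx]),
        module_ids=module_ids,
        true_weights={proteins[module_idx[j]]: float(weights[j]) for j in range(config.module_size)},
        beta_hazard=config.beta_hazard,
        group_labels={subjects[i]: ("PM" if pm_status[i] else "PM-free") for i in range(n_sub)},
        pm_effects={proteins[module_idx[j]]: float(module_sign[j] * delta) for j in range(config.module_size)},
        true_score={subjects[i]: float(score[i]) for i in range(n_sub)},
    )
    return expr, peptides, samples, truth


def simulate_external_transcriptome(config: SimulationConfig, truth: GroundTruth):
    """ACRG-like external mRNA cohort sharing the planted module structure.

    Module genes carry the proteomic PM effect with the same sign, shrunk by
    ``external_attenuation``; all other genes are pure noise.  PM labels are
    balanced.  Returns an ``ExpressionMatrix`` (z-like scale, tagged
    ``log2z``) and a sample table with ``pm_status``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_654_321]))
    p = config.n_proteins
    width = max(4, len(str(p)))
    proteins = np.array([f"P{i + 1:0{width}d}" for i in range(p)])
    if truth.module_ids and not truth.module_ids <= set(proteins):
        raise ValueError("ground-truth module proteins not present in external identifier set")

    n = config.external_n
    n_pm = n // 2
    pm = np.array([1] * n_pm + [0] * (n - n_pm))
    x = rng.normal(0.0, config.external_noise_sd, size=(p, n)) if config.external_noise_sd > 0 else np.zeros((p, n))
    idx = {pid: i for i, pid in enumerate(proteins)}
    for pid, eff in truth.pm_effects.items():
        x[idx[pid], pm == 1] += config.external_attenuation * eff

    cols = [f"EXT{i + 1:04d}" for i in range(n)]
    expr = ExpressionMatrix(pd.DataFrame(x, index=proteins, columns=cols), "log2z")
    samples = pd.DataFrame({"sample_id": cols, "pm_status": pm})
    return expr, samples


def simulate_survival_cohort(weights: dict, n: int, beta_hazard: float,
                             censor_frac: float = 0.3, seed: int = 0):
    """Stand-alone survival cohort for validating a fixed signature.

    Expression for the panel proteins is standard normal per protein; the
    planted score is the weighted sum; survival follows an exponential
    proportional-hazards law in the standardized score.

    Returns an ``ExpressionMatrix`` (tagged ``log2z``) over the panel
    proteins and a clinical table with survival and covariates.
    """
    rng = np.random.default_rng(seed)
    panel = sorted(weights)
    w = np.array([weights[pid] for pid in panel])
    x = rng.normal(0.0, 1.0, size=(len(panel), n))
    raw_score = w @ x
    sd = raw_score.std(ddof=1)
    score = (raw_score - raw_score.mean()) / sd if sd > 0 else np.zeros(n)

    lam0 = np.log(2.0) / 24.0
    t_event = rng.exponential(1.0 / (lam0 * np.exp(beta_hazard * score)))
    if censor_frac > 0:
        c = _tune_censor_scale(t_event, censor_frac)
        t_cens = rng.uniform(0.0, c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    os_months = np.maximum(np.minimum(t_event, t_cens), 0.01)
    os_event = (t_event <= t_cens).astype(int)

    cols = [f"V{i + 1:04d}" for i in range(n)]
    expr = ExpressionMatrix(pd.DataFrame(x, index=panel, columns=cols), "log2z")
    clinical = pd.DataFrame(
        {
            "sample_id": cols,
            "subject_id": cols,
            "os_months": np.round(os_months, 4),
            "os_event": os_event,
            "age": rng.integers(40, 80, size=n),
            "stage": rng.choice([2, 3, 4], size=n),
        }
    )
    return expr, clinical


def write_cohort(outdir, expr: ExpressionMatrix, peptides: pd.DataFrame,
                 samples: pd.DataFrame, truth: GroundTruth | None = None) -> None:
    """Write the cohort in the pipeline's plain-text exchange formats."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr.to_tsv(outdir / "expression.tsv")
    peptides.to_csv(outdir / "peptides.tsv", sep="\t", index=False)
    samples.to_csv(outdir / "samples.csv", index=False)
    if truth is not None:
        truth.to_json(outdir / "ground_truth.json")
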