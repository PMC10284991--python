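"""End-to-end orchestration with one config, provenance and determinism.

Stages: simulate -> preprocess -> dep -> module -> select -> fit -> score ->
survival.  Each stage writes its artifact plus a provenance record (input
checksums, parameters, seed); a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix import ExpressionMatrix
from . import dep as dep_mod
from . import modules as module_mod
from . import preprocess as prep_mod
from . import risk as risk_mod
from . import signature as sig_mod
from . import simulate as sim_mod
from . import survival as surv_mod

STAGES = ("simulate", "preprocess", "dep", "module", "select", "fit", "score", "survival")
# each stage requires the one before it ("simulate" may instead be satisfied
# by pre-existing input files in the output directory)
_REQUIRES = {
    "dep": ("preprocess",),
    "module": ("dep",),
    "select": ("module",),
    "fit": ("select",),
    "score": ("fit",),
    "survival": ("score",),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """One config for the whole pipeline; defaults are desk-scale."""

    seed: int = 0
    outdir: str = "pmsig_run"
    stages: tuple = STAGES
    # simulate
    simulate: dict = field(default_factory=dict)       # SimulationConfig overrides
    # preprocess
    min_unique: int = 2
    min_fot: float = 1e-5
    floor: float = 1e-8
    zscore_axis: str = "sample"
    # dep
    fdr: float = 0.05
    fc: float = 1.5
    n_perm: int = 100
    pair_p: float = 0.05
    pair_min_frac: float = 0.5
    group_fdr: float = 0.05
    group_fc: float = 1.5
    # module
    k: int = 8
    ext_p: float = 0.05
    snr_agg: str = "mean"
    # select
    size_min: int = 3
    size_max: int = 10
    budget: int = 2000
    top_n: int = 500
    panel_size: int = 10
    folds: int = 5
    model_backend: str = "logistic"
    # survival
    adjust: tuple = ("age", "stage")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**obj)
        cfg.stages = tuple(cfg.stages)
        cfg.adjust = tuple(cfg.adjust)
        return cfg

    def to_yaml(self, path) -> None:
        obj = asdict(self)
        obj["stages"] = list(self.stages)
        obj["adjust"] = list(self.adjust)
        with open(path, "w") as fh:
            yaml.safe_dump(obj, fh, sort_keys=True)

    def validate(self) -> None:
        for st in self.stages:
            if st not in STAGES:
                raise PipelineError(f"unknown stage {st!r}")
        enabled = set(self.stages)
        for st in self.stages:
            for req in _REQUIRES.get(st, ()):
                if req not in enabled:
                    raise PipelineError(
                        f"stage {st!r} requires stage {req!r}, which is disabled"
                    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def run_all(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the final report dict.

    Artifacts and a provenance record land in ``config.outdir``.  All
    randomness derives from ``config.seed``, so reruns are byte-identical.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = set(config.stages)
    provenance = {"seed": config.seed, "parameters": asdict(config), "artifacts": {}}
    provenance["parameters"]["stages"] = list(config.stages)
    provenance["parameters"]["adjust"] = list(config.adjust)
    provenance["parameters"].pop("outdir")  # the record lives in that directory
    report: dict = {"seed": config.seed}

    def record(name: str, path: Path):
        provenance["artifacts"][name] = {"path": path.name, "sha256": _sha256(path)}

    def fail(stage: str, exc: Exception):
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- simulate (or load pre-existing inputs) -------------------------
    if "simulate" in enabled:
        sim_cfg = sim_mod.SimulationConfig(**{**config.simulate, "seed": config.seed})
        try:
            expr_raw, peptides, samples, truth = sim_mod.simulate_cohort(sim_cfg)
            ext_expr, ext_samples = sim_mod.simulate_external_transcriptome(sim_cfg, truth)
        except Exception as exc:  # noqa: BLE001
            fail("simulate", exc)
        sim_mod.write_cohort(out, expr_raw, peptides, samples, truth)
        ext_expr.to_tsv(out / "external_expression.tsv")
        ext_samples.to_csv(out / "external_samples.csv", index=False)
        for name in ("expression.tsv", "peptides.tsv", "samples.csv", "ground_truth.json",
                     "external_expression.tsv", "external_samples.csv"):
            record(name, out / name)
    else:
        needed = ["expression.tsv", "peptides.tsv", "samples.csv",
                  "external_expression.tsv", "external_samples.csv"]
        missing = [n for n in needed if not (out / n).exists()]
        if missing:
            raise PipelineError(
                f"simulate disabled but input files missing from {out}: {missing}"
            )
        expr_raw = ExpressionMatrix.from_tsv(out / "expression.tsv", "raw")
        peptides = pd.read_csv(out / "peptides.tsv", sep="\t")
        samples = pd.read_csv(out / "samples.csv")
        ext_expr = ExpressionMatrix.from_tsv(out / "external_expression.tsv", "log2z")
        ext_samples = pd.read_csv(out / "external_samples.csv")
        truth = (
            sim_mod.GroundTruth.from_json(out / "ground_truth.json")
            if (out / "ground_truth.json").exists()
            else None
        )
        for name in needed:
            record(name, out / name)

    if "preprocess" not in enabled:
        _dump_json(provenance, out / "provenance.json")
        _dump_json(report, out / "report.json")
        return report

    # --- preprocess -----------------------------------------------------
    try:
        fot = prep_mod.fot_normalize(expr_raw)
        filtered, removed = prep_mod.filter_proteins(
            fot, peptides, min_unique=config.min_unique, min_fot=config.min_fot
        )
        mz = prep_mod.log2_zscore(filtered, floor=config.floor, axis=config.zscore_axis)
        log2_fot = pd.DataFrame(
            np.log2(np.maximum(filtered.values, config.floor)),
            index=filtered.data.index,
            columns=filtered.data.columns,
        )
    except Exception as exc:  # noqa: BLE001
        fail("preprocess", exc)
    mz.to_tsv(out / "expression_log2z.tsv")
    removed.to_csv(out / "filter_log.tsv", sep="\t", index=False)
    record("expression_log2z.tsv", out / "expression_log2z.tsv")
    record("filter_log.tsv", out / "filter_log.tsv")
    report["n_proteins_quantified"] = expr_raw.n_proteins
    report["n_proteins_retained"] = mz.n_proteins

    samples_ix = samples.set_index("sample_id")
    tumor_samples = list(samples_ix.index[samples_ix["tissue"] == "T"])
    normal_samples = list(samples_ix.index[samples_ix["tissue"] == "N"])
    pairs = [
        (f"{sub}_T", f"{sub}_N") for sub in samples_ix["subject_id"].unique()
    ]
    pm_by_tumor = samples_ix.loc[tumor_samples, "pm_status"]

    if "dep" not in enabled:
        _dump_json(provenance, out / "provenance.json")
        _dump_json(report, out / "report.json")
        return report

    # --- dep ------------------------------------------------------------
    try:
        sam = dep_mod.sam_test(
            mz, pairs=pairs, n_perm=config.n_perm, fdr=config.fdr, fc=config.fc,
            seed=config.seed, fc_matrix=log2_fot,
        )
        tumor_m = mz.subset(samples=tumor_samples)
        normal_m = mz.subset(samples=normal_samples)
        pfc = dep_mod.pairfc_test(
            tumor_m, normal_m, pairs, p_thresh=config.pair_p,
            min_frac=config.pair_min_frac,
        )
        dep_table = dep_mod.combine_dep(sam, pfc)
        final_deps = dep_mod.overlap_deps(sam, pfc)
        if not final_deps:
            raise ValueError("no overlapped differential proteins were called")
        group = dep_mod.group_dep(
            tumor_m.subset(proteins=final_deps),
            pm_by_tumor,
            set(final_deps),
            contrast=(1, 0),
            n_perm=config.n_perm,
            fdr=config.group_fdr,
            fc=config.group_fc,
            seed=config.seed,
            fc_matrix=log2_fot[tumor_samples],
        )
    except Exception as exc:  # noqa: BLE001
        fail("dep", exc)
    dep_out = dep_table.copy()
    dep_out.insert(0, "protein_id", dep_out.index)
    dep_out.to_csv(out / "deps.tsv", sep="\t", index=False)
    record("deps.tsv", out / "deps.tsv")
    report["n_deps_tumor_normal"] = int(len(final_deps))
    report["n_deps_pm_group"] = int(group.table["called"].sum())

    if "module" not in enabled:
        _dump_json(provenance, out / "provenance.json")
        _dump_json(report, out / "report.json")
        return report

    # --- module ---------------------------------------------------------
    try:
        assignment = module_mod.cluster_deps(
            tumor_m, pm_by_tumor, set(final_deps), k=config.k, seed=config.seed,
            normals=normal_m,
        )
        assignment = module_mod.score_modules(
            assignment, tumor_m, pm_by_tumor, agg=config.snr_agg
        )
        pm_module = module_mod.select_pm_module(assignment)
        directions = dep_table.loc[pm_module, "direction"]
        ext_labels = ext_samples.set_index("sample_id")["pm_status"]
        pool = module_mod.external_filter(
            pm_module, ext_expr, ext_labels, directions, p_thresh=config.ext_p
        )
    except Exception as exc:  # noqa: BLE001
        fail("module", exc)
    _dump_json(
        {
            "assignment": {p: int(v) for p, v in assignment.assignment.items()},
            "snr": {str(k): v for k, v in assignment.snr.items()},
            "selected_module": assignment.selected_module,
            "module_members": pm_module,
            "filtered_pool": pool,
        },
        out / "module.json",
    )
    record("module.json", out / "module.json")
    report["module_size"] = len(pm_module)
    report["module_snr"] = assignment.snr[assignment.selected_module]
    report["pool_size"] = len(pool)

    if "select" not in enabled:
        _dump_json(provenance, out / "provenance.json")
        _dump_json(report, out / "report.json")
        return report

    # --- select ---------------------------------------------------------
    try:
        scored, mode = sig_mod.enumerate_and_score(
            tumor_m, pm_by_tumor, pool,
            size_range=(min(config.size_min, len(pool)), config.size_max),
            budget=config.budget, folds=config.folds, seed=config.seed,
            model=config.model_backend,
        )
        selection = sig_mod.frequency_select(
            scored, tumor_m, pm_by_tumor, top_n=config.top_n,
            panel_size=min(config.panel_size, len(pool)), mode=mode, seed=config.seed,
        )
    except Exception as exc:  # noqa: BLE001
        fail("select", exc)
    selection.to_json(out / "selection.json")
    record("selection.json", out / "selection.json")
    report["panel"] = selection.panel
    report["enumeration_mode"] = mode
    report["best_combo_cv_auc"] = selection.top_combos[0][1]

    if "fit" not in enabled:
        _dump_json(provenance, out / "provenance.json")
        _dump_json(report, out / "report.json")
        return report

    # --- fit ------------------------------------------------------------
    try:
        model = risk_mod.fit_weights(
            tumor_m, pm_by_tumor, selection.panel, seed=config.seed, cohort="internal"
        )
        panel_auc = sig_mod.cv_auc(
            tumor_m, pm_by_tumor, selection.panel, folds=config.folds,
            seed=config.seed, model=config.model_backend,
        )
    except Exception as exc:  # noqa: BLE001
        fail("fit", exc)
    report["panel_cv_auc"] = panel_auc.mean_cv_auc

    if "score" not in enabled:
        model.to_json(out / "model.json")
        record("model.json", out / "model.json")
        _dump_json(provenance, out / "provenance.json")
        _dump_json(report, out / "report.json")
        return report

    # --- score ----------------------------------------------------------
    try:
        scores = risk_mod.pm_risk_score(model, tumor_m)
        model.cutpoints = risk_mod.quartile_cutpoints(scores)
        strata = risk_mod.stratify(scores)
    except Exception as exc:  # noqa: BLE001
        fail("score", exc)
    model.to_json(out / "model.json")
    record("model.json", out / "model.json")
    pd.DataFrame(
        {"sample_id": scores.index, "pm_risk_score": scores.values,
         "risk_level": strata.values}
    ).to_csv(out / "scores.csv", index=False)
    record("scores.csv", out / "scores.csv")
    report["risk_group_sizes"] = strata.value_counts().to_dict()

    if "survival" not in enabled:
        _dump_json(provenance, out / "provenance.json")
        _dump_json(report, out / "report.json")
        return report

    # --- survival -------------------------------------------------------
    try:
        clin = samples_ix.loc[tumor_samples].reset_index()
        surv_report = surv_mod.validate_signature(
            model, tumor_m, clin, adjust=config.adjust
        )
    except surv_mod.ConvergenceError as exc:
        # at n=20 the extreme-quartile Cox fit can separate perfectly;
        # record the failure rather than halting the run
        surv_report = {"error": str(exc)}
    except Exception as exc:  # noqa: BLE001
        fail("survival", exc)
    _dump_json(surv_report, out / "survival_report.json")
    record("survival_report.json", out / "survival_report.json")
    if "logrank" in surv_report:
        report["logrank_p_high_vs_low"] = surv_report["logrank"]["p"]

    if truth is not None:
        report["panel_planted_overlap"] = len(set(selection.panel) & truth.module_ids)
    _dump_json(provenance, out / "provenance.json")
    _dump_json(report, out / "report.json")
    return report
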