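"""Phenotype-differential module selection.

Differential proteins are clustered by their phenotype-conditioned profile
(mean z in PM tumors, mean z in PM-free tumors, mean z in normals), the
resulting modules are ranked by signal-to-noise between the PM phenotypes,
and the top module is filtered against an external transcriptome cohort for
sign-concordant significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

SNR_EPS = 1e-8


@dataclass
class ModuleAssignment:
    """Partition of differential proteins into modules, with per-module SNR."""

    assignment: pd.Series                      # protein -> module index
    profiles: pd.DataFrame                     # protein x (pm, pm_free, normal)
    snr: dict = field(default_factory=dict)    # module index -> SNR
    selected_module: int | None = None

    def members(self, module: int) -> list:
        return sorted(self.assignment.index[self.assignment == module])

    @property
    def module_sizes(self) -> dict:
        return self.assignment.value_counts().sort_index().to_dict()


def _phenotype_masks(m: ExpressionMatrix, pm_labels) -> tuple[np.ndarray, np.ndarray]:
    lab = pd.Series(pm_labels).reindex(m.sample_ids)
    if lab.isna().any():
        raise ValueError(f"samples without PM labels: {list(lab.index[lab.isna()])[:5]}")
    pm = lab.astype(int).to_numpy() == 1
    if pm.sum() < 2 or (~pm).sum() < 2:
        raise ValueError("each phenotype group needs >= 2 samples")
    return pm, ~pm


def cluster_deps(
    m: ExpressionMatrix,
    pm_labels,
    deps: set,
    k: int = 8,
    seed: int | None = 0,
    normals: ExpressionMatrix | None = None,
    n_init: int = 10,
    center: bool = True,
    whiten: bool = True,
) -> ModuleAssignment:
    """Partition DEPs into k modules by centroid clustering of phenotype profiles.

    ``m`` holds the tumor samples; ``pm_labels`` maps each tumor sample to
    0/1 PM status; ``normals`` optionally supplies the paired normal matrix
    for the third profile coordinate (omitted when absent).  With ``center``
    (default) each protein's profile is centered on its own mean before
    clustering, so modules form by differential shape rather than baseline
    abundance -- sample-wise z-scores still carry each protein's absolute
    abundance level, which would otherwise dominate the partition.  With
    ``whiten`` (default) the centered profiles are PCA-whitened before
    KMeans, balancing the dominant tumor-vs-normal axis against the weaker
    PM-contrast axis so phenotype-differential modules are not split along
    effect magnitude.
    """
    dep_list = [p for p in m.protein_ids if p in deps]
    if len(dep_list) < k:
        raise ValueError(f"k={k} exceeds the number of DEPs ({len(dep_list)})")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    sub = m.subset(proteins=dep_list)
    pm, free = _phenotype_masks(sub, pm_labels)
    x = sub.values
    cols = {"pm": x[:, pm].mean(axis=1), "pm_free": x[:, free].mean(axis=1)}
    if normals is not None:
        cols["normal"] = normals.subset(proteins=dep_list).values.mean(axis=1)
    profiles = pd.DataFrame(cols, index=dep_list)

    feat = profiles.to_numpy()
    if center:
        feat = feat - feat.mean(axis=1, keepdims=True)
    if whiten:
        feat = feat - feat.mean(axis=0)
        _, sv, vt = np.linalg.svd(feat, full_matrices=False)
        keep = sv > 1e-9 * sv[0] if sv[0] > 0 else sv > -1
        if keep.any():
            feat = (feat @ vt[keep].T) / sv[keep]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(feat)
    return ModuleAssignment(
        assignment=pd.Series(labels, index=dep_list), profiles=profiles
    )


def module_snr(m: ExpressionMatrix, pm_labels, proteins, agg: str = "mean") -> float:
    """Mean (or median) per-protein signal-to-noise of a module.

    SNR_p = |mu_PM,p - mu_PMfree,p| / (sigma_PM,p + sigma_PMfree,p + eps).
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("module is empty")
    sub = m.subset(proteins=proteins)
    pm, free = _phenotype_masks(sub, pm_labels)
    x = sub.values
    num = np.abs(x[:, pm].mean(axis=1) - x[:, free].mean(axis=1))
    den = x[:, pm].std(axis=1, ddof=1) + x[:, free].std(axis=1, ddof=1) + SNR_EPS
    per_protein = num / den
    if agg == "mean":
        return float(per_protein.mean())
    if agg == "median":
        return float(np.median(per_protein))
    raise ValueError(f"unknown aggregation {agg!r}")


def score_modules(
    assignment: ModuleAssignment, m: ExpressionMatrix, pm_labels, agg: str = "mean"
) -> ModuleAssignment:
    """Attach per-module SNRs and mark the argmax module (ties -> smaller index)."""
    snrs = {}
    for mod in sorted(assignment.assignment.unique()):
        snrs[int(mod)] = module_snr(m, pm_labels, assignment.members(mod), agg=agg)
    assignment.snr = snrs
    best = max(sorted(snrs), key=lambda mod: (snrs[mod], -mod))
    assignment.selected_module = int(best)
    return assignment


def select_pm_module(assignment: ModuleAssignment) -> list:
    """Members of the highest-SNR module."""
    if not assignment.snr:
        raise ValueError("assignment has no SNRs; run score_modules first")
    if assignment.selected_module is None:
        best = max(sorted(assignment.snr), key=lambda mod: (assignment.snr[mod], -mod))
        assignment.selected_module = int(best)
    return assignment.members(assignment.selected_module)


def external_filter(
    proteins,
    ext: ExpressionMatrix,
    ext_pm_labels,
    directions: pd.Series | dict,
    p_thresh: float = 0.05,
) -> list:
    """Keep module proteins confirmed in an external cohort.

    A protein survives when its external two-sample Welch test has
    p < ``p_thresh`` and the sign of the external PM-vs-PM-free mean
    difference matches the proteomic direction (``directions``: protein ->
    'up'/'down' or a signed number).  Proteins absent from the external
    matrix are dropped with a warning.
    """
    proteins = list(proteins)
    present = [p for p in proteins if p in ext.data.index]
    absent = sorted(set(proteins) - set(present))
    if absent:
        logger.warning("%d module proteins absent from external matrix: %s",
                       len(absent), absent[:5])
    if not present:
        raise ValueError("no module proteins present in the external matrix")

    lab = pd.Series(ext_pm_labels)
    if "sample_id" in getattr(ext_pm_labels, "columns", []):
        raise TypeError("pass a mapping sample -> pm status, not a DataFrame")
    lab = lab.reindex(ext.sample_ids)
    if lab.isna().any():
        raise ValueError("external samples without PM labels")
    pm = lab.astype(int).to_numpy() == 1
    sub = ext.subset(proteins=present)
    x = sub.values
    t, p = stats.ttest_ind(x[:, pm], x[:, ~pm], axis=1, equal_var=False)
    diff = x[:, pm].mean(axis=1) - x[:, ~pm].mean(axis=1)

    dirs = pd.Series(directions)
    kept = []
    for i, pid in enumerate(present):
        want = dirs.get(pid)
        if want is None:
            continue
        sign = 1.0 if want in ("up", "Up") else -1.0 if want in ("down", "Down") else np.sign(float(want))
        if p[i] < p_thresh and np.sign(diff[i]) == sign:
            kept.append(pid)
    if not kept:
        raise ValueError(
            "external filtering removed every module protein; consider relaxing p_thresh"
        )
    return sorted(kept)
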