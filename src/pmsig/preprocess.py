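"""Protein filtering and normalization.

The order of operations is fixed and enforced through the matrix state tag:
raw intensities -> fraction of total (FOT) -> unique-peptide / FOT filtering
-> log2 z-scores.  FOT divides each sample column by its total so samples
with different loading become comparable; the peptide and FOT thresholds
drop proteins whose quantification is unreliable; z-scoring puts every
sample on a common log2 scale for the differential analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


def fot_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Fraction-of-total normalization: value[p, s] = raw[p, s] / sum_p raw[p, s]."""
    m.require_state("raw", "fot_normalize")
    vals = m.values.astype(float)
    if (vals < 0).any():
        r, c = np.argwhere(vals < 0)[0]
        raise ValueError(f"negative intensity for sample {m.sample_ids[c]} (protein {m.protein_ids[r]})")
    sums = vals.sum(axis=0)
    zero = np.where(sums <= 0)[0]
    if zero.size:
        raise ValueError(f"all-zero sample column: {m.sample_ids[zero[0]]}")
    out = pd.DataFrame(vals / sums, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(out, "fot")


def filter_proteins(
    m: ExpressionMatrix,
    peptides: pd.DataFrame,
    min_unique: int = 2,
    min_fot: float = 1e-5,
):
    """Keep proteins with >= ``min_unique`` unique peptides and max FOT > ``min_fot``.

    ``peptides`` must have columns ``protein_id`` and ``unique_peptides`` and
    cover every protein in the matrix.  Returns the filtered matrix (original
    protein order preserved) and a removal log recording each dropped
    protein's reason.
    """
    m.require_state("fot", "filter_proteins")
    pep = peptides.set_index("protein_id")["unique_peptides"]
    missing = [p for p in m.protein_ids if p not in pep.index]
    if missing:
        raise ValueError(f"proteins missing from peptide table: {missing[:5]}")
    pep = pep.loc[m.protein_ids]
    max_fot = m.data.max(axis=1)
    keep_pep = pep.to_numpy() >= min_unique
    keep_fot = max_fot.to_numpy() > min_fot
    keep = keep_pep & keep_fot

    reasons = []
    for pid, ok_p, ok_f in zip(m.protein_ids, keep_pep, keep_fot):
        if ok_p and ok_f:
            continue
        why = []
        if not ok_p:
            why.append(f"unique_peptides < {min_unique}")
        if not ok_f:
            why.append(f"max FOT <= {min_fot:g}")
        reasons.append({"protein_id": pid, "reason": "; ".join(why)})
    log = pd.DataFrame(reasons, columns=["protein_id", "reason"])
    out = ExpressionMatrix(m.data.loc[keep], "fot")
    return out, log


def log2_zscore(m: ExpressionMatrix, floor: float = 1e-8, axis: str = "sample") -> ExpressionMatrix:
    """log2-transform FOT values (floored) and z-score.

    ``axis='sample'`` (default) standardizes each sample column by its own
    mean and SD over the retained proteins; ``axis='protein'`` standardizes
    each protein row across samples instead.  Sample SD uses ddof=1.
    """
    m.require_state("fot", "log2_zscore")
    if floor <= 0:
        raise ValueError(f"floor must be > 0, got {floor}")
    if axis not in ("sample", "protein"):
        raise ValueError(f"axis must be 'sample' or 'protein', got {axis!r}")
    x = np.log2(np.maximum(m.values, floor))
    ax = 0 if axis == "sample" else 1
    mean = x.mean(axis=ax, keepdims=True)
    sd = x.std(axis=ax, ddof=1, keepdims=True)
    zero = np.where(sd.ravel() == 0)[0]
    if zero.size:
        which = m.sample_ids[zero[0]] if axis == "sample" else m.protein_ids[zero[0]]
        raise ValueError(f"constant {axis} (zero SD), cannot z-score: {which}")
    z = (x - mean) / sd
    return ExpressionMatrix(pd.DataFrame(z, index=m.data.index, columns=m.data.columns), "log2z")


def preprocess(
    raw: ExpressionMatrix,
    peptides: pd.DataFrame,
    min_unique: int = 2,
    min_fot: float = 1e-5,
    floor: float = 1e-8,
    axis: str = "sample",
):
    """raw -> fot -> filter -> log2z in one call; returns (matrix, removal log)."""
    fot = fot_normalize(raw)
    filtered, log = filter_proteins(fot, peptides, min_unique=min_unique, min_fot=min_fot)
    return log2_zscore(filtered, floor=floor, axis=axis), log
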