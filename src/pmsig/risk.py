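"""PM risk score: boosted-linear weights, weighted score, quartile strata.

A gradient-boosted linear classifier (L2-regularized additive boosting of a
linear base learner) is fit to discriminate PM from PM-free tumors on the
final panel; its per-protein coefficients become the signature weights.
The PM risk score of a subject is the weighted sum of panel expression, and
cohorts are stratified into high (top quartile), moderate and low (bottom
quartile) risk by the cohort's own score distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclass
class SignatureModel:
    """Ordered panel, per-protein weights and quartile cutpoints."""

    panel: list
    weights: dict
    cutpoints: tuple | None = None   # (q1, q3) from the training cohort
    seed: int | None = None
    cohort: str | None = None

    def __post_init__(self) -> None:
        if set(self.weights) != set(self.panel):
            raise ValueError("weights must be keyed exactly by the panel")
        if self.cutpoints is not None and self.cutpoints[0] > self.cutpoints[1]:
            raise ValueError("q1 cutpoint exceeds q3")

    def to_json(self, path) -> None:
        obj = {
            "panel": list(self.panel),
            "weights": {k: float(v) for k, v in self.weights.items()},
            "cutpoints": (
                {"q1": self.cutpoints[0], "q3": self.cutpoints[1]}
                if self.cutpoints is not None
                else None
            ),
            "seed": self.seed,
            "cohort": self.cohort,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            obj = json.load(fh)
        cut = obj.get("cutpoints")
        return cls(
            panel=obj["panel"],
            weights=obj["weights"],
            cutpoints=(cut["q1"], cut["q3"]) if cut else None,
            seed=obj.get("seed"),
            cohort=obj.get("cohort"),
        )


def fit_weights(
    m: ExpressionMatrix,
    pm_labels,
    panel,
    seed: int | None = 0,
    n_rounds: int = 100,
    learning_rate: float = 0.5,
    reg_lambda: float = 1.0,
    cohort: str | None = None,
) -> SignatureModel:
    """Extract signature weights from a boosted linear classifier.

    The intercept is dropped: the score is used only for ranking and
    quartile stratification, which are translation-invariant.
    """
    from xgboost import XGBClassifier

    panel = list(panel)
    missing = [p for p in panel if p not in m.data.index]
    if missing:
        raise ValueError(f"panel proteins missing from matrix: {missing}")
    sub = m.subset(proteins=panel)
    lab = pd.Series(pm_labels).reindex(sub.sample_ids)
    if lab.isna().any():
        raise ValueError("samples without PM labels")
    y = lab.astype(int).to_numpy()
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present to fit weights")

    clf = XGBClassifier(
        booster="gblinear",
        updater="coord_descent",
        feature_selector="cyclic",
        n_estimators=n_rounds,
        learning_rate=learning_rate,
        reg_lambda=reg_lambda,
        reg_alpha=0.0,
        n_jobs=1,
        random_state=0 if seed is None else int(seed) % (2**31 - 1),
        eval_metric="logloss",
    )
    clf.fit(sub.values.T, y)
    coefs = np.asarray(clf.coef_, dtype=float).ravel()
    weights = {pid: float(w) for pid, w in zip(panel, coefs)}
    return SignatureModel(panel=panel, weights=weights, seed=seed, cohort=cohort)


def pm_risk_score(model: SignatureModel, m: ExpressionMatrix) -> pd.Series:
    """score_s = sum_j w_j * z_{j,s} over the panel, per sample."""
    missing = [p for p in model.panel if p not in m.data.index]
    if missing:
        raise ValueError(f"panel proteins missing from matrix: {missing}")
    sub = m.subset(proteins=model.panel)
    w = np.array([model.weights[p] for p in model.panel])
    return pd.Series(w @ sub.values, index=m.sample_ids, name="pm_risk_score")


def stratify(scores: pd.Series, cutpoints: tuple | None = None) -> pd.Series:
    """Quartile risk strata: >= q3 high, <= q1 low, moderate between.

    Cutpoints are the 25th/75th linear-interpolation percentiles of the
    cohort's own scores unless fixed cutpoints are supplied.  Boundary ties
    go to the extreme groups.
    """
    scores = pd.Series(scores)
    if len(scores) < 4:
        raise ValueError(f"need >= 4 subjects to stratify, got {len(scores)}")
    if cutpoints is None:
        q1, q3 = np.percentile(scores.to_numpy(), [25, 75])
    else:
        q1, q3 = cutpoints
    if q1 == q3:
        raise ValueError(
            "degenerate score distribution (q1 == q3); strata are not defined"
        )
    out = pd.Series("moderate", index=scores.index, name="risk_level")
    out[scores >= q3] = "high"
    out[scores <= q1] = "low"
    return out


def quartile_cutpoints(scores: pd.Series) -> tuple[float, float]:
    q1, q3 = np.percentile(pd.Series(scores).to_numpy(), [25, 75])
    return float(q1), float(q3)
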