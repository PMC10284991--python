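"""Cross-validated combinatorial panel selection.

Candidate proteins (the externally filtered PM module) are combined into
subsets; each subset is scored by the mean AUC of a classifier over
stratified k-fold cross-validation; the proteins appearing most frequently
in the top-scoring combinations form the final panel.  Because the number
of subsets explodes combinatorially, enumeration is exhaustive only up to a
budget and switches to uniform sampling of distinct combinations beyond it,
with the mode recorded in the report.
"""

from __future__ import annotations

import itertools
import json
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .matrix import ExpressionMatrix


def auc(scores, labels) -> float:
    """Rank-based AUC: Mann-Whitney U / (n1 * n0), ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _make_model(model: str, seed: int | None):
    if model == "logistic":
        return LogisticRegression(C=1.0, max_iter=2000)
    if model == "gbtree":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=60,
            max_depth=2,
            learning_rate=0.3,
            subsample=1.0,
            reg_lambda=1.0,
            tree_method="hist",
            n_jobs=1,
            random_state=0 if seed is None else int(seed) % (2**31 - 1),
            eval_metric="logloss",
        )
    raise ValueError(f"unknown model backend {model!r}; use 'gbtree' or 'logistic'")


@dataclass
class ComboScore:
    combo: tuple
    mean_cv_auc: float
    fold_aucs: list

    def __post_init__(self) -> None:
        self.combo = tuple(sorted(set(self.combo)))


def cv_auc(
    m: ExpressionMatrix,
    labels,
    combo=None,
    folds: int = 5,
    seed: int | None = 0,
    model: str = "gbtree",
) -> ComboScore:
    """Mean out-of-fold AUC of a classifier on a protein subset.

    Folds are stratified and shuffled with a fixed seed; the model is refit
    per fold with fixed hyperparameters, so the result is reproducible.
    """
    combo = tuple(sorted(set(combo if combo is not None else m.protein_ids)))
    sub = m.subset(proteins=list(combo))
    x = sub.values.T                       # samples x features
    lab = pd.Series(labels).reindex(sub.sample_ids)
    if lab.isna().any():
        raise ValueError("samples without labels")
    y = lab.astype(int).to_numpy()
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; use at most that many folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs = []
    for train, test in skf.split(x, y):
        clf = _make_model(model, seed)
        clf.fit(x[train], y[train])
        prob = clf.predict_proba(x[test])[:, 1]
        fold_aucs.append(auc(prob, y[test]))
    return ComboScore(combo=combo, mean_cv_auc=float(np.mean(fold_aucs)), fold_aucs=fold_aucs)


def rank_pool(
    m: ExpressionMatrix, labels, pool, seed: int | None = 0, model: str = "gbtree"
) -> list:
    """Order a candidate pool by informativeness.

    With the tree backend, a full-data fit supplies gain importances;
    proteins with tied or zero importance (and the logistic backend) fall
    back to the marginal univariate AUC distance from 0.5.  Ties break
    lexicographically, so the order is deterministic.
    """
    pool = sorted(set(pool))
    sub = m.subset(proteins=pool)
    lab = pd.Series(labels).reindex(sub.sample_ids).astype(int).to_numpy()
    marginal = {
        pid: abs(auc(sub.data.loc[pid].to_numpy(), lab) - 0.5) for pid in pool
    }
    importance = dict.fromkeys(pool, 0.0)
    if model == "gbtree":
        clf = _make_model(model, seed)
        clf.fit(sub.values.T, lab)
        importance.update(dict(zip(pool, clf.feature_importances_.astype(float))))
    return sorted(pool, key=lambda pid: (-importance[pid], -marginal[pid], pid))


def best_panel_size(
    m: ExpressionMatrix,
    labels,
    pool,
    folds: int = 5,
    seed: int | None = 0,
    model: str = "gbtree",
):
    """Size of the nested importance-ranked prefix with the best CV AUC.

    Returns (size, ranked pool, per-size scores); ties prefer the smaller
    size.
    """
    ranked = rank_pool(m, labels, pool, seed=seed, model=model)
    scores = {}
    for size in range(1, len(ranked) + 1):
        scores[size] = cv_auc(
            m, labels, ranked[:size], folds=folds, seed=seed, model=model
        ).mean_cv_auc
    best = max(sorted(scores), key=lambda s: (scores[s], -s))
    return best, ranked, scores


def enumerate_and_score(
    m: ExpressionMatrix,
    labels,
    pool,
    size_range: tuple[int, int] = (3, 10),
    budget: int = 200_000,
    folds: int = 5,
    seed: int | None = 0,
    model: str = "gbtree",
):
    """Score protein combinations within a size range, under a budget.

    When the total number of combinations fits the budget they are all
    enumerated; otherwise ``budget`` distinct combinations are sampled
    uniformly (sizes weighted by their combination counts).  Returns
    (list of ComboScore, mode) with mode in {'exhaustive', 'sampled'}.
    """
    pool = sorted(set(pool))
    lo, hi = size_range
    hi = min(hi, len(pool))
    if lo < 1 or lo > hi:
        raise ValueError(f"invalid size range [{size_range[0]}, {size_range[1]}] for pool of {len(pool)}")
    if budget < 1:
        raise ValueError(f"budget must be >= 1, got {budget}")

    counts = {k: math.comb(len(pool), k) for k in range(lo, hi + 1)}
    total = sum(counts.values())
    rng = np.random.default_rng(seed)
    if total <= budget:
        combos = [
            cmb for k in range(lo, hi + 1) for cmb in itertools.combinations(pool, k)
        ]
        mode = "exhaustive"
    else:
        sizes = np.array(sorted(counts))
        weights = np.array([counts[k] for k in sizes], dtype=float)
        weights /= weights.sum()
        seen: set = set()
        combos = []
        while len(combos) < budget:
            k = int(rng.choice(sizes, p=weights))
            cmb = tuple(sorted(rng.choice(len(pool), size=k, replace=False)))
            if cmb in seen:
                continue
            seen.add(cmb)
            combos.append(tuple(pool[i] for i in cmb))
        mode = "sampled"

    scored = [
        cv_auc(m, labels, cmb, folds=folds, seed=seed, model=model) for cmb in combos
    ]
    return scored, mode


@dataclass
class SelectionReport:
    pool: list
    panel: list
    panel_size: int
    top_combos: list                 # [(combo tuple, mean auc), ...] capped at top_n
    frequency: dict                  # protein -> count within top combos
    mode: str
    seed: int | None
    best_size: int | None = None
    size_scores: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        obj = {
            "pool": self.pool,
            "panel": self.panel,
            "panel_size": self.panel_size,
            "top_combos": [[list(c), s] for c, s in self.top_combos],
            "frequency": self.frequency,
            "mode": self.mode,
            "seed": self.seed,
            "best_size": self.best_size,
            "size_scores": {str(k): v for k, v in self.size_scores.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)


def frequency_select(
    scored: list,
    m: ExpressionMatrix,
    labels,
    top_n: int = 500,
    panel_size: int = 10,
    mode: str = "exhaustive",
    seed: int | None = None,
) -> SelectionReport:
    """Panel = the proteins most frequent among the top-scoring combinations.

    Combinations are ordered by mean CV AUC (ties: smaller, then
    lexicographically earlier combination); the ``top_n`` best are kept and
    member frequencies counted; frequency ties break by higher marginal
    univariate AUC, then lexicographically.
    """
    if not scored:
        raise ValueError("no scored combinations")
    ordered = sorted(scored, key=lambda cs: (-cs.mean_cv_auc, len(cs.combo), cs.combo))
    top = ordered[:top_n]
    freq = Counter(pid for cs in top for pid in cs.combo)
    if len(freq) < panel_size:
        raise ValueError(
            f"only {len(freq)} distinct proteins in the top combinations; "
            f"cannot form a panel of {panel_size}"
        )
    lab = pd.Series(labels).reindex(m.sample_ids).astype(int).to_numpy()
    marginal = {pid: auc(m.data.loc[pid].to_numpy(), lab) for pid in freq}
    panel = sorted(freq, key=lambda pid: (-freq[pid], -abs(marginal[pid] - 0.5), pid))[
        :panel_size
    ]
    pool = sorted({pid for cs in scored for pid in cs.combo})
    return SelectionReport(
        pool=pool,
        panel=panel,
        panel_size=panel_size,
        top_combos=[(cs.combo, cs.mean_cv_auc) for cs in top],
        frequency=dict(sorted(freq.items())),
        mode=mode,
        seed=seed,
    )
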