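"""Survival validation: Kaplan-Meier, log-rank, and Cox proportional hazards.

The Kaplan-Meier product-limit estimator (with Greenwood variance) and the
Cox partial-likelihood Newton solver are implemented here; the Cox solver
uses Breslow tie handling by default with Efron available, Wald confidence
intervals, and an explicit error on monotone likelihood (perfect
separation).  The multi-group log-rank test is delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ConvergenceError(RuntimeError):
    """Cox partial likelihood failed to converge (possibly monotone likelihood)."""


def _check_records(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if (time <= 0).any():
        raise ValueError("survival times must be > 0")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return time, event.astype(int)


def km_estimate(time, event) -> pd.DataFrame:
    """Product-limit survival estimate with Greenwood variance.

    Returns one row per distinct event time: at-risk count, events,
    survival and Greenwood variance of the survival estimate.
    """
    time, event = _check_records(time, event)
    if time.size == 0:
        raise ValueError("empty group")
    event_times = np.unique(time[event == 1])
    rows = []
    surv = 1.0
    green = 0.0
    for t in event_times:
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        surv *= 1.0 - d / n_at_risk
        if n_at_risk > d:
            green += d / (n_at_risk * (n_at_risk - d))
        else:
            green = np.inf
        rows.append(
            {
                "time": float(t),
                "at_risk": n_at_risk,
                "events": d,
                "survival": surv,
                "variance": surv**2 * green if np.isfinite(green) else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival", "variance"])


def km_by_group(df: pd.DataFrame, time_col="os_months", event_col="os_event",
                group_col="risk_level") -> dict:
    out = {}
    for g, sub in df.groupby(group_col):
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        out[g] = km_estimate(sub[time_col], sub[event_col])
    return out


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Multi-group log-rank test; returns (chi-square statistic, p-value)."""
    from lifelines.statistics import multivariate_logrank_test

    time, event = _check_records(time, event)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    if event.sum() == 0:
        return 0.0, 1.0
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value)


def _cox_loglik(beta, x, time, event, ties="breslow"):
    """Negative log partial likelihood with gradient and Hessian.

    Samples must be sorted by ascending time.  Risk sets are suffix sums.
    """
    n, p = x.shape
    eta = x @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    # suffix cumulative sums over the risk set {j : t_j >= t_i}
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * x)[::-1], axis=0)[::-1]
    s2 = np.cumsum((w[:, None, None] * x[:, :, None] * x[:, None, :])[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        ev = [k for k in range(i, j) if event[k] == 1]
        d = len(ev)
        if d > 0:
            xs = x[ev].sum(axis=0)
            ll += eta[ev].sum()
            if ties == "breslow":
                ll -= d * np.log(s0[i])
                mu = s1[i] / s0[i]
                grad += xs - d * mu
                hess -= d * (s2[i] / s0[i] - np.outer(mu, mu))
            elif ties == "efron":
                wd = w[ev].sum()
                s1d = (w[ev, None] * x[ev]).sum(axis=0)
                s2d = (w[ev, None, None] * x[ev][:, :, None] * x[ev][:, None, :]).sum(axis=0)
                grad += xs
                for r in range(d):
                    f = r / d
                    denom = s0[i] - f * wd
                    ll -= np.log(denom)
                    mu = (s1[i] - f * s1d) / denom
                    grad -= mu
                    hess -= (s2[i] - f * s2d) / denom - np.outer(mu, mu)
            else:
                raise ValueError(f"unknown tie handling {ties!r}")
        i = j
    return ll, grad, hess


def cox_fit(
    df: pd.DataFrame,
    covariates,
    time_col: str = "os_months",
    event_col: str = "os_event",
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cox proportional-hazards fit by Newton iterations on the partial likelihood.

    Returns one row per covariate: coefficient, HR, Wald CI and p-value.
    Raises :class:`ConvergenceError` on non-convergence or monotone
    likelihood (perfect separation drives a coefficient to infinity).
    """
    covariates = list(covariates)
    time, event = _check_records(df[time_col], df[event_col])
    if event.sum() < len(covariates) + 1:
        raise ValueError(
            f"{event.sum()} events cannot support {len(covariates)} covariates"
        )
    x = df[covariates].to_numpy(dtype=float)
    order = np.argsort(time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    # center covariates for numerical stability; coefficients are unaffected
    x = x - x.mean(axis=0)

    beta = np.zeros(len(covariates))
    ll_old = -np.inf
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik(beta, x, time, event, ties=ties)
        # gradient criterion, with a likelihood-plateau fallback at the
        # floating-point precision of the partial likelihood itself
        if np.linalg.norm(grad) < tol or abs(ll - ll_old) < 1e-12 * max(1.0, abs(ll)):
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        # step halving keeps the likelihood non-decreasing (up to rounding)
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, _, _ = _cox_loglik(cand, x, time, event, ties=ties)
            if ll_new >= ll - 1e-9 * max(1.0, abs(ll)):
                break
            factor /= 2.0
        beta = beta + factor * step
        if np.abs(beta).max() > 50:
            raise ConvergenceError(
                "coefficient diverging; monotone partial likelihood (perfect separation?)"
            )
        ll_old = ll
    else:
        raise ConvergenceError(f"no convergence in {max_iter} Newton iterations")
    if np.abs(beta).max() > 10:
        raise ConvergenceError(
            "implausibly large coefficient at optimum; monotone partial "
            "likelihood (perfect separation?)"
        )

    _, _, hess = _cox_loglik(beta, x, time, event, ties=ties)
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular information matrix at optimum") from exc
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    zq = stats.norm.ppf(1 - alpha / 2)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    return pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "se": se,
            "hr_lower": np.exp(np.clip(beta - zq * se, -700, 700)),
            "hr_upper": np.exp(np.clip(beta + zq * se, -700, 700)),
            "p": 2 * stats.norm.sf(np.abs(z)),
        },
        index=covariates,
    )


def validate_signature(
    model,
    expr,
    clinical: pd.DataFrame,
    adjust=("age", "stage"),
    time_col: str = "os_months",
    event_col: str = "os_event",
) -> dict:
    """Score, stratify and test a cohort against survival.

    High vs low strata (the middle half is excluded from the contrast, as in
    an extreme-quartile comparison) are compared by log-rank and by
    univariate plus covariate-adjusted Cox regression with high-vs-low risk
    as the exposure.  Returns a machine-readable report.
    """
    from .risk import pm_risk_score, stratify

    scores = pm_risk_score(model, expr)
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    missing = [s for s in scores.index if s not in clin.index]
    if missing:
        raise ValueError(f"samples without clinical records: {missing[:5]}")
    clin = clin.loc[scores.index].copy()
    clin["pm_risk_score"] = scores
    levels = stratify(scores)
    clin["risk_level"] = levels

    sizes = levels.value_counts().to_dict()
    extreme = clin[clin["risk_level"].isin(["high", "low"])].copy()
    extreme["risk_high"] = (extreme["risk_level"] == "high").astype(int)

    stat, p = logrank_test(
        extreme[time_col], extreme[event_col], extreme["risk_level"]
    )
    uni = cox_fit(extreme, ["risk_high"], time_col=time_col, event_col=event_col)
    report = {
        "n": int(len(clin)),
        "group_sizes": {k: int(sizes.get(k, 0)) for k in ("high", "moderate", "low")},
        "logrank": {"statistic": stat, "p": p},
        "cox_univariate": uni.loc["risk_high"].to_dict(),
        "km": {
            g: df.to_dict(orient="list")
            for g, df in km_by_group(extreme, time_col, event_col, "risk_level").items()
        },
        "scores": {s: float(v) for s, v in scores.items()},
        "risk_level": {s: str(v) for s, v in levels.items()},
    }
    adjust = [c for c in adjust if c in clin.columns]
    if adjust:
        multi = cox_fit(
            extreme, ["risk_high"] + adjust, time_col=time_col, event_col=event_col
        )
        report["cox_adjusted"] = {
            cov: multi.loc[cov].to_dict() for cov in multi.index
        }
    return report
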