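"""Differential protein calling by two intersected tests.

Two independent procedures call tumor-vs-normal differential proteins:

(a) a SAM-style moderated test: per-protein statistic d = r / (s + s0),
    where r is the (paired or unpaired) mean log2 difference, s its standard
    error and s0 a small fudge constant stabilizing low-variance proteins.
    The null distribution of d comes from label permutations (sign flips of
    the paired differences in the paired design); a symmetric cutoff Delta
    on |d| is chosen as the smallest value whose estimated false discovery
    rate -- pi0 x expected false calls / observed calls, the expectation
    taken over the pooled permutation tail with a +1 pseudocount so the
    estimate is never exactly zero -- falls below the nominal level.
    Calls additionally require a fold-change criterion.

(b) a per-pair fold-change test: within each tumor/normal pair the vector
    of per-protein log2 fold changes is fit by a location-scale
    t-distribution and each protein receives a two-tail p-value; proteins
    significant with a consistent sign in enough pairs are called.

The final differential set is the intersection of (a) and (b).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

S0_PERCENTILE_GRID = np.arange(0, 100, 5)


def _moderated_stat_unpaired(x1: np.ndarray, x2: np.ndarray, s0: float):
    """d = (mean1 - mean2) / (pooled SE + s0) for proteins x samples blocks."""
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    s = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    r = m1 - m2
    denom = s + s0
    d = np.divide(r, denom, out=np.zeros_like(r), where=denom > 0)
    return d, r, s


def _moderated_stat_paired(diffs: np.ndarray, s0: float):
    """d = mean(diff) / (SE + s0) for a proteins x pairs difference block."""
    n = diffs.shape[1]
    r = diffs.mean(axis=1)
    s = diffs.std(axis=1, ddof=1) / math.sqrt(n)
    denom = s + s0
    d = np.divide(r, denom, out=np.zeros_like(r), where=denom > 0)
    return d, r, s


def _choose_s0(r: np.ndarray, s: np.ndarray, n_bins: int = 5):
    """Tusher-style fudge constant: the percentile of {s} minimizing the
    coefficient of variation of the MAD of d across s-quantile bins."""
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_bins)
    bins = [b for b in bins if b.size > 0]
    best_s0, best_cv = 0.0, np.inf
    for pct in S0_PERCENTILE_GRID:
        s0 = float(np.percentile(s, pct))
        denom = s + s0
        d = np.divide(r, denom, out=np.zeros_like(r), where=denom > 0)
        mads = []
        for b in bins:
            db = d[b]
            mads.append(np.median(np.abs(db - np.median(db))) * 1.4826)
        mads = np.asarray(mads)
        mu = mads.mean()
        if mu == 0:
            cv = np.inf
        else:
            cv = mads.std(ddof=1) / mu if len(mads) > 1 else 0.0
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, s0
    return best_s0


@dataclass
class SamResult:
    """Output of :func:`sam_test`: per-protein table plus permutation diagnostics."""

    table: pd.DataFrame          # d_stat, fold_change, q_value, called, direction
    s0: float
    delta: float                 # chosen |d| cutoff; inf if no cutoff meets the FDR
    perm_d: np.ndarray           # n_perm x n_proteins permuted statistics
    exhaustive: bool
    fdr: float
    fc: float | None

    @property
    def called_ids(self) -> set:
        return set(self.table.index[self.table["called"]])

    @property
    def universe(self) -> set:
        return set(self.table.index)


def sam_test(
    m: ExpressionMatrix,
    labels: pd.Series | dict | None = None,
    *,
    pairs: list[tuple[str, str]] | None = None,
    contrast: tuple | None = None,
    n_perm: int = 100,
    fdr: float = 0.05,
    fc: float | None = 1.5,
    seed: int | None = None,
    s0_percentile: float | None = None,
    pi0: float | str = 1.0,
    fc_matrix: pd.DataFrame | None = None,
) -> SamResult:
    """SAM-style moderated test with permutation FDR.

    Parameters
    ----------
    m : ExpressionMatrix
        log2 z-scored matrix.
    labels : mapping sample -> class (unpaired design), or None.
    pairs : list of (sample_1, sample_2) tuples (paired design: per-pair
        difference sample_1 - sample_2, null by random sign flips).
    contrast : (class_1, class_2) order for the unpaired difference
        mean(class_1) - mean(class_2); defaults to sorted class labels.
    n_perm : permutation count; when the number of distinct permutations is
        at most ``n_perm`` the full set is enumerated instead of sampled.
    fc : fold-change threshold on the linear scale (2**r); ``None`` disables.
    pi0 : proportion of null proteins; 1 (conservative) or ``"iqr"`` for the
        interquartile estimator from the permuted statistics.
    fc_matrix : optional log2-scale matrix (same protein/sample ids) from
        which the fold change is computed; use the unstandardized log2 FOT
        values here, since per-sample z-scoring rescales log2 differences
        by the cohort-wide spread.  Defaults to the test matrix itself.
    """
    m.require_state("log2z", "sam_test")
    if n_perm < 10:
        raise ValueError(f"n_perm must be >= 10, got {n_perm}")
    x = m.values
    proteins = m.data.index
    rng = np.random.default_rng(seed)

    if pairs is not None:
        pairs = list(pairs)
        flat = [s for pr in pairs for s in pr]
        if len(set(flat)) != len(flat):
            raise ValueError("pairs reuse a sample")
        if len(pairs) < 2:
            raise ValueError("need at least 2 pairs")
        col = {s: i for i, s in enumerate(m.sample_ids)}
        missing = [s for s in flat if s not in col]
        if missing:
            raise ValueError(f"pair samples not in matrix: {missing[:5]}")
        i1 = [col[a] for a, _ in pairs]
        i2 = [col[b] for _, b in pairs]
        diffs = x[:, i1] - x[:, i2]
        n = diffs.shape[1]
        _, r, s = _moderated_stat_paired(diffs, 0.0)
        s0 = (
            float(np.percentile(s, s0_percentile))
            if s0_percentile is not None
            else _choose_s0(r, s)
        )
        d, r, s = _moderated_stat_paired(diffs, s0)

        total = 2 ** n
        if total <= n_perm:
            signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
            exhaustive = True
        else:
            signs = rng.choice([1.0, -1.0], size=(n_perm, n))
            exhaustive = False
        # identity sign vector first: the observed statistics are taken from
        # that row so they share the exact floating-point path with the
        # permuted ones (ties at the observed cutoffs count consistently)
        signs = np.vstack([np.ones((1, n)), signs])
        # mean and variance under sign flips from fixed sufficient statistics
        ss = (diffs ** 2).sum(axis=1)                      # invariant to flips
        mean_p = (signs @ diffs.T) / n                     # (n_perm + 1) x p
        var_p = (ss[None, :] - n * mean_p ** 2) / (n - 1)
        var_p = np.maximum(var_p, 0.0)
        s_p = np.sqrt(var_p / n)
        denom = s_p + s0
        d_all = np.divide(mean_p, denom, out=np.zeros_like(mean_p), where=denom > 0)
        d, r, s = d_all[0], mean_p[0], s_p[0]
        perm_d = d_all[1:]
    else:
        if labels is None:
            raise ValueError("either labels or pairs must be given")
        lab = pd.Series(labels).reindex(m.sample_ids)
        if lab.isna().any():
            raise ValueError(f"samples without labels: {list(lab.index[lab.isna()])[:5]}")
        classes = sorted(lab.unique().tolist())
        if len(classes) != 2:
            raise ValueError(f"exactly two classes required, got {classes}")
        if contrast is None:
            contrast = tuple(classes)
        elif sorted(contrast) != classes:
            raise ValueError(f"contrast {contrast} does not match classes {classes}")
        g1 = np.array([lab[s] == contrast[0] for s in m.sample_ids])
        n1, n2 = int(g1.sum()), int((~g1).sum())
        if n1 < 2 or n2 < 2:
            raise ValueError(f"need >= 2 samples per class, got {n1} and {n2}")
        _, r, s = _moderated_stat_unpaired(x[:, g1], x[:, ~g1], 0.0)
        s0 = (
            float(np.percentile(s, s0_percentile))
            if s0_percentile is not None
            else _choose_s0(r, s)
        )
        d, r, s = _moderated_stat_unpaired(x[:, g1], x[:, ~g1], s0)

        n = n1 + n2
        total = math.comb(n, n1)
        if total <= n_perm:
            combos = itertools.combinations(range(n), n1)
            masks = np.zeros((total, n), dtype=bool)
            for j, cmb in enumerate(combos):
                masks[j, list(cmb)] = True
            exhaustive = True
        else:
            masks = np.zeros((n_perm, n), dtype=bool)
            for j in range(n_perm):
                masks[j, rng.permutation(n)[:n1]] = True
            exhaustive = False
        # identity mask first, as in the paired branch
        masks = np.vstack([g1[None, :], masks])
        xs = x.T                                            # n x p
        xs2 = xs ** 2
        tot = xs.sum(axis=0)
        tot2 = xs2.sum(axis=0)
        sum1 = masks.astype(float) @ xs                     # (n_perm + 1) x p
        ssq1 = masks.astype(float) @ xs2
        m1 = sum1 / n1
        m2 = (tot[None, :] - sum1) / n2
        sp2 = (tot2[None, :] - n1 * m1 ** 2 - n2 * m2 ** 2) / (n - 2)
        sp2 = np.maximum(sp2, 0.0)
        s_p = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        denom = s_p + s0
        d_all = np.divide(m1 - m2, denom, out=np.zeros_like(m1), where=denom > 0)
        d, r, s = d_all[0], m1[0] - m2[0], s_p[0]
        perm_d = d_all[1:]

    if isinstance(pi0, str):
        if pi0 != "iqr":
            raise ValueError(f"unknown pi0 estimator {pi0!r}")
        q25, q75 = np.percentile(perm_d, [25, 75])
        in_iqr = ((d >= q25) & (d <= q75)).sum()
        expected = 0.5 * d.size
        pi0_val = min(1.0, in_iqr / expected) if expected > 0 else 1.0
    else:
        pi0_val = float(pi0)

    # |d| rounded to 12 decimals: permutations that mirror each other have
    # exactly opposite statistics in exact arithmetic, and rounding makes
    # those ties count consistently despite float path differences
    abs_d = np.round(np.abs(d), 12)
    thresholds = np.unique(abs_d)                           # ascending
    observed = abs_d.size - np.searchsorted(np.sort(abs_d), thresholds, side="left")
    perm_sorted = np.sort(np.round(np.abs(perm_d), 12), axis=1)
    counts = perm_d.shape[1] - np.array(
        [np.searchsorted(row, thresholds, side="left") for row in perm_sorted]
    )
    # expected false calls from the pooled permutation tail, with a +1
    # pseudocount (Phipson-Smyth): the tail estimate is never exactly zero,
    # which would otherwise let a single extreme observed statistic be
    # called at an estimated FDR of 0 under a global null
    e_false = (counts.sum(axis=0) + 1.0) / (perm_d.shape[0] + 1.0)
    fdr_curve = np.minimum(
        np.divide(pi0_val * e_false, observed,
                  out=np.ones_like(e_false, dtype=float), where=observed > 0),
        1.0,
    )
    q_at_threshold = np.minimum.accumulate(fdr_curve)       # min FDR over cutoffs <= t
    idx = np.searchsorted(thresholds, abs_d)
    q = q_at_threshold[idx]

    meets = np.where(fdr_curve <= fdr)[0]
    delta = float(thresholds[meets[0]]) if meets.size else np.inf

    if fc_matrix is not None:
        fx = fc_matrix.reindex(index=proteins, columns=m.sample_ids)
        if fx.isna().any().any():
            raise ValueError("fc_matrix does not cover the test matrix ids")
        fxv = fx.to_numpy()
        if pairs is not None:
            r_fc = (fxv[:, i1] - fxv[:, i2]).mean(axis=1)
        else:
            r_fc = fxv[:, g1].mean(axis=1) - fxv[:, ~g1].mean(axis=1)
    else:
        r_fc = r
    fold = np.power(2.0, r_fc)
    if fc is not None:
        fc_ok = (fold >= fc) | (fold <= 1.0 / fc)
    else:
        fc_ok = np.ones_like(fold, dtype=bool)
    called = (abs_d >= delta) & fc_ok

    table = pd.DataFrame(
        {
            "d_stat": d,
            "fold_change": fold,
            "q_value": np.clip(q, 0.0, 1.0),
            "called": called,
            "direction": np.where(r > 0, "up", np.where(r < 0, "down", "none")),
        },
        index=proteins,
    )
    return SamResult(table=table, s0=s0, delta=delta, perm_d=perm_d,
                     exhaustive=exhaustive, fdr=fdr, fc=fc)


@dataclass
class PairFCResult:
    """Output of :func:`pairfc_test`."""

    pvalues: pd.DataFrame        # proteins x pairs
    lfc: pd.DataFrame            # proteins x pairs, centered log2 fold changes
    fit: pd.DataFrame            # per-pair location / scale / df
    called: pd.Series
    direction: pd.Series
    p_thresh: float
    min_frac: float

    @property
    def called_ids(self) -> set:
        return set(self.called.index[self.called])

    @property
    def universe(self) -> set:
        return set(self.called.index)


def pairfc_test(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    p_thresh: float = 0.05,
    min_frac: float = 0.5,
    df: float = 4.0,
    fit: str = "robust",
) -> PairFCResult:
    """Per-pair log2 fold-change test against a fitted t-distribution.

    For each tumor/normal pair the per-protein log2 fold changes are fit by
    a location-scale t (``fit='robust'``: location = median, scale =
    1.4826 x MAD, fixed df; ``fit='ml'``: full maximum-likelihood fit) and
    two-tail p-values are computed.  A protein is called when it is
    significant in at least one pair, every significant pair agrees in
    sign, and that direction holds in at least ``min_frac`` of all pairs.
    A single pair can only flag fold changes in the far tail of that pair's
    distribution, so the cross-pair rule asks for directional consistency
    rather than per-pair significance everywhere.
    """
    if list(tumor.data.index) != list(normal.data.index):
        raise ValueError("tumor and normal matrices must share the protein index")
    t_samples = [a for a, _ in pairs]
    n_samples = [b for _, b in pairs]
    if len(set(t_samples)) != len(t_samples):
        raise ValueError("a tumor sample is matched to more than one normal")
    missing = [s for s in t_samples if s not in tumor.data.columns] + [
        s for s in n_samples if s not in normal.data.columns
    ]
    if missing:
        raise ValueError(f"unmatched pair samples: {missing[:5]}")

    proteins = tumor.data.index
    pair_names = [f"{a}|{b}" for a, b in pairs]
    pvals = np.empty((len(proteins), len(pairs)))
    lfc_centered = np.empty_like(pvals)
    fits = []
    for j, (a, b) in enumerate(pairs):
        lfc = tumor.data[a].to_numpy() - normal.data[b].to_numpy()
        if fit == "robust":
            loc = float(np.median(lfc))
            scale = float(1.4826 * np.median(np.abs(lfc - loc)))
            nu = df
        elif fit == "ml":
            nu, loc, scale = stats.t.fit(lfc)
        else:
            raise ValueError(f"unknown fit mode {fit!r}")
        if scale == 0:
            raise ValueError(f"degenerate fold-change distribution (zero scale) in pair {a}|{b}")
        z = (lfc - loc) / scale
        pvals[:, j] = 2.0 * stats.t.sf(np.abs(z), nu)
        lfc_centered[:, j] = lfc - loc
        fits.append({"pair": f"{a}|{b}", "location": loc, "scale": scale, "df": nu})

    sig = pvals < p_thresh
    pos = lfc_centered > 0
    n_pairs = len(pairs)
    n_sig = sig.sum(axis=1)
    n_sig_up = (sig & pos).sum(axis=1)
    n_sig_down = (sig & ~pos).sum(axis=1)
    one_sign = (n_sig_up == n_sig) | (n_sig_down == n_sig)
    up = n_sig_up == n_sig
    frac_dir = np.where(up, pos.sum(axis=1), (~pos).sum(axis=1)) / n_pairs
    called = (n_sig >= 1) & one_sign & (frac_dir >= min_frac)
    direction = np.where(called & up, "up", np.where(called, "down", "none"))

    return PairFCResult(
        pvalues=pd.DataFrame(pvals, index=proteins, columns=pair_names),
        lfc=pd.DataFrame(lfc_centered, index=proteins, columns=pair_names),
        fit=pd.DataFrame(fits),
        called=pd.Series(called, index=proteins),
        direction=pd.Series(direction, index=proteins),
        p_thresh=p_thresh,
        min_frac=min_frac,
    )


def overlap_deps(a, b) -> list:
    """Intersect the call sets of two procedures sharing a protein universe.

    ``a`` and ``b`` expose ``called_ids`` and ``universe`` (as SamResult and
    PairFCResult do).  Returns the sorted intersected protein ids.
    """
    if a.universe != b.universe:
        raise ValueError("protein universes of the two tests differ")
    return sorted(a.called_ids & b.called_ids)


def combine_dep(sam: SamResult, pfc: PairFCResult) -> pd.DataFrame:
    """Per-protein table merging both tests and their intersection."""
    if set(sam.table.index) != set(pfc.called.index):
        raise ValueError("protein universes of the two tests differ")
    tab = sam.table.copy()
    tab = tab.rename(columns={"called": "called_a"})
    tab["called_b"] = pfc.called.reindex(tab.index)
    tab["called_final"] = tab["called_a"] & tab["called_b"]
    return tab


def group_dep(
    m_tumor: ExpressionMatrix,
    pm_labels: pd.Series | dict,
    deps: set,
    *,
    contrast: tuple | None = None,
    n_perm: int = 100,
    fdr: float = 0.05,
    fc: float | None = 1.5,
    seed: int | None = None,
    fc_matrix: pd.DataFrame | None = None,
) -> SamResult:
    """Second-level unpaired comparison (PM vs PM-free tumors) on first-level DEPs.

    Every protein in the matrix must already be a called tumor-vs-normal
    differential protein.
    """
    extra = [p for p in m_tumor.protein_ids if p not in deps]
    if extra:
        raise ValueError(f"proteins not in the first-level DEP set: {extra[:5]}")
    return sam_test(
        m_tumor, pm_labels, contrast=contrast, n_perm=n_perm, fdr=fdr, fc=fc,
        seed=seed, fc_matrix=fc_matrix,
    )
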