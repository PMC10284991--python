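import itertools
import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pmsig import ExpressionMatrix, sam_test, pairfc_test, overlap_deps, combine_dep, group_dep
from tests.conftest import make_matrix


def unpaired_d_oracle(x, idx1, idx2, s0):
    """Straight-loop moderated statistic for one label split."""
    out = []
    for row in x:
        a, b = row[list(idx1)], row[list(idx2)]
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        s = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        out.append((a.mean() - b.mean()) / (s + s0))
    return np.array(out)


class TestSamTest:
    def test_exhaustive_permutations_match_enumeration_oracle(self, rng):
        """3-vs-3 toy: the permutation null and FDR curve equal full enumeration."""
        x = rng.normal(0, 1, size=(8, 6))
        m = make_matrix(x)
        labels = {s: ("A" if i < 3 else "B") for i, s in enumerate(m.sample_ids)}
        res = sam_test(m, labels, n_perm=100, fc=None, seed=0)
        assert res.exhaustive and res.perm_d.shape == (20, 8)

        # independent oracle: all 20 splits of 6 samples into 3+3
        perm_oracle = np.array(
            [
                unpaired_d_oracle(x, c, tuple(set(range(6)) - set(c)), res.s0)
                for c in itertools.combinations(range(6), 3)
            ]
        )
        np.testing.assert_allclose(
            np.sort(res.perm_d, axis=0), np.sort(perm_oracle, axis=0), atol=1e-12
        )

        # FDR estimates: pooled-tail expected false calls (with +1
        # pseudocount) over observed calls at each cutoff
        d_obs = res.table["d_stat"].to_numpy()
        n_perm = perm_oracle.shape[0]
        for i, t in enumerate(np.sort(np.unique(np.round(np.abs(d_obs), 12)))):
            observed = (np.round(np.abs(d_obs), 12) >= t).sum()
            e_false = ((np.round(np.abs(perm_oracle), 12) >= t).sum() + 1.0) / (n_perm + 1.0)
            fdr_oracle = min(1.0, e_false / observed)
            q_imp = res.table["q_value"].to_numpy()[np.abs(d_obs) == t]
            assert (q_imp <= fdr_oracle + 1e-12).all()

    def test_identical_groups_yield_no_calls(self, rng):
        block = rng.normal(0, 1, size=(30, 4))
        m = make_matrix(np.hstack([block, block]))
        labels = {s: ("A" if i < 4 else "B") for i, s in enumerate(m.sample_ids)}
        res = sam_test(m, labels, seed=1)
        assert res.table["called"].sum() == 0

    def test_power_on_planted_shift(self):
        """50 of 500 proteins shifted by 2 log2 units, 10 vs 10: >=80% recalled."""
        recalls = []
        for seed in range(5):
            g = np.random.default_rng(seed)
            x = g.normal(0, 1, size=(500, 20))
            x[:50, :10] += 2.0
            m = make_matrix(x)
            labels = {s: ("A" if i < 10 else "B") for i, s in enumerate(m.sample_ids)}
            res = sam_test(m, labels, contrast=("A", "B"), seed=seed)
            called = res.table["called"].to_numpy()
            recalls.append(called[:50].mean())
        assert np.mean(recalls) >= 0.8

    def test_statistic_invariant_to_order_and_shift(self, rng):
        x = rng.normal(0, 1, size=(40, 12))
        m = make_matrix(x)
        labels = {s: ("A" if i < 6 else "B") for i, s in enumerate(m.sample_ids)}
        res = sam_test(m, labels, seed=3)

        perm = rng.permutation(40)
        m2 = ExpressionMatrix(m.data.iloc[perm], "log2z")
        res2 = sam_test(m2, labels, seed=3)
        pd.testing.assert_series_equal(
            res.table["d_stat"].sort_index(), res2.table["d_stat"].sort_index()
        )

        shifted = m.data.copy()
        shifted.iloc[7] += 5.0  # constant added to every sample of one protein
        res3 = sam_test(ExpressionMatrix(shifted, "log2z"), labels, seed=3)
        np.testing.assert_allclose(
            res.table["d_stat"].to_numpy(), res3.table["d_stat"].to_numpy(), atol=1e-9
        )

    def test_paired_mode_uses_sign_flips(self, rng):
        x = rng.normal(0, 1, size=(20, 8))
        x[:5, :4] += 1.5
        m = make_matrix(x)
        pairs = [(f"S{i + 1:02d}", f"S{i + 5:02d}") for i in range(4)]
        res = sam_test(m, pairs=pairs, n_perm=100, seed=0)
        assert res.exhaustive and res.perm_d.shape[0] == 16  # 2^4 sign vectors

    def test_input_validation(self, rng):
        m = make_matrix(rng.normal(size=(5, 4)))
        labels = {s: ("A" if i < 2 else "B") for i, s in enumerate(m.sample_ids)}
        with pytest.raises(ValueError, match="n_perm"):
            sam_test(m, labels, n_perm=5)
        bad = {s: "A" for s in m.sample_ids}
        with pytest.raises(ValueError, match="two classes"):
            sam_test(m, bad)


class TestPairFCTest:
    def test_gene_at_location_has_p_one(self):
        lfc = np.array([0.2, -0.3, 0.1, 0.1, 0.5, -0.2, 0.1])
        tumor = make_matrix(lfc[:, None], samples=["T1"])
        normal = make_matrix(np.zeros((7, 1)), samples=["N1"])
        res = pairfc_test(tumor, normal, [("T1", "N1")])
        at_loc = np.isclose(lfc, np.median(lfc))
        assert np.allclose(res.pvalues.to_numpy()[at_loc], 1.0)

    def test_outlier_detected_and_pvalues_match_t_oracle(self):
        lfc = np.array([0.0, 0.1, -0.1, 0.05, -0.05, 5.0])
        tumor = make_matrix(lfc[:, None], samples=["T1"])
        normal = make_matrix(np.zeros((6, 1)), samples=["N1"])
        res = pairfc_test(tumor, normal, [("T1", "N1")])
        p = res.pvalues.to_numpy().ravel()
        assert p[-1] < 0.05 and (p[:-1] > 0.2).all()
        # independent oracle: evaluate the t CDF at the standardized values
        loc = np.median(lfc)
        scale = 1.4826 * np.median(np.abs(lfc - loc))
        oracle = 2 * stats.t.sf(np.abs(lfc - loc) / scale, 4)
        np.testing.assert_allclose(p, oracle, atol=1e-12)
        assert res.called.iloc[-1] and not res.called.iloc[:-1].any()

    def test_opposite_sign_significant_pairs_not_called(self, rng):
        base = rng.normal(0, 0.1, size=(50, 2))
        base[0] = [5.0, -5.0]  # strongly up in pair 1, down in pair 2
        tumor = make_matrix(base, samples=["T1", "T2"])
        normal = make_matrix(np.zeros((50, 2)), samples=["N1", "N2"])
        res = pairfc_test(tumor, normal, [("T1", "N1"), ("T2", "N2")], min_frac=0.5)
        assert (res.pvalues.iloc[0] < 0.05).all()
        assert not res.called.iloc[0]

    def test_degenerate_scale_errors(self):
        tumor = make_matrix(np.ones((5, 1)), samples=["T1"])
        normal = make_matrix(np.zeros((5, 1)), samples=["N1"])
        with pytest.raises(ValueError, match="zero scale"):
            pairfc_test(tumor, normal, [("T1", "N1")])

    def test_unmatched_pair_errors(self, rng):
        tumor = make_matrix(rng.normal(size=(5, 1)), samples=["T1"])
        normal = make_matrix(rng.normal(size=(5, 1)), samples=["N1"])
        with pytest.raises(ValueError, match="unmatched"):
            pairfc_test(tumor, normal, [("T1", "NX")])


class TestOverlapAndGroup:
    def test_overlap_examples(self):
        uni = {f"p{i}" for i in range(1, 6)}
        a = SimpleNamespace(called_ids={"p1", "p2", "p3"}, universe=uni)
        b = SimpleNamespace(called_ids={"p2", "p3", "p4"}, universe=uni)
        assert overlap_deps(a, b) == ["p2", "p3"]
        empty = SimpleNamespace(called_ids=set(), universe=uni)
        assert overlap_deps(a, empty) == []
        with pytest.raises(ValueError, match="universes"):
            overlap_deps(a, SimpleNamespace(called_ids=set(), universe={"x"}))

    def test_overlap_matches_set_oracle_on_random_calls(self, rng):
        uni = {f"p{i}" for i in range(100)}
        ca = set(rng.choice(sorted(uni), 40, replace=False))
        cb = set(rng.choice(sorted(uni), 40, replace=False))
        a = SimpleNamespace(called_ids=ca, universe=uni)
        b = SimpleNamespace(called_ids=cb, universe=uni)
        assert overlap_deps(a, b) == sorted(ca & cb)

    def test_combine_final_is_conjunction(self, cohort):
        sam = sam_test(cohort.mz, pairs=cohort.pairs, seed=2,
                       fc_matrix=cohort.log2_fot)
        pfc = pairfc_test(cohort.tumor, cohort.normal, cohort.pairs)
        tab = combine_dep(sam, pfc)
        assert (tab["called_final"] == (tab["called_a"] & tab["called_b"])).all()
        assert tab["called_final"].sum() <= min(tab["called_a"].sum(), tab["called_b"].sum())

    def test_group_dep_requires_dep_restriction(self, cohort):
        with pytest.raises(ValueError, match="first-level"):
            group_dep(cohort.tumor, cohort.pm_labels, deps={"P0001"})

    def test_group_dep_null_labels_give_no_calls(self, cohort, rng):
        deps = set(cohort.tumor.protein_ids[:100])
        sub = cohort.tumor.subset(proteins=sorted(deps))
        shuffled = pd.Series(
            rng.permutation(cohort.pm_labels.to_numpy()), index=cohort.pm_labels.index
        )
        res = group_dep(sub, shuffled, deps, contrast=(1, 0), seed=0)
        assert res.table["called"].sum() <= 3


class TestGroupDepPower:
    def test_strong_pm_module_recovered_at_group_level(self):
        """PM-vs-PM-free comparison recalls nearly the whole planted module
        when the per-protein signal-to-noise is 1.5."""
        from pmsig import SimulationConfig, simulate_cohort
        from pmsig.preprocess import fot_normalize, filter_proteins, log2_zscore

        recalls = []
        for seed in range(5):
            cfg = SimulationConfig(target_snr=1.5, seed=seed)
            expr, pep, samples, truth = simulate_cohort(cfg)
            filt, _ = filter_proteins(fot_normalize(expr), pep)
            mz = log2_zscore(filt)
            lf = pd.DataFrame(
                np.log2(np.maximum(filt.values, 1e-8)),
                index=filt.data.index, columns=filt.data.columns,
            )
            si = samples.set_index("sample_id")
            tum = [s for s in mz.sample_ids if si.loc[s, "tissue"] == "T"]
            deps = truth.dep_ids & set(mz.protein_ids)
            sub = mz.subset(samples=tum).subset(proteins=sorted(deps))
            res = group_dep(sub, si.loc[tum, "pm_status"], deps, contrast=(1, 0),
                            seed=seed, fc_matrix=lf[tum])
            module = truth.module_ids & set(sub.protein_ids)
            recalls.append(len(res.called_ids & module) / len(module))
        assert np.mean(recalls) >= 0.9
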