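import numpy as np
import pandas as pd
import pytest

from pmsig import auc, cv_auc, best_panel_size, enumerate_and_score, frequency_select
from tests.conftest import make_matrix


def auc_pairs_oracle(scores, labels):
    """O(n^2) all-pairs count: wins + half ties over positive x negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else 0.5 if a == b else 0.0
    return total / (len(pos) * len(neg))


def labeled_matrix(rng, n_proteins, n_samples, informative=None, effect=2.0, n_pos=None):
    """Matrix plus binary labels; `informative` rows get `effect` added in positives."""
    n_pos = n_pos if n_pos is not None else n_samples // 2
    x = rng.normal(0, 1, size=(n_proteins, n_samples))
    if informative:
        x[np.ix_(informative, range(n_pos))] += effect
    m = make_matrix(x)
    labels = pd.Series([1] * n_pos + [0] * (n_samples - n_pos), index=m.sample_ids)
    return m, labels


class TestAuc:
    def test_perfect_separation(self):
        assert auc([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0]) == 1.0

    def test_null_is_half(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert abs(auc(scores, labels) - 0.5) < 0.05

    def test_matches_all_pairs_oracle_with_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 200))
            scores = rng.integers(0, 10, size=n).astype(float)  # heavy ties
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=max(1, n // 3), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            assert auc(scores, labels) == pytest.approx(
                auc_pairs_oracle(scores, labels), abs=1e-12
            )

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([1, 2, 3], [1, 1, 1])


class TestCvAuc:
    def test_label_feature_scores_one(self):
        x = np.array([[1.0] * 10 + [0.0] * 10])
        m = make_matrix(x)
        labels = pd.Series([1] * 10 + [0] * 10, index=m.sample_ids)
        for model in ("logistic", "gbtree"):
            res = cv_auc(m, labels, folds=5, seed=0, model=model)
            assert res.mean_cv_auc == 1.0

    def test_noise_feature_near_half(self):
        aucs = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            m = make_matrix(g.normal(size=(1, 30)))
            labels = pd.Series([1] * 15 + [0] * 15, index=m.sample_ids)
            aucs.append(cv_auc(m, labels, seed=seed, model="logistic").mean_cv_auc)
        assert 0.3 <= np.mean(aucs) <= 0.7

    def test_deterministic_given_seed(self, rng):
        m, labels = labeled_matrix(rng, 4, 24, informative=[0])
        a = cv_auc(m, labels, seed=5, model="gbtree")
        b = cv_auc(m, labels, seed=5, model="gbtree")
        assert a.fold_aucs == b.fold_aucs
        assert a.mean_cv_auc == pytest.approx(np.mean(a.fold_aucs), abs=1e-12)

    def test_small_class_errors(self, rng):
        m, _ = labeled_matrix(rng, 3, 8)
        labels = pd.Series([1, 1, 1, 0, 0, 0, 0, 0], index=m.sample_ids)
        with pytest.raises(ValueError, match="folds"):
            cv_auc(m, labels, folds=5)


class TestBestPanelSize:
    def test_pool_of_one(self, rng):
        m, labels = labeled_matrix(rng, 1, 20, informative=[0])
        size, ranked, _ = best_panel_size(m, labels, m.protein_ids, model="logistic")
        assert size == 1 and ranked == m.protein_ids

    def test_identical_copies_tie_to_smallest(self, rng):
        row = rng.normal(size=20)
        row[:10] += 2.0
        m = make_matrix(np.vstack([row] * 4))
        labels = pd.Series([1] * 10 + [0] * 10, index=m.sample_ids)
        size, _, scores = best_panel_size(m, labels, m.protein_ids, model="logistic")
        assert size == 1  # duplicates add nothing; ties prefer smaller panels

    def test_recovers_informative_subset_size(self):
        good = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            m, labels = labeled_matrix(g, 5, 60, informative=[0, 1], effect=1.5)
            size, _, _ = best_panel_size(m, labels, m.protein_ids, seed=seed,
                                         model="logistic")
            if size in (2, 3):
                good += 1
        assert good >= 8


class TestEnumerateAndScore:
    def test_exhaustive_counts_all_subsets(self, rng):
        m, labels = labeled_matrix(rng, 5, 20, informative=[0])
        scored, mode = enumerate_and_score(
            m, labels, m.protein_ids, size_range=(1, 5), budget=1000,
            model="logistic", seed=0,
        )
        assert mode == "exhaustive" and len(scored) == 31  # 2^5 - 1

    def test_sampling_respects_budget_and_distinctness(self, rng):
        m, labels = labeled_matrix(rng, 12, 20, informative=[0, 1])
        scored, mode = enumerate_and_score(
            m, labels, m.protein_ids, size_range=(3, 10), budget=50,
            model="logistic", seed=0,
        )
        assert mode == "sampled" and len(scored) == 50
        assert len({cs.combo for cs in scored}) == 50

    def test_ranking_matches_rescoring_oracle(self, rng):
        m, labels = labeled_matrix(rng, 3, 20, informative=[0], effect=3.0)
        scored, _ = enumerate_and_score(
            m, labels, m.protein_ids, size_range=(1, 3), budget=100,
            model="logistic", seed=3,
        )
        assert len(scored) == 7
        rescored = {
            cs.combo: cv_auc(m, labels, cs.combo, seed=3, model="logistic").mean_cv_auc
            for cs in scored
        }
        for cs in scored:
            assert cs.mean_cv_auc == pytest.approx(rescored[cs.combo], abs=1e-12)

    def test_budget_validation(self, rng):
        m, labels = labeled_matrix(rng, 3, 12)
        with pytest.raises(ValueError, match="budget"):
            enumerate_and_score(m, labels, m.protein_ids, budget=0, size_range=(1, 2))

    def test_informative_duplicate_never_lowers_best_auc(self, rng):
        m, labels = labeled_matrix(rng, 4, 24, informative=[0], effect=4.0)
        scored, _ = enumerate_and_score(m, labels, m.protein_ids,
                                        size_range=(1, 4), budget=100,
                                        model="logistic", seed=1)
        best = max(cs.mean_cv_auc for cs in scored)
        dup = m.data.copy()
        dup.loc["PDUP"] = labels.to_numpy().astype(float)  # perfectly informative
        from pmsig import ExpressionMatrix

        m2 = ExpressionMatrix(dup, "log2z")
        scored2, _ = enumerate_and_score(m2, labels, m2.protein_ids,
                                         size_range=(1, 4), budget=100,
                                         model="logistic", seed=1)
        assert max(cs.mean_cv_auc for cs in scored2) >= best


class TestFrequencySelect:
    def test_ubiquitous_protein_ranks_first(self, rng):
        m, labels = labeled_matrix(rng, 4, 20, informative=[0], effect=3.0)
        scored, mode = enumerate_and_score(m, labels, m.protein_ids,
                                           size_range=(2, 3), budget=100,
                                           model="logistic", seed=0)
        # keep only combos containing the first protein
        keep = [cs for cs in scored if "P001" in cs.combo]
        rep = frequency_select(keep, m, labels, top_n=500, panel_size=2, mode=mode)
        assert rep.panel[0] == "P001"
        assert rep.frequency["P001"] == len(keep)

    def test_fewer_combos_than_top_n_all_retained(self, rng):
        m, labels = labeled_matrix(rng, 3, 16, informative=[0])
        scored, mode = enumerate_and_score(m, labels, m.protein_ids,
                                           size_range=(1, 3), budget=100,
                                           model="logistic", seed=0)
        rep = frequency_select(scored, m, labels, top_n=500, panel_size=3, mode=mode)
        assert len(rep.top_combos) == 7

    def test_insufficient_distinct_proteins_errors(self, rng):
        m, labels = labeled_matrix(rng, 3, 16, informative=[0])
        scored, mode = enumerate_and_score(m, labels, m.protein_ids,
                                           size_range=(1, 2), budget=100,
                                           model="logistic", seed=0)
        with pytest.raises(ValueError, match="panel"):
            frequency_select(scored, m, labels, panel_size=10, mode=mode)

    def test_planted_informative_proteins_dominate_panel(self):
        """Half the pool is informative; the selected panel should be mostly planted."""
        overlaps = []
        for seed in range(5):
            g = np.random.default_rng(seed)
            m, labels = labeled_matrix(
                g, 12, 24, informative=list(range(6)), effect=1.8
            )
            scored, mode = enumerate_and_score(
                m, labels, m.protein_ids, size_range=(3, 4), budget=300,
                model="logistic", seed=seed,
            )
            rep = frequency_select(scored, m, labels, top_n=100, panel_size=6,
                                   mode=mode, seed=seed)
            overlaps.append(len(set(rep.panel) & set(m.protein_ids[:6])))
        assert np.mean(overlaps) >= 4.8  # >= 80% of a 6-protein panel
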