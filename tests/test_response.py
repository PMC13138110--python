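"""Dose-response models, AUC, and rank statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from rptdose.response import (
    crossval_auc,
    fit_logistic_2d,
    fit_quality,
    fit_sigmoid,
    fit_svm_rbf,
    group_patients,
    make_svm_estimator,
    mann_whitney_auc,
    sigmoid_probability,
    spearman,
    wilcoxon_signed_rank,
    wilcoxon_rank_sum,
)


class TestGrouping:
    @pytest.mark.parametrize("n,sizes", [(73, [11] * 6 + [7]), (11, [11]), (25, [11, 11, 3]), (44, [11] * 4)])
    def test_group_sizes(self, n, sizes, rng):
        groups = group_patients(rng.uniform(0, 300, n), rng.random(n) < 0.4)
        assert [g.n for g in groups] == sizes

    def test_partition_and_sorted_medians(self, rng):
        vals = rng.uniform(0, 300, 60)
        groups = group_patients(vals, rng.random(60) < 0.4)
        members = list(itertools.chain.from_iterable(g.member_indices for g in groups))
        assert sorted(members) == list(range(60))
        medians = [g.median_metric for g in groups]
        assert medians == sorted(medians)

    def test_too_few_patients(self):
        with pytest.raises(ValueError, match="at least 11"):
            group_patients([1.0] * 10, [True] * 10)

    def test_stable_tie_break(self):
        groups = group_patients([5.0] * 12, [True] * 11 + [False])
        assert groups[0].member_indices == tuple(range(11))


class TestFitQuality:
    def test_perfect_fit(self):
        q = fit_quality([0, 50, 100], [0, 50, 100])
        assert q.r_squared == 1.0 and q.rmse == 0.0

    def test_mean_predictor_zero_r2(self):
        q = fit_quality([0, 50, 100], [50, 50, 50])
        assert q.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        q = fit_quality([0, 50, 100], [10, 50, 90])
        assert q.r_squared == pytest.approx(0.96, abs=1e-12)
        assert q.rmse == pytest.approx(np.sqrt(200.0 / 3.0), abs=1e-9)

    def test_zero_variance_flagged(self):
        q = fit_quality([40, 40, 40], [40, 41, 39])
        assert not q.r2_defined


class TestSigmoidFit:
    def test_noiseless_parameter_recovery(self):
        """Points generated on the curve at (Pmax=100, Dhalf=135, k=58)."""
        cad = np.linspace(20, 280, 8)
        pct = np.asarray(sigmoid_probability(cad, 100.0, 135.0, 58.0))
        groups = [
            type("G", (), {"median_metric": c, "pct_pr": p, "n": 11})()
            for c, p in zip(cad, pct)
        ]
        model, quality = fit_sigmoid(groups)
        assert model.pmax == pytest.approx(100.0, rel=1e-4)
        assert model.dhalf == pytest.approx(135.0, rel=1e-4)
        assert model.k == pytest.approx(58.0, rel=1e-4)
        assert quality.r_squared == pytest.approx(1.0, abs=1e-9)
        assert quality.rmse == pytest.approx(0.0, abs=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        """Noisy grouped points: fit SSE agrees with a dense parameter grid."""
        cad = np.linspace(10, 290, 9)
        pct = np.clip(
            np.asarray(sigmoid_probability(cad, 90.0, 140.0, 50.0)) + rng.normal(0, 8, 9),
            0, 100,
        )
        groups = [
            type("G", (), {"median_metric": c, "pct_pr": p, "n": 11})()
            for c, p in zip(cad, pct)
        ]
        model, _ = fit_sigmoid(groups)
        fit_sse = np.sum((np.asarray(model.predict(cad)) - pct) ** 2)

        best = np.inf
        for pmax in np.linspace(50, 100, 51):
            for dhalf in np.linspace(50, 250, 101):
                for k in np.geomspace(10, 200, 61):
                    pred = pmax / (1 + np.exp(-(cad - dhalf) / k))
                    best = min(best, np.sum((pred - pct) ** 2))
        assert fit_sse <= best * (1 + 1e-4)

    def test_too_few_groups(self):
        groups = [type("G", (), {"median_metric": c, "pct_pr": 50.0})() for c in (1.0, 2.0)]
        with pytest.raises(ValueError, match="3 groups"):
            fit_sigmoid(groups)


class TestLogistic2D:
    def test_uninformative_features(self, rng):
        """Independent labels: slopes ~0, intercept ~ log-odds of the rate."""
        n = 10_000
        cad = rng.uniform(0, 300, n)
        delta = rng.uniform(-60, 20, n)
        y = rng.random(n) < 0.4
        m = fit_logistic_2d(cad, delta, y)
        rate = y.mean()
        assert m.beta0 == pytest.approx(np.log(rate / (1 - rate)), abs=0.15)
        assert abs(m.beta1) < 0.001 and abs(m.beta2) < 0.01
        assert not m.separation_flag

    def test_parameter_recovery(self, rng):
        n = 10_000
        cad = rng.uniform(0, 300, n)
        delta = rng.uniform(-60, 20, n)
        z = -2.0 + 0.02 * cad - 0.03 * delta
        y = rng.random(n) < 1 / (1 + np.exp(-z))
        m = fit_logistic_2d(cad, delta, y)
        assert m.beta0 == pytest.approx(-2.0, rel=0.10)
        assert m.beta1 == pytest.approx(0.02, rel=0.10)
        assert m.beta2 == pytest.approx(-0.03, rel=0.10)

    def test_duplication_invariance(self, rng):
        cad = rng.uniform(0, 300, 200)
        delta = rng.uniform(-60, 20, 200)
        y = rng.random(200) < 1 / (1 + np.exp(-(-1 + 0.01 * cad)))
        m1 = fit_logistic_2d(cad, delta, y)
        m2 = fit_logistic_2d(np.tile(cad, 2), np.tile(delta, 2), np.tile(y, 2))
        assert m1.beta0 == pytest.approx(m2.beta0, rel=1e-5)
        assert m1.beta1 == pytest.approx(m2.beta1, rel=1e-5)

    def test_separation_flagged(self):
        cad = np.array([0, 10, 20, 200, 210, 220], dtype=float)
        y = np.array([False, False, False, True, True, True])
        m = fit_logistic_2d(cad, np.zeros(6), y)
        assert m.separation_flag

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            fit_logistic_2d([1.0, 2.0], [0.0, 0.0], [True, True])


class TestSVM:
    def test_separable_training_accuracy(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [5, 5], [5, 6], [6, 5]], dtype=float)
        y = [False, False, False, True, True, True]
        clf = fit_svm_rbf(X, y)
        assert (clf.predict(X) == np.asarray(y, dtype=int)).all()

    def test_xor_needs_kernel(self, rng):
        """RBF separates the XOR pattern; a linear boundary cannot beat 75%."""
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        X = np.vstack([c + rng.normal(0, 0.05, (25, 2)) for c in centers])
        y = np.array([0] * 50 + [1] * 50)
        rbf = fit_svm_rbf(X, y, c_param=10.0)
        assert (rbf.predict(X) == y).mean() == 1.0
        linear = make_pipeline(StandardScaler(), SVC(kernel="linear")).fit(X, y)
        assert (linear.predict(X) == y).mean() <= 0.75

    def test_label_flip_negates_scores(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1], [2, 2], [3, 2], [2, 3]])
        y = np.array([0, 0, 0, 1, 1, 1])
        s_pos = fit_svm_rbf(X, y).decision_function(X)
        s_neg = fit_svm_rbf(X, 1 - y).decision_function(X)
        # sign symmetry up to the SVC solver tolerance
        assert np.allclose(s_pos, -s_neg, atol=1e-2)
        assert np.all(np.sign(s_pos) == -np.sign(s_neg))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            fit_svm_rbf(np.zeros((3, 2)), [1, 1, 1])


class TestAUC:
    def test_perfect_scores(self):
        y = [0, 0, 1, 1, 0, 1]
        assert mann_whitney_auc(np.asarray(y, float), np.asarray(y, bool)) == 1.0

    def test_random_scores_near_half(self, rng):
        y = rng.random(10_000) < 0.4
        s = rng.random(10_000)
        assert mann_whitney_auc(s, y) == pytest.approx(0.5, abs=0.02)

    def test_pairwise_ordering_oracle(self, rng):
        """AUC equals the fraction of correctly ordered pos/neg pairs (ties 1/2)."""
        y = rng.random(50) < 0.4
        if not y.any() or y.all():
            y[:3] = [True, True, False]
        s = np.round(rng.random(50), 1)  # coarse scores force ties
        pairs = [
            1.0 if sp > sn else 0.5 if sp == sn else 0.0
            for sp in s[y]
            for sn in s[~y]
        ]
        assert mann_whitney_auc(s, y) == pytest.approx(np.mean(pairs), abs=1e-12)
        assert mann_whitney_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        """Scoring patients by the fitted sigmoid equals scoring by cAD itself."""
        cad = rng.uniform(0, 300, 80)
        y = rng.random(80) < np.asarray(sigmoid_probability(cad, 100, 135, 58)) / 100
        if not y.any() or y.all():
            y[:2] = [True, False]
        scores = np.asarray(sigmoid_probability(cad, 100.0, 135.0, 58.0))
        assert mann_whitney_auc(scores, y) == mann_whitney_auc(cad, y)


class TestCrossval:
    def test_stratification_and_pooling(self, rng):
        n = 120
        X = rng.normal(size=(n, 2))
        y = rng.random(n) < 0.4
        X[y, 0] += 1.5
        ev = crossval_auc(make_svm_estimator(), X, y, n_folds=5, seed=3)
        assert 0.5 < ev.auc <= 1.0
        assert len(ev.per_fold_auc) == 5
        # stratified folds: class counts per fold balanced within 1
        for fold in range(5):
            in_fold = ev.fold_assignment == fold
            assert abs(y[in_fold].mean() - y.mean()) < 0.1

    def test_class_too_small(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.array([True] * 3 + [False] * 17)
        with pytest.raises(ValueError, match="at least 5"):
            crossval_auc(make_svm_estimator(), X, y, n_folds=5, seed=0)

    def test_seed_reproducible(self, rng):
        X = rng.normal(size=(60, 2))
        y = rng.random(60) < 0.5
        X[y, 1] -= 1.0
        a = crossval_auc(make_svm_estimator(), X, y, seed=7)
        b = crossval_auc(make_svm_estimator(), X, y, seed=7)
        assert a.auc == b.auc and (a.fold_assignment == b.fold_assignment).all()


class TestRankStats:
    def test_identical_pairs_flagged(self):
        stat, p, flag = wilcoxon_signed_rank([1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5])
        assert flag and p == 1.0

    def test_monotone_spearman(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 25, 30, 100])
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_signed_rank_vs_permutation_oracle(self, rng):
        """Two-sided signed-rank p-value vs full sign-flip enumeration at n=10."""
        x = rng.normal(0.4, 1.0, 10)
        diffs = x
        ranks = stats.rankdata(np.abs(diffs))
        w_obs = ranks[diffs > 0].sum()
        n = len(diffs)
        w_all = np.array(
            [ranks[np.array(signs)].sum() for signs in itertools.product([False, True], repeat=n)]
        )
        mu = n * (n + 1) / 4
        p_perm = np.mean(np.abs(w_all - mu) >= np.abs(w_obs - mu) - 1e-12)
        _, p, _ = wilcoxon_signed_rank(x, np.zeros(n))
        assert p == pytest.approx(p_perm, rel=0.02)

    def test_rank_sum_detects_shift(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(1.2, 1, 40)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 0.001
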