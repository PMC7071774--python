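"""Response rules, LDA posteriors, cross-validated ROC, descriptive tests."""

import numpy as np
import pytest

import dosiflare as df
from oracles import (
    oracle_auc_mannwhitney,
    oracle_lda_posterior_1d,
    oracle_ranksum_exact_p,
)


class TestClassifyResponse:
    def test_complete_response(self):
        r = df.classify_response(4.0, 0.0, residual_invasive=False)
        assert r.label == "pCR" and r.responder

    def test_partial_response_over_half(self):
        r = df.classify_response(4.0, 1.9, residual_invasive=True)
        assert r.label == "PR" and r.responder  # 52.5% reduction

    def test_exact_half_is_no_response(self):
        r = df.classify_response(4.0, 2.0, residual_invasive=True)
        assert r.label == "NR" and not r.responder

    def test_growth_is_no_response(self):
        assert df.classify_response(2.0, 3.0, True).label == "NR"

    def test_zero_baseline_with_residual_rejected(self):
        with pytest.raises(ValueError):
            df.classify_response(0.0, 1.0, True)


class TestLDA:
    @pytest.mark.parametrize(
        "mu0,mu1,sigma,prior1",
        [(-13.0, 40.0, 25.0, 0.7), (0.0, 1.0, 1.0, 0.5), (2.0, -3.0, 4.0, 0.3)],
    )
    def test_posterior_matches_closed_form_logistic(self, mu0, mu1, sigma, prior1, rng):
        n1 = max(int(round(200 * prior1)), 2)
        n0 = 200 - n1
        x = np.concatenate([rng.normal(mu0, sigma, n0), rng.normal(mu1, sigma, n1)])
        y = np.concatenate([np.zeros(n0), np.ones(n1)])
        model = df.lda_fit(x, y)
        s2 = float(model.pooled_cov[0, 0])
        m0, m1 = float(model.means[0, 0]), float(model.means[1, 0])
        p1 = float(model.priors[1])
        for xi in (-20.0, 0.0, 15.0, 60.0):
            ref = oracle_lda_posterior_1d(xi, m0, m1, s2, p1)
            assert model.posterior([xi])[0] == pytest.approx(ref, abs=1e-10)

    def test_equal_class_means_posterior_equals_prior(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = df.lda_fit(x, y)
        assert np.allclose(model.posterior(np.linspace(-5, 5, 7)), model.priors[1])

    def test_matches_sklearn_reference(self, rng):
        skl = pytest.importorskip("sklearn.discriminant_analysis")
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 20)])
        y = np.concatenate([np.zeros(30), np.ones(20)]).astype(int)
        model = df.lda_fit(x, y)
        # align covariance conventions: this package pools with 1/(n-2),
        # scikit-learn with 1/n; the Bayes-rule posterior path stays ours
        n = len(y)
        aligned = df.LDAModel(model.means, model.pooled_cov * (n - 2) / n, model.priors)
        ref = (
            skl.LinearDiscriminantAnalysis(solver="lsqr")
            .fit(x[:, None], y)
            .predict_proba(x[:, None])[:, 1]
        )
        assert np.max(np.abs(aligned.posterior(x) - ref)) < 1e-8

    def test_one_sample_class_rejected(self):
        with pytest.raises(ValueError):
            df.lda_fit(np.array([0.0, 1.0, 2.0]), np.array([0, 0, 1]))


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 0.95])
        labels = np.array([0, 0, 0, 1, 1, 1])
        roc = df.roc_from_scores(scores, labels)
        assert roc.auc == 1.0
        assert roc.optimal["sensitivity"] == 1.0 and roc.optimal["specificity"] == 1.0

    def test_auc_equals_mann_whitney_identity(self, rng):
        for _ in range(25):
            n1, n0 = rng.integers(5, 30), rng.integers(5, 30)
            scores = np.concatenate(
                [rng.normal(0, 1, n0), rng.normal(rng.uniform(0, 2), 1, n1)]
            )
            labels = np.concatenate([np.zeros(n0), np.ones(n1)]).astype(int)
            roc = df.roc_from_scores(scores, labels)
            assert roc.auc == pytest.approx(oracle_auc_mannwhitney(scores, labels), abs=1e-12)

    def test_monotone_staircase(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        if 0 < labels.sum() < 40:
            roc = df.roc_from_scores(scores, labels)
            assert np.all(np.diff(roc.sensitivity) >= 0)
            assert np.all(np.diff(1 - roc.specificity) >= 0)

    def test_crossval_separable_classes(self, rng):
        x = np.concatenate([rng.normal(-10, 0.5, 15), rng.normal(10, 0.5, 15)])
        y = np.concatenate([np.zeros(15), np.ones(15)]).astype(int)
        roc = df.crossval_roc(x, y, k=5, seed=1)
        assert roc.auc == 1.0

    def test_crossval_label_shuffle_centered_at_half(self):
        rng = np.random.default_rng(99)
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(1.5, 1, 20)])
        y = np.concatenate([np.zeros(20), np.ones(20)]).astype(int)
        aucs = []
        for i in range(200):
            y_perm = rng.permutation(y)
            aucs.append(df.crossval_roc(x, y_perm, k=5, seed=i).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_k_exceeding_class_count_rejected(self, rng):
        x = rng.normal(size=8)
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="class count"):
            df.crossval_roc(x, y, k=5, seed=0)

    def test_crossval_deterministic_per_seed(self, rng):
        x = rng.normal(size=30)
        y = (rng.random(30) < 0.4).astype(int)
        a = df.crossval_roc(x, y, k=3, seed=7).auc
        b = df.crossval_roc(x, y, k=3, seed=7).auc
        assert a == b


class TestDescriptiveTests:
    def test_ranksum_identical_groups(self):
        p = df.rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_ranksum_matches_exact_enumeration(self, rng):
        for _ in range(5):
            a = rng.normal(size=6)
            b = rng.normal(0.5, 1, size=7)
            assert df.rank_sum_test(a, b) == pytest.approx(
                oracle_ranksum_exact_p(a, b), abs=1e-10
            )

    def test_published_responder_proportions_not_different(self):
        # 25/35 MTD responders vs 10/19 MET responders: p > 0.05
        assert df.two_proportion_ztest(25, 35, 10, 19) > 0.05

    def test_ztest_identical_proportions(self):
        assert df.two_proportion_ztest(5, 10, 10, 20) == 1.0

    def test_ztest_matches_statsmodels(self):
        props = pytest.importorskip("statsmodels.stats.proportion")
        ref = props.proportions_ztest([25, 10], [35, 19])[1]
        assert df.two_proportion_ztest(25, 35, 10, 19) == pytest.approx(ref, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            df.two_proportion_ztest(5, 4, 1, 10)
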