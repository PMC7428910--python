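import numpy as np
import pytest

from elmh import (SimulationConfig, bartlett_scores, extract_factors,
                  fit_score_regressions, regression_factor_score,
                  retain_factors, simulate_cohort)
from elmh.errors import EstimationError, InputError
from elmh.factor import (DEFAULT_DOMAIN_SPEC, DEFAULT_SCORE_REGRESSION,
                         FactorScorer, align_factors_to_domains, varimax)
from elmh.simulate import eight_domain_config


def _two_block_data(n=300, seed=0):
    """Two disjoint item blocks, each driven by one latent trait."""
    rng = np.random.default_rng(seed)
    t1, t2 = rng.normal(size=(2, n))
    X = np.empty((n, 8))
    X[:, :4] = t1[:, None] + 0.5 * rng.normal(size=(n, 4))
    X[:, 4:] = t2[:, None] + 0.5 * rng.normal(size=(n, 4))
    return X


class TestRetention:
    def test_inclusive_threshold(self):
        assert retain_factors([3.2, 1.5, 1.0, 0.4]) == 3

    def test_warns_when_no_factor_qualifies(self):
        with pytest.warns(UserWarning, match="criterion"):
            assert retain_factors([0.9, 0.5]) == 0

    def test_rejects_empty_and_unsorted(self):
        with pytest.raises(InputError):
            retain_factors([])
        with pytest.raises(InputError):
            retain_factors([1.0, 2.0])

    def test_eight_independent_domain_traits_retain_eight(self):
        cohort = simulate_cohort(eight_domain_config(seed=3))
        R = np.corrcoef(cohort.to_numpy(), rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(R))[::-1]
        assert retain_factors(evals) == 8


class TestExtraction:
    def test_block_structure_recovered(self):
        X = _two_block_data()
        loadings, _ = extract_factors(X, 2)
        top_factor = np.argmax(np.abs(loadings), axis=1)
        assert len(set(top_factor[:4])) == 1
        assert len(set(top_factor[4:])) == 1
        assert top_factor[0] != top_factor[4]

    def test_matches_sklearn_block_assignment(self):
        from sklearn.decomposition import FactorAnalysis

        X = _two_block_data(seed=4)
        loadings, _ = extract_factors(X, 2)
        sk = FactorAnalysis(n_components=2, rotation="varimax").fit(X)
        mine = np.argmax(np.abs(loadings), axis=1)
        theirs = np.argmax(np.abs(sk.components_.T), axis=1)
        # same partition of items into blocks (factor order may differ)
        same = (mine == theirs).all() or (mine == 1 - theirs).all()
        assert same

    def test_pure_noise_has_small_communalities(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(600, 10))
        loadings, uniq = extract_factors(X, 1)
        assert (loadings ** 2).sum(axis=1).max() < 0.35
        assert uniq.min() > 0.65

    def test_communality_plus_uniqueness_is_one(self):
        X = _two_block_data(seed=2)
        loadings, uniq = extract_factors(X, 2)
        assert np.allclose((loadings ** 2).sum(axis=1) + uniq, 1.0,
                           atol=1e-6)

    def test_varimax_preserves_communalities(self):
        X = _two_block_data(seed=5)
        unrot, _ = extract_factors(X, 2, rotate=False)
        rot = varimax(unrot)
        assert np.allclose((unrot ** 2).sum(axis=1),
                           (rot ** 2).sum(axis=1), atol=1e-8)

    def test_constant_column_raises(self):
        X = _two_block_data(seed=6)
        X[:, 0] = 3.0
        with pytest.raises(EstimationError):
            extract_factors(X, 2)


class TestBartlettScores:
    def test_single_item_identity(self):
        X = np.array([[1.0], [2.0], [3.0]])
        s = bartlett_scores(X, np.array([[1.0]]), np.array([1.0]))
        z = (X - X.mean()) / X.std(ddof=1)
        assert np.allclose(s, z)

    def test_column_means_are_zero(self, default_cohort):
        X = default_cohort.to_numpy()
        loadings, uniq = extract_factors(X, 8)
        scores = bartlett_scores(X, loadings, uniq)
        assert np.abs(scores.mean(axis=0)).max() < 1e-8

    def test_matches_gls_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        loadings = np.array([[0.9, 0.0], [0.8, 0.1], [0.1, 0.7],
                             [0.0, 0.8], [0.3, 0.3]])
        uniq = np.array([0.19, 0.35, 0.50, 0.36, 0.82])
        X = rng.normal(size=(30, 5)) * 2.0 + 3.0
        scores = bartlett_scores(X, loadings, uniq)
        z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        psi_inv = np.diag(1.0 / uniq)
        for i in range(len(X)):  # brute-force GLS solve, person by person
            lhs = loadings.T @ psi_inv @ loadings
            rhs = loadings.T @ psi_inv @ z[i]
            assert np.allclose(scores[i], np.linalg.solve(lhs, rhs),
                               atol=1e-10)

    def test_zero_uniqueness_raises(self):
        with pytest.raises(EstimationError):
            bartlett_scores(np.eye(3), np.ones((3, 1)), np.zeros(3))

    def test_bartlett_scores_conditionally_unbiased(self):
        # conditional unbiasedness E[estimate | truth] = truth: regressing
        # the estimated score on the true factor gives slope ~ 1 (the
        # reverse regression is attenuated by estimation noise)
        rng = np.random.default_rng(12)
        n = 1000
        t = rng.normal(size=n)
        lam = np.array([0.8, 0.7, 0.6, 0.75])
        X = t[:, None] * lam + rng.normal(size=(n, 4)) * \
            np.sqrt(1 - lam ** 2)
        scores = bartlett_scores(X, lam[:, None], 1 - lam ** 2)
        slope = np.polyfit(t, scores.ravel(), 1)[0]
        assert abs(slope - 1.0) < 0.1


class TestScoreRegressions:
    def test_published_intercept_at_zero_sum(self):
        assert regression_factor_score(1, 0.0) == pytest.approx(-3.2516)

    def test_domain8_worked_example(self):
        assert regression_factor_score(8, 10.0) == pytest.approx(2.1614)

    def test_domain6_zero_crossing(self):
        assert abs(regression_factor_score(6, 9.6868)) < 1e-3

    def test_out_of_range_domain(self):
        with pytest.raises(InputError):
            regression_factor_score(9, 0.0)

    def test_strictly_increasing_for_positive_slopes(self):
        for d in range(1, 9):
            assert DEFAULT_SCORE_REGRESSION.slopes[d - 1] > 0
            lo = regression_factor_score(d, 4.0)
            hi = regression_factor_score(d, 4.5)
            assert hi > lo

    def test_ols_recovers_exact_linear_map(self):
        sums = np.linspace(16, 80, 20)[:, None] * np.ones((1, 8))
        scores = -3.2516 + 0.0819 * sums
        reg = fit_score_regressions(sums, scores)
        assert np.allclose(reg.intercepts, -3.2516, atol=1e-10)
        assert np.allclose(reg.slopes, 0.0819, atol=1e-10)

    def test_three_point_hand_example(self):
        sums = np.array([[0.0], [1.0], [2.0]])
        scores = np.array([[1.0], [3.0], [5.0]])
        reg = fit_score_regressions(sums, scores)
        assert reg.intercepts[0] == pytest.approx(1.0)
        assert reg.slopes[0] == pytest.approx(2.0)

    def test_zero_variance_raises(self):
        sums = np.ones((5, 1))
        with pytest.raises(EstimationError):
            fit_score_regressions(sums, sums)

    def test_regression_scores_track_bartlett_scores(self):
        cohort = simulate_cohort(eight_domain_config(seed=3))
        X = cohort.to_numpy()
        scorer = FactorScorer(n_factors=8,
                              align_to=DEFAULT_DOMAIN_SPEC).fit(X)
        F = scorer.transform(X)
        sums = DEFAULT_DOMAIN_SPEC.domain_sums(X)
        reg = fit_score_regressions(sums, F)
        pred = sums * np.array(reg.slopes) + np.array(reg.intercepts)
        for d in range(8):
            assert np.corrcoef(pred[:, d], F[:, d])[0, 1] > 0.8


class TestFactorScorer:
    def test_alignment_orders_factors_by_domain(self):
        cohort = simulate_cohort(eight_domain_config(seed=8))
        X = cohort.to_numpy()
        scorer = FactorScorer(n_factors=8,
                              align_to=DEFAULT_DOMAIN_SPEC).fit(X)
        assign = DEFAULT_DOMAIN_SPEC.item_assignment
        for d in range(8):
            own = np.abs(scorer.loadings_[assign == d, d]).mean()
            other = np.abs(scorer.loadings_[assign != d, d]).mean()
            assert own > other

    def test_alignment_requires_one_factor_per_domain(self):
        with pytest.raises(InputError):
            align_factors_to_domains(np.ones((44, 3)),
                                     DEFAULT_DOMAIN_SPEC)

    def test_transform_consistent_for_new_respondent(self, default_cohort):
        X = default_cohort.to_numpy()
        scorer = FactorScorer(n_factors=8).fit(X)
        full = scorer.transform(X)
        single = scorer.transform(X[5])
        assert np.allclose(single, full[5])

    def test_get_set_params_round_trip(self):
        scorer = FactorScorer()
        scorer.set_params(n_factors=4)
        assert scorer.get_params()["n_factors"] == 4
        with pytest.raises(ValueError):
            scorer.set_params(bogus=1)
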