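"""Logistic regression: closed forms, a likelihood-grid oracle, and sandwiches."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import optimize

from coffeemr.models import (ClusterRobustLogit, RobustOLS, SeparationError,
                             cluster_sandwich)


def test_saturated_2x2_matches_odds_ratio():
    # cases: 20 exposed / 10 unexposed; controls: 10 exposed / 20 unexposed
    x = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
    y = np.r_[np.ones(30), np.zeros(30)]
    m = ClusterRobustLogit().fit(x[:, None], y)
    assert np.exp(m.coef_[1]) == pytest.approx(4.0, abs=1e-8)


def test_null_covariate_gives_or_near_one(rng):
    n = 20000
    x = rng.standard_normal(n)
    y = rng.binomial(1, 0.4, n).astype(float)
    m = ClusterRobustLogit().fit(x[:, None], y)
    assert np.exp(m.coef_[1]) == pytest.approx(1.0, abs=0.05)


def test_mle_matches_likelihood_grid_oracle():
    """Six observations, two parameters: compare to a brute-force Bernoulli
    likelihood maximisation that never touches the IRLS code path. Both
    outcome classes occur at the extreme dosages, so the MLE is finite."""
    x = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
    y = np.array([0.0, 1.0, 1.0, 1.0, 0.0, 1.0])

    def negll(theta):
        eta = theta[0] + theta[1] * x
        return -(y @ eta - np.logaddexp(0.0, eta).sum())

    grid = optimize.brute(negll, ((-6, 6), (-6, 6)), Ns=61, finish=optimize.fmin)
    m = ClusterRobustLogit().fit(x[:, None], y)
    assert m.coef_ == pytest.approx(grid, abs=1e-4)


def test_matches_statsmodels_coefficients_and_cluster_se(logistic_data):
    X, y, g = logistic_data
    m = ClusterRobustLogit().fit(X, y, clusters=g)
    sm_fit = sm.Logit(y, sm.add_constant(X)).fit(
        disp=0, cov_type="cluster",
        cov_kwds={"groups": g, "use_correction": False})
    assert m.coef_ == pytest.approx(np.asarray(sm_fit.params), abs=1e-7)
    n_g = len(np.unique(g))
    expected = np.asarray(sm_fit.bse) * np.sqrt(n_g / (n_g - 1))
    assert m.bse_ == pytest.approx(expected, rel=1e-6)


def test_aliased_column_dropped_estimates_unchanged(logistic_data):
    X, y, g = logistic_data
    base = ClusterRobustLogit().fit(X, y)
    X_alias = np.column_stack([X, X[:, 0] + 2 * X[:, 1]])
    m = ClusterRobustLogit().fit(X_alias, y)
    assert m.dropped_features_ == ["x2"]
    assert m.coef_[:3] == pytest.approx(base.coef_, abs=1e-8)
    assert m.coef_[3] == 0.0


def test_complete_separation_raises_named_error():
    x = np.r_[np.zeros(10), np.ones(10)]
    y = np.r_[np.zeros(10), np.ones(10)]
    with pytest.raises(SeparationError, match="separat"):
        ClusterRobustLogit().fit(x[:, None], y, feature_names=["expo"])


def test_constant_outcome_rejected():
    with pytest.raises(ValueError, match="constant"):
        ClusterRobustLogit().fit(np.arange(5.0)[:, None], np.ones(5))


def test_singleton_clusters_equal_hc0_times_correction(logistic_data):
    X, y, _ = logistic_data
    n = len(y)
    m = ClusterRobustLogit().fit(X, y, clusters=np.arange(n))
    hc0 = sm.Logit(y, sm.add_constant(X)).fit(disp=0, cov_type="HC0")
    assert m.bse_ == pytest.approx(
        np.asarray(hc0.bse) * np.sqrt(n / (n - 1)), rel=1e-6)


def test_duplicated_clusters_leave_point_estimate_unchanged(logistic_data):
    X, y, _ = logistic_data
    X2, y2 = np.vstack([X, X]), np.r_[y, y]
    clusters = np.r_[np.zeros(len(y)), np.ones(len(y))]
    single = ClusterRobustLogit().fit(X, y)
    double = ClusterRobustLogit().fit(X2, y2, clusters=clusters)
    assert double.coef_ == pytest.approx(single.coef_, abs=1e-7)


def test_cluster_robust_close_to_model_se_under_independence(rng):
    # correctly specified independent data: sandwich ≈ model-based SE
    n = 20000
    x = rng.binomial(2, 0.4, n).astype(float)
    y = rng.binomial(1, 1 / (1 + np.exp(-(0.1 * x)))).astype(float)
    g = rng.integers(0, 200, n)
    m = ClusterRobustLogit().fit(x[:, None], y, clusters=g)
    model_se = np.sqrt(np.diag(m.cov_model_))
    assert m.bse_[1] == pytest.approx(model_se[1], rel=0.15)


def test_ci_bounds_are_exp_of_log_scale_bounds(logistic_data):
    X, y, g = logistic_data
    m = ClusterRobustLogit().fit(X, y, clusters=g)
    tab = m.summary_frame()
    lo = np.exp(m.coef_ - 1.959963984540054 * m.bse_)
    assert np.asarray(tab["ci_low"]) == pytest.approx(lo, rel=1e-12)


class TestRobustOLS:
    def test_noiseless_recovery_zero_robust_se(self):
        x = np.arange(50.0)
        y = 2.0 + 0.10 * x
        m = RobustOLS().fit(x[:, None], y)
        assert m.coef_[1] == pytest.approx(0.10, abs=1e-10)
        assert m.bse_[1] == pytest.approx(0.0, abs=1e-7)

    def test_hc1_matches_statsmodels(self, rng):
        n = 400
        X = rng.standard_normal((n, 2))
        y = 1 + 0.5 * X[:, 0] + rng.standard_normal(n) * (1 + np.abs(X[:, 1]))
        m = RobustOLS().fit(X, y)
        s = sm.OLS(y, sm.add_constant(X)).fit(cov_type="HC1")
        assert m.coef_ == pytest.approx(np.asarray(s.params), abs=1e-10)
        assert m.bse_ == pytest.approx(np.asarray(s.bse), rel=1e-10)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            RobustOLS().fit(np.eye(3), np.ones(3))

    def test_permuted_outcome_null_slope(self, rng):
        n = 5000
        x = rng.binomial(4, 0.4, n).astype(float)
        y = 1.5 + 0.1 * x + rng.gamma(2.0, 0.5, n)
        perm = rng.permutation(y)
        m = RobustOLS().fit(x[:, None], perm)
        assert abs(m.coef_[1]) < 4 * m.bse_[1] + 0.05


def test_cluster_sandwich_requires_two_clusters():
    with pytest.raises(ValueError, match="2 clusters"):
        cluster_sandwich(np.eye(2), np.ones((5, 2)), np.zeros(5))
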