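"""Cox model: partial-likelihood oracle, lifelines cross-checks, PH test."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy import optimize

from coffeemr.assoc import ModelFit
from coffeemr.models import LeftTruncatedCoxPH
from coffeemr.survival import fit_cox, ph_test


def _hand_partial_loglik(beta, x, time, event):
    """Independent Breslow partial likelihood for untied right-censored data."""
    ll = 0.0
    for i in np.flatnonzero(event):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def test_matches_exhaustive_partial_likelihood_oracle():
    """Four subjects, one covariate: golden-section maximisation of a
    hand-written partial likelihood agrees to 4 decimals."""
    x = np.array([1.0, 0.0, 1.0, 0.0])
    time = np.array([1.0, 2.0, 3.0, 4.0])
    event = np.array([1, 1, 0, 1])
    res = optimize.minimize_scalar(
        lambda b: -_hand_partial_loglik(b, x, time, event),
        bounds=(-5, 5), method="bounded",
        options={"xatol": 1e-10})
    m = LeftTruncatedCoxPH().fit(x[:, None], np.zeros(4), time, event)
    assert m.coef_[0] == pytest.approx(res.x, abs=1e-4)


def test_right_censored_no_ties_equals_lifelines(rng):
    n = 500
    X = rng.standard_normal((n, 2))
    t = rng.exponential(scale=np.exp(-0.5 * X[:, 0]))
    c = rng.exponential(scale=1.5, size=n)
    exit = np.minimum(t, c)
    event = (t <= c).astype(int)
    m = LeftTruncatedCoxPH().fit(X, np.zeros(n), exit, event)
    df = pd.DataFrame({"x0": X[:, 0], "x1": X[:, 1], "t": exit, "e": event})
    cf = CoxPHFitter().fit(df, duration_col="t", event_col="e")
    assert m.coef_ == pytest.approx(np.asarray(cf.params_), abs=1e-6)
    assert m.bse_ == pytest.approx(np.asarray(cf.standard_errors_), rel=1e-5)


def test_left_truncated_tied_equals_lifelines_efron(survival_data):
    X, entry, exit, event, _ = survival_data
    exit_t = np.maximum(np.round(exit, 1), entry + 1e-4)  # induce heavy ties
    m = LeftTruncatedCoxPH().fit(X, entry, exit_t, event)
    df = pd.DataFrame({"x0": X[:, 0], "x1": X[:, 1], "entry": entry,
                       "exit": exit_t, "e": event})
    cf = CoxPHFitter().fit(df, duration_col="exit", event_col="e",
                           entry_col="entry")
    assert m.coef_ == pytest.approx(np.asarray(cf.params_), abs=1e-6)
    assert m.bse_ == pytest.approx(np.asarray(cf.standard_errors_), rel=1e-5)


def test_timescale_invariance(survival_data):
    X, entry, exit, event, _ = survival_data
    m1 = LeftTruncatedCoxPH().fit(X, entry, exit, event)
    m2 = LeftTruncatedCoxPH().fit(X, 3.0 * entry, 3.0 * exit, event)
    assert m2.coef_ == pytest.approx(m1.coef_, abs=1e-8)


def test_recovers_generative_log_hazard(survival_data):
    X, entry, exit, event, beta = survival_data
    m = LeftTruncatedCoxPH().fit(X, entry, exit, event)
    assert m.coef_ == pytest.approx(beta, abs=3.5 * np.max(m.bse_))


def test_null_covariate_hr_near_one(rng):
    n = 8000
    entry = np.clip(rng.normal(65, 8, n), 40, 90)
    death = entry + rng.weibull(1.2, n) * 10
    censor = entry + 7
    exit = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    x = rng.binomial(2, 0.4, n).astype(float)
    m = LeftTruncatedCoxPH().fit(x[:, None], entry, exit, event)
    assert np.exp(m.coef_[0]) == pytest.approx(1.0, abs=0.05)


def test_no_events_rejected(rng):
    n = 10
    with pytest.raises(ValueError, match="no events"):
        LeftTruncatedCoxPH().fit(rng.standard_normal((n, 1)), np.zeros(n),
                                 np.ones(n), np.zeros(n, dtype=int))


def test_constant_covariate_named(rng):
    n = 50
    exit = rng.exponential(size=n) + 0.1
    with pytest.raises(ValueError, match="x0"):
        LeftTruncatedCoxPH().fit(np.ones((n, 1)), np.zeros(n), exit,
                                 np.ones(n, dtype=int))


def test_zero_length_interval_shifted_with_warning(rng):
    n = 60
    entry = np.full(n, 60.0)
    exit = entry + rng.exponential(size=n)
    exit[0] = entry[0]
    event = np.ones(n, dtype=int)
    x = rng.standard_normal((n, 1))
    with pytest.warns(UserWarning, match="shifted"):
        m = LeftTruncatedCoxPH().fit(x, entry, exit, event)
    assert np.isfinite(m.coef_).all()


def test_cluster_robust_matches_lifelines_lin_wei(rng):
    n = 2000
    X = rng.standard_normal((n, 2))
    t = rng.exponential(scale=np.exp(-0.4 * X[:, 0]))
    c = rng.exponential(scale=1.5, size=n)
    exit = np.minimum(t, c)
    event = (t <= c).astype(int)
    g = rng.integers(0, 10, n)
    m = LeftTruncatedCoxPH().fit(X, np.zeros(n), exit, event, clusters=g)
    df = pd.DataFrame({"x0": X[:, 0], "x1": X[:, 1], "t": exit, "e": event,
                       "g": g})
    cf = CoxPHFitter().fit(df, duration_col="t", event_col="e",
                           cluster_col="g", robust=True)
    # identical Lin-Wei sandwich up to the G/(G-1) small-sample factor
    expected = np.asarray(cf.standard_errors_) * np.sqrt(10 / 9)
    assert m.bse_ == pytest.approx(expected, rel=1e-5)
    # score residuals sum to ~0 at the MLE
    assert np.abs(m._score_rows_.sum(axis=0)).max() < 1e-5


def test_singleton_cluster_robust_close_to_model_se(survival_data):
    X, entry, exit, event, _ = survival_data
    m = LeftTruncatedCoxPH().fit(X, entry, exit, event,
                                 clusters=np.arange(len(entry)))
    model_se = np.sqrt(np.diag(m.cov_model_))
    assert m.bse_ == pytest.approx(model_se, rel=0.10)


class TestPHTest:
    @staticmethod
    def _wrap(est):
        return ModelFit(term="x0", estimate=float(est.coef_[0]),
                        se=float(est.bse_[0]), n=est.n_obs_,
                        scale="loghazard", model=est)

    def test_null_data_not_rejected_en_masse(self, rng):
        pvals = []
        for _ in range(30):
            n = 600
            entry = np.clip(rng.normal(65, 8, n), 40, 90)
            death = entry + rng.weibull(1.2, n) * np.exp(
                -0.2 * rng.standard_normal(n) * 0) * 10
            censor = entry + 7
            exit = np.minimum(death, censor)
            event = (death <= censor).astype(int)
            x = rng.standard_normal((n, 1))
            est = LeftTruncatedCoxPH().fit(x, entry, exit, event)
            pvals.append(ph_test(self._wrap(est))["global_p"])
        # under proportional hazards roughly 5% of tests reject at 0.05
        assert np.mean(np.asarray(pvals) < 0.05) < 0.25

    def test_reversing_hazard_detected(self, rng):
        # covariate effect flips sign at the median age => PH violated
        n = 6000
        entry = np.full(n, 50.0)
        x = rng.binomial(1, 0.5, n).astype(float)
        u = rng.random(n)
        # piecewise hazard: HR=2 before age 55, HR=0.5 after
        t1 = -np.log(u) / (0.1 * np.exp(np.log(2) * x))
        exit = np.where(t1 < 5.0, entry + t1, np.nan)
        need = np.isnan(exit)
        t2 = -np.log(rng.random(need.sum())) / (0.1 * np.exp(np.log(0.5)
                                                             * x[need]))
        exit[need] = entry[need] + 5.0 + t2
        censor = entry + 12.0
        event = (exit <= censor).astype(int)
        exit = np.minimum(exit, censor)
        est = LeftTruncatedCoxPH().fit(x[:, None], entry, exit, event)
        res = ph_test(self._wrap(est))
        assert res["global_p"] < 0.01

    def test_minimal_two_events_returns_value(self):
        x = np.array([[1.0], [0.0], [1.0]])
        est = LeftTruncatedCoxPH().fit(x, np.zeros(3),
                                       np.array([1.0, 2.0, 3.0]),
                                       np.array([1, 1, 0]))
        res = ph_test(self._wrap(est))
        assert set(res["per_covariate"]) == {"x0"}
        assert 0.0 <= res["per_covariate"]["x0"] <= 1.0

    def test_fewer_events_than_covariates_skips_global(self, rng):
        n = 30
        X = rng.standard_normal((n, 3))
        exit = rng.exponential(size=n) + 0.1
        event = np.zeros(n, dtype=int)
        event[:3] = 1  # as many events as covariates: global test undefined
        est = LeftTruncatedCoxPH().fit(X, np.zeros(n), exit, event)
        fit = ModelFit(term="x0", estimate=float(est.coef_[0]),
                       se=float(est.bse_[0]), n=n, scale="loghazard",
                       model=est)
        with pytest.warns(UserWarning, match="fewer events"):
            res = ph_test(fit)
        assert res["global_p"] is None


def test_fit_cox_wrapper_reports_exposure_term(rng):
    n = 2500
    entry = np.clip(rng.normal(65, 8, n), 40, 90)
    grs = rng.binomial(4, 0.4, n).astype(float)
    lam, k = 28.0, 1.2
    w = np.exp(0.1 * grs)
    death = lam * ((entry / lam) ** k + rng.exponential(size=n) / w) ** (1 / k)
    censor = entry + 8
    df = pd.DataFrame({"grs": grs, "entry_age": entry,
                       "exit_age": np.minimum(death, censor),
                       "event": (death <= censor).astype(int),
                       "study": rng.choice(["A", "B", "C"], n)})
    for j in range(1, 9):
        df[f"pc{j}"] = rng.standard_normal(n)
    fit = fit_cox(df, "grs", "event")
    assert fit.scale == "loghazard"
    assert fit.ratio == pytest.approx(np.exp(0.1), abs=0.06)
    assert fit.n_clusters == 3
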