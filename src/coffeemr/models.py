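"""Regression estimators used throughout the pipeline.

All three estimators are written against plain numpy from first principles:

* :class:`ClusterRobustLogit` — binary logistic regression by iteratively
  reweighted least squares (IRLS) with a cluster-robust sandwich covariance
  (clusters = studies).
* :class:`RobustOLS` — ordinary least squares with heteroscedasticity-robust
  (HC1) or cluster-robust standard errors, used for the instrument → cups/day
  first stage where the outcome is right skewed.
* :class:`LeftTruncatedCoxPH` — Cox proportional hazards on the age timescale
  with delayed entry (entry at diagnosis) and Efron tie handling, plus
  Lin–Wei score-residual robust variance.

They follow scikit-learn estimator conventions (``get_params``/``set_params``,
fitted attributes with a trailing underscore) so they compose with sklearn
tooling; the field-facing wrappers live in :mod:`coffeemr.assoc` and
:mod:`coffeemr.survival`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg, special, stats
from sklearn.base import BaseEstimator

__all__ = [
    "ClusterRobustLogit",
    "RobustOLS",
    "LeftTruncatedCoxPH",
    "ConvergenceError",
    "SeparationError",
    "cluster_sandwich",
    "Z_95",
]

# normal critical value used for all reported 95% intervals
Z_95 = 1.959963984540054


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge."""


class SeparationError(RuntimeError):
    """Raised when a logistic fit diverges (complete/quasi-complete separation)."""


def _as_matrix(X, feature_names=None):
    """Return (array, names) from a DataFrame or array-like design."""
    if isinstance(X, pd.DataFrame):
        names = list(map(str, X.columns))
        return np.asarray(X, dtype=float), names
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-dimensional")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    return X, list(feature_names)


def drop_aliased_columns(X, names, protected=()):
    """Identify linearly dependent columns via pivoted QR and return kept indices.

    Columns listed in ``protected`` must survive; if one is aliased a
    ``ValueError`` is raised instead of silently dropping it.
    """
    n, p = X.shape
    if p == 0:
        return np.arange(0)
    # greedy Gram-Schmidt in column order, so later redundant columns (e.g. a
    # surplus study indicator) are the ones dropped
    keep_list: list[int] = []
    basis = np.zeros((n, 0))
    for j in range(p):
        col = X[:, j].astype(float)
        resid = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(col)
        if np.linalg.norm(resid) > max(norm, 1.0) * 1e-9:
            keep_list.append(j)
            basis = np.column_stack([basis, resid / np.linalg.norm(resid)])
    keep = np.asarray(keep_list, dtype=int)
    dropped = set(range(p)) - set(keep_list)
    for j in dropped:
        if names[j] in protected:
            raise ValueError(f"column '{names[j]}' is aliased with other design columns")
    return keep


def cluster_sandwich(bread, score_rows, clusters, df_correction=True):
    """Sandwich covariance A⁻¹ B A⁻¹ from per-observation score rows.

    ``bread`` is the observed information (A); ``score_rows`` an (n, p) array of
    per-observation score contributions; B sums per-cluster score totals'
    outer products, scaled by G/(G−1) when ``df_correction``.
    """
    clusters = np.asarray(clusters)
    labels, inverse = np.unique(clusters, return_inverse=True)
    n_groups = labels.size
    if n_groups < 2:
        raise ValueError(
            "cluster-robust variance needs >= 2 clusters; "
            "use the unclustered robust (HC) variance instead"
        )
    p = score_rows.shape[1]
    sums = np.zeros((n_groups, p))
    np.add.at(sums, inverse, score_rows)
    meat = sums.T @ sums
    if df_correction:
        meat *= n_groups / (n_groups - 1.0)
    a_inv = linalg.inv(bread)
    return a_inv @ meat @ a_inv


class ClusterRobustLogit(BaseEstimator):
    """Maximum-likelihood logistic regression with cluster-robust variance.

    Parameters
    ----------
    fit_intercept : bool
        Prepend a constant column.
    max_iter, score_tol, loglik_tol : IRLS stopping rules — converged when the
        max absolute score falls below ``score_tol`` (1e-8) or the relative
        log-likelihood change below ``loglik_tol`` (1e-10), at most ``max_iter``
        (50) iterations.
    drop_aliased : bool
        Detect and drop linearly dependent columns (e.g. a redundant study
        indicator) before fitting; dropped names are recorded in
        ``dropped_features_`` and get a zero coefficient and NaN SE.

    Fitted attributes: ``coef_`` (full coefficient vector, intercept first when
    present), ``feature_names_``, ``cov_model_``, ``cov_robust_`` (when
    clusters are passed to ``fit``), ``bse_``, ``loglik_``, ``n_iter_``,
    ``converged_``, ``n_obs_``.
    """

    def __init__(self, fit_intercept=True, max_iter=50, score_tol=1e-8,
                 loglik_tol=1e-10, drop_aliased=True):
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.score_tol = score_tol
        self.loglik_tol = loglik_tol
        self.drop_aliased = drop_aliased

    def fit(self, X, y, clusters=None, feature_names=None, protected=()):
        X, names = _as_matrix(X, feature_names)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y have different lengths")
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError("outcome must be binary 0/1")
        if uniq.size < 2:
            raise ValueError("outcome is constant; logistic model undefined")
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
            names = ["const"] + names
            protected = ("const",) + tuple(protected)

        keep = (drop_aliased_columns(X, names, protected)
                if self.drop_aliased else np.arange(X.shape[1]))
        dropped = [names[j] for j in range(X.shape[1]) if j not in set(keep.tolist())]
        Xk = X[:, keep]
        kept_names = [names[j] for j in keep]

        beta, loglik, n_iter, converged, info = self._irls(Xk, y, kept_names)

        p_full = X.shape[1]
        full_beta = np.zeros(p_full)
        full_beta[keep] = beta
        self.coef_ = full_beta
        self.feature_names_ = names
        self.dropped_features_ = dropped
        self._keep_idx_ = keep
        self.loglik_ = loglik
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_obs_ = y.size

        cov_k = linalg.inv(info)
        self.cov_model_ = np.full((p_full, p_full), np.nan)
        self.cov_model_[np.ix_(keep, keep)] = cov_k

        eta = Xk @ beta
        mu = special.expit(eta)
        self._score_rows_ = Xk * (y - mu)[:, None]
        self._info_ = info
        self.fitted_prob_ = mu

        if clusters is not None:
            cov_r = cluster_sandwich(info, self._score_rows_, clusters)
            self.cov_robust_ = np.full((p_full, p_full), np.nan)
            self.cov_robust_[np.ix_(keep, keep)] = cov_r
            self.n_clusters_ = np.unique(np.asarray(clusters)).size
        else:
            self.cov_robust_ = None
            self.n_clusters_ = None
        self.bse_ = np.sqrt(np.diag(
            self.cov_robust_ if self.cov_robust_ is not None else self.cov_model_))
        return self

    def _irls(self, X, y, names):
        n, p = X.shape
        beta = np.zeros(p)
        loglik = -n * np.log(2.0)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = X @ beta
            mu = special.expit(eta)
            w = mu * (1.0 - mu)
            score = X.T @ (y - mu)
            info = (X * w[:, None]).T @ X
            try:
                step = linalg.solve(info, score, assume_a="pos")
            except linalg.LinAlgError as exc:  # pragma: no cover - defensive
                raise ConvergenceError(f"singular information matrix: {exc}") from exc
            new_beta = beta + step
            new_ll = self._loglik(X, y, new_beta)
            # step-halving keeps the likelihood monotone
            halves = 0
            while new_ll < loglik - 1e-12 and halves < 30:
                step *= 0.5
                new_beta = beta + step
                new_ll = self._loglik(X, y, new_beta)
                halves += 1
            scale = np.maximum(np.abs(X).max(axis=0), 1e-12)
            if np.max(np.abs(new_beta) * scale) > 40.0:
                j = int(np.argmax(np.abs(new_beta) * scale))
                raise SeparationError(
                    f"coefficient for '{names[j]}' diverging; data are "
                    "(quasi-)completely separated on this term"
                )
            rel_change = abs(new_ll - loglik) / max(abs(new_ll), 1.0)
            beta, loglik = new_beta, new_ll
            eta = X @ beta
            mu = special.expit(eta)
            score = X.T @ (y - mu)
            if np.max(np.abs(score)) < self.score_tol or rel_change < self.loglik_tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(f"IRLS did not converge in {self.max_iter} iterations")
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        return beta, loglik, it, converged, info

    @staticmethod
    def _loglik(X, y, beta):
        eta = X @ beta
        # log(1+exp(eta)) computed stably
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    def predict_proba(self, X):
        X, _ = _as_matrix(X)
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        p1 = special.expit(X @ self.coef_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def summary_frame(self):
        """Coefficients with SEs, odds ratios, 95% CIs and Wald p-values."""
        se = self.bse_
        z = np.divide(self.coef_, se, out=np.full_like(se, np.nan), where=se > 0)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "coef": self.coef_,
            "se": se,
            "or": np.exp(self.coef_),
            "ci_low": np.exp(self.coef_ - Z_95 * se),
            "ci_high": np.exp(self.coef_ + Z_95 * se),
            "p": pvals,
        }, index=self.feature_names_)


class RobustOLS(BaseEstimator):
    """OLS with HC1 (default) or cluster-robust standard errors."""

    def __init__(self, fit_intercept=True, cov_type="HC1", drop_aliased=True):
        self.fit_intercept = fit_intercept
        self.cov_type = cov_type
        self.drop_aliased = drop_aliased

    def fit(self, X, y, clusters=None, feature_names=None, protected=()):
        X, names = _as_matrix(X, feature_names)
        y = np.asarray(y, dtype=float).ravel()
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
            names = ["const"] + names
            protected = ("const",) + tuple(protected)
        keep = (drop_aliased_columns(X, names, protected)
                if self.drop_aliased else np.arange(X.shape[1]))
        Xk = X[:, keep]
        n, p = Xk.shape
        if n <= p:
            raise ValueError(f"n={n} observations cannot identify {p} parameters")
        xtx = Xk.T @ Xk
        beta = linalg.solve(xtx, Xk.T @ y, assume_a="pos")
        resid = y - Xk @ beta
        xtx_inv = linalg.inv(xtx)

        p_full = X.shape[1]
        self.coef_ = np.zeros(p_full)
        self.coef_[keep] = beta
        self.feature_names_ = names
        self.dropped_features_ = [names[j] for j in range(p_full)
                                  if j not in set(keep.tolist())]
        sigma2 = resid @ resid / (n - p)
        self.cov_model_ = np.full((p_full, p_full), np.nan)
        self.cov_model_[np.ix_(keep, keep)] = xtx_inv * sigma2

        score_rows = Xk * resid[:, None]
        if self.cov_type == "cluster" or clusters is not None:
            if clusters is None:
                raise ValueError("cov_type='cluster' requires cluster labels")
            cov_r = cluster_sandwich(xtx, score_rows, clusters)
        else:
            meat = score_rows.T @ score_rows
            cov_r = xtx_inv @ meat @ xtx_inv * (n / (n - p))  # HC1
        self.cov_robust_ = np.full((p_full, p_full), np.nan)
        self.cov_robust_[np.ix_(keep, keep)] = cov_r
        self.bse_ = np.sqrt(np.diag(self.cov_robust_))
        self.resid_ = resid
        self.n_obs_ = n
        self._keep_idx_ = keep
        return self

    def predict(self, X):
        X, _ = _as_matrix(X)
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        return X @ self.coef_

    def summary_frame(self):
        se = self.bse_
        z = np.divide(self.coef_, se, out=np.full_like(se, np.nan), where=se > 0)
        return pd.DataFrame({
            "coef": self.coef_,
            "se": se,
            "ci_low": self.coef_ - Z_95 * se,
            "ci_high": self.coef_ + Z_95 * se,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        }, index=self.feature_names_)


DAY = 1.0 / 365.25


class LeftTruncatedCoxPH(BaseEstimator):
    """Cox proportional hazards with delayed entry on the age timescale.

    The partial likelihood uses risk sets ``{i : entry_i < t <= exit_i}`` and
    Efron's correction for tied event ages. Newton–Raphson iterates until the
    max absolute score falls below ``score_tol`` (1e-8). Robust (cluster)
    variance follows Lin–Wei using per-subject score residuals.

    ``fit(X, entry, exit, event, clusters=None)``; fitted attributes mirror
    :class:`ClusterRobustLogit` with coefficients on the log-hazard scale.
    """

    def __init__(self, max_iter=50, score_tol=1e-8, loglik_tol=1e-10,
                 drop_aliased=True):
        self.max_iter = max_iter
        self.score_tol = score_tol
        self.loglik_tol = loglik_tol
        self.drop_aliased = drop_aliased

    def fit(self, X, entry, exit, event, clusters=None, feature_names=None,
            protected=()):
        X, names = _as_matrix(X, feature_names)
        entry = np.asarray(entry, dtype=float).ravel()
        exit = np.asarray(exit, dtype=float).ravel().copy()
        event = np.asarray(event, dtype=float).ravel().astype(int)
        n = X.shape[0]
        if not (entry.size == exit.size == event.size == n):
            raise ValueError("X, entry, exit, event lengths differ")
        if np.any(exit < entry):
            raise ValueError("exit age before entry age")
        zero_len = exit <= entry
        if np.any(zero_len):
            warnings.warn(
                f"{int(zero_len.sum())} record(s) with exit == entry shifted by "
                "one day equivalent (1/365.25 y)", stacklevel=2)
            exit[zero_len] = entry[zero_len] + DAY
        if event.sum() < 1:
            raise ValueError("no events; Cox model undefined")

        keep = (drop_aliased_columns(X, names, protected)
                if self.drop_aliased else np.arange(X.shape[1]))
        Xk = X[:, keep]
        kept_names = [names[j] for j in keep]

        self._prepare(Xk, entry, exit, event)
        self._check_risk_variation(Xk, kept_names)
        beta, loglik, n_iter, info = self._newton(Xk)

        p_full = X.shape[1]
        self.coef_ = np.zeros(p_full)
        self.coef_[keep] = beta
        self.feature_names_ = names
        self.dropped_features_ = [names[j] for j in range(p_full)
                                  if j not in set(keep.tolist())]
        self.loglik_ = loglik
        self.n_iter_ = n_iter
        self.converged_ = True
        self.n_obs_ = n
        self.n_events_ = int(event.sum())
        cov_k = linalg.inv(info)
        self.cov_model_ = np.full((p_full, p_full), np.nan)
        self.cov_model_[np.ix_(keep, keep)] = cov_k
        self._info_ = info

        score_rows = self._score_residuals(Xk, beta)
        self._score_rows_ = score_rows
        if clusters is not None:
            cov_r = cluster_sandwich(info, score_rows, clusters)
            self.cov_robust_ = np.full((p_full, p_full), np.nan)
            self.cov_robust_[np.ix_(keep, keep)] = cov_r
            self.n_clusters_ = np.unique(np.asarray(clusters)).size
        else:
            self.cov_robust_ = None
            self.n_clusters_ = None
        self.bse_ = np.sqrt(np.diag(
            self.cov_robust_ if self.cov_robust_ is not None else self.cov_model_))
        # Schoenfeld residual ingredients for the PH test
        self._keep_idx_ = keep
        self._beta_k_ = beta
        self._Xk_ = Xk
        return self

    # ---- internal machinery -------------------------------------------------

    def _prepare(self, X, entry, exit, event):
        self._entry = entry
        self._exit = exit
        self._event = event
        self._order_exit = np.argsort(exit, kind="stable")
        self._order_entry = np.argsort(entry, kind="stable")
        self._exit_sorted = exit[self._order_exit]
        self._entry_sorted = entry[self._order_entry]
        ev_mask = event == 1
        ev_times = exit[ev_mask]
        self._ev_idx = np.flatnonzero(ev_mask)
        uniq, inv, counts = np.unique(ev_times, return_inverse=True, return_counts=True)
        self._uniq_times = uniq
        self._tie_counts = counts
        self._ev_group = inv  # group index per event
        # searchsorted positions of each unique event time
        self._pos_exit = np.searchsorted(self._exit_sorted, uniq, side="left")
        self._pos_entry = np.searchsorted(self._entry_sorted, uniq, side="left")
        # events sorted by time for reduceat group sums
        order_ev = np.argsort(ev_times, kind="stable")
        self._ev_sorted_idx = self._ev_idx[order_ev]
        self._group_starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        # per-subject window (entry_i, exit_i] over unique event times
        self._k_exit = np.searchsorted(uniq, exit, side="right")
        self._k_entry = np.searchsorted(uniq, entry, side="right")
        self._any_ties = bool(np.any(counts > 1))
        # Efron (time, l) pair expansion: group index and l/d per pair
        total = int(counts.sum())
        self._pair_j = np.repeat(np.arange(uniq.size), counts)
        within = np.arange(total) - np.repeat(self._group_starts, counts)
        self._pair_frac = within / counts[self._pair_j]

    def _check_risk_variation(self, X, names):
        # a covariate constant within every risk set cannot be identified
        for j in range(X.shape[1]):
            if np.ptp(X[:, j]) == 0:
                raise ValueError(f"covariate '{names[j]}' is constant; not identifiable")

    def _risk_aggregates(self, X, r, need_s1=True):
        """S0 (and S1) over risk sets {entry < t ≤ exit} at unique event times.

        Each risk-set sum is the difference of two prefix sums: subjects with
        entry < t minus subjects with exit < t.
        """
        def prefix(arr, order):
            a = arr[order]
            return np.concatenate([np.zeros((1,) + a.shape[1:]),
                                   np.cumsum(a, axis=0)])

        p0e = np.concatenate([[0.0], np.cumsum(r[self._order_exit])])
        p0n = np.concatenate([[0.0], np.cumsum(r[self._order_entry])])
        s0 = p0n[self._pos_entry] - p0e[self._pos_exit]
        s1 = None
        if need_s1:
            rX = r[:, None] * X
            p1e = prefix(rX, self._order_exit)
            p1n = prefix(rX, self._order_entry)
            s1 = p1n[self._pos_entry] - p1e[self._pos_exit]
        return s0, s1, None

    def _tied_sums(self, X, r, need_t2=False):
        idx = self._ev_sorted_idx
        t0 = np.add.reduceat(r[idx], self._group_starts)
        t1 = np.add.reduceat(r[idx, None] * X[idx], self._group_starts, axis=0)
        return t0, t1, None

    def _partial_loglik(self, X, beta):
        """Log partial likelihood only (cheap; used for step-halving)."""
        eta = X @ beta
        r = np.exp(eta)
        s0, _, _ = self._risk_aggregates(X, r, need_s1=False)
        if self._any_ties:
            t0 = np.add.reduceat(r[self._ev_sorted_idx], self._group_starts)
            denom = s0[self._pair_j] - self._pair_frac * t0[self._pair_j]
        else:
            denom = s0
        return float(eta[self._ev_idx].sum()) - float(np.log(denom).sum())

    def _loglik_grad_hess(self, X, beta):
        """Efron partial likelihood, score and information.

        The Efron sum over tied-event positions l = 0..d_j−1 is expanded into
        (event time j, l) pairs with precomputed indices. The risk-set part of
        the information uses the identity
        Σ_{j,l} S2_j / D_jl = Xᵀ diag(r·c) X with
        c_i = Σ_{j: entry_i < t_j ≤ exit_i} Σ_l 1/D_jl, and the tied-event
        correction only touches event rows — no n×p×p intermediate is formed.
        """
        eta = X @ beta
        r = np.exp(eta)
        s0, s1, _ = self._risk_aggregates(X, r)
        jidx, frac = self._pair_j, self._pair_frac
        ev = self._ev_idx
        n_uniq = s0.size
        if self._any_ties:
            t0, t1, _ = self._tied_sums(X, r, need_t2=False)
            denom = s0[jidx] - frac * t0[jidx]                   # (pairs,)
            m = (s1[jidx] - frac[:, None] * t1[jidx]) / denom[:, None]
        else:
            denom = s0
            m = s1 / denom[:, None]
        ll = float(eta[ev].sum()) - float(np.log(denom).sum())
        grad = X[ev].sum(axis=0) - m.sum(axis=0)
        # per-unique-time weights: q_j = Σ_l 1/D_jl, κ_j = Σ_l (l/d_j)/D_jl
        q = np.bincount(jidx, weights=1.0 / denom, minlength=n_uniq)
        a0 = np.concatenate([[0.0], np.cumsum(q)])
        c = a0[self._k_exit] - a0[self._k_entry]
        info = (X * (r * c)[:, None]).T @ X - m.T @ m
        if self._any_ties:
            kappa = np.bincount(jidx, weights=frac / denom, minlength=n_uniq)
            evs = self._ev_sorted_idx
            kap_ev = kappa[np.repeat(np.arange(n_uniq), self._tie_counts)]
            Xe = X[evs]
            info -= (Xe * (r[evs] * kap_ev)[:, None]).T @ Xe
        return ll, grad, info

    def _newton(self, X):
        p = X.shape[1]
        beta = np.zeros(p)
        ll, grad, info = self._loglik_grad_hess(X, beta)
        for it in range(1, self.max_iter + 1):
            if np.max(np.abs(grad)) < self.score_tol:
                return beta, ll, it, info
            try:
                step = linalg.solve(info, grad, assume_a="pos")
            except linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix: {exc}") from exc
            new_beta = beta + step
            new_ll = self._partial_loglik(X, new_beta)
            halves = 0
            while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halves < 30:
                step *= 0.5
                new_beta = beta + step
                new_ll = self._partial_loglik(X, new_beta)
                halves += 1
            new_ll, new_grad, new_info = self._loglik_grad_hess(X, new_beta)
            rel = abs(new_ll - ll) / max(abs(new_ll), 1.0)
            beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
            if np.max(np.abs(grad)) < self.score_tol or rel < self.loglik_tol:
                return beta, ll, it, info
        raise ConvergenceError(f"Cox Newton did not converge in {self.max_iter} iterations")

    def _event_means(self, X, beta):
        """Risk-set weighted covariate means m(t_j) and S0 at unique event times."""
        r = np.exp(X @ beta)
        s0, s1, _ = self._risk_aggregates(X, r)
        return s0, s1 / s0[:, None], r

    def _score_residuals(self, X, beta):
        """Per-subject score residuals (Breslow form) for the robust variance."""
        s0, m, r = self._event_means(X, beta)
        d = self._tie_counts.astype(float)
        # prefix sums over unique event times of d/S0 and d*m/S0
        a0 = np.concatenate([[0.0], np.cumsum(d / s0)])
        a1 = np.concatenate([np.zeros((1, X.shape[1])),
                             np.cumsum((d / s0)[:, None] * m, axis=0)])
        k_exit = np.searchsorted(self._uniq_times, self._exit, side="right")
        k_entry = np.searchsorted(self._uniq_times, self._entry, side="right")
        da0 = a0[k_exit] - a0[k_entry]
        da1 = a1[k_exit] - a1[k_entry]
        u = -r[:, None] * (X * da0[:, None] - da1)
        ev = self._ev_idx
        pos = np.searchsorted(self._uniq_times, self._exit[ev])
        u[ev] += X[ev] - m[pos]
        return u

    def schoenfeld_residuals(self):
        """Per-event (time, residual) pairs on the kept-covariate design."""
        s0, m, _ = self._event_means(self._Xk_, self._beta_k_)
        ev = self._ev_idx
        times = self._exit[ev]
        pos = np.searchsorted(self._uniq_times, times)
        resid = self._Xk_[ev] - m[pos]
        order = np.argsort(times, kind="stable")
        return times[order], resid[order]

    def predict_partial_hazard(self, X):
        X, _ = _as_matrix(X)
        return np.exp(X @ self.coef_)

    def summary_frame(self):
        se = self.bse_
        z = np.divide(self.coef_, se, out=np.full_like(se, np.nan), where=se > 0)
        return pd.DataFrame({
            "coef": self.coef_,
            "se": se,
            "hr": np.exp(self.coef_),
            "ci_low": np.exp(self.coef_ - Z_95 * se),
            "ci_high": np.exp(self.coef_ + Z_95 * se),
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        }, index=self.feature_names_)
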