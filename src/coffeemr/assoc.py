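"""Association models: outcome ~ instrument with PC/study adjustment.

Thin, field-facing wrappers over the estimators in :mod:`coffeemr.models`.
Every wrapper builds the design the consortium analysis uses — exposure
(SNP dosage or GRS), eight genetic principal components, study indicator
columns — fits the model, and returns a :class:`ModelFit` holding the
exposure term on both the log and exponentiated scales with robust
(study-clustered) standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import ClusterRobustLogit, RobustOLS, Z_95, cluster_sandwich

__all__ = [
    "ModelFit",
    "build_design",
    "fit_logistic",
    "fit_linear_robust",
    "cluster_robust_cov",
    "subgroup_interaction",
]

PC_COLUMNS = tuple(f"pc{i}" for i in range(1, 9))


@dataclass
class ModelFit:
    """Result of one association model, focused on the exposure term."""

    term: str
    estimate: float            # log OR, log HR, or cups/day per unit
    se: float
    n: int
    scale: str                 # "logodds", "loghazard", "linear"
    model: object = field(repr=False, default=None)
    n_clusters: Optional[int] = None
    converged: bool = True
    n_events: Optional[int] = None

    @property
    def ratio(self) -> float:
        """exp(estimate) — OR or HR; identity on the linear scale."""
        return float(np.exp(self.estimate)) if self.scale != "linear" else self.estimate

    @property
    def ci(self):
        lo, hi = self.estimate - Z_95 * self.se, self.estimate + Z_95 * self.se
        if self.scale != "linear":
            return float(np.exp(lo)), float(np.exp(hi))
        return float(lo), float(hi)

    @property
    def p(self) -> float:
        if self.se <= 0:
            return float("nan")
        return float(2.0 * stats.norm.sf(abs(self.estimate) / self.se))


def build_design(data: pd.DataFrame, exposure: str,
                 pcs: Sequence[str] = PC_COLUMNS,
                 study_col: Optional[str] = "study") -> pd.DataFrame:
    """Exposure + PCs + study indicator columns (first study as reference)."""
    cols = [data[exposure].rename(exposure)]
    for pc in pcs:
        cols.append(data[pc])
    X = pd.concat(cols, axis=1)
    if study_col is not None and data[study_col].nunique() > 1:
        dummies = pd.get_dummies(data[study_col].astype(str), prefix="study",
                                 drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return X


def _complete_rows(data, cols):
    mask = np.ones(len(data), dtype=bool)
    for c in cols:
        mask &= pd.notna(data[c]).to_numpy()
    return data.loc[mask]


def fit_logistic(data: pd.DataFrame, outcome: str, exposure: str,
                 pcs: Sequence[str] = PC_COLUMNS,
                 study_col: Optional[str] = "study",
                 cluster: bool = True) -> ModelFit:
    """PC/study-adjusted logistic regression with study-clustered errors."""
    use = _complete_rows(data, [outcome, exposure, *pcs])
    X = build_design(use, exposure, pcs, study_col)
    y = use[outcome].astype(float).to_numpy()
    clusters = None
    if cluster and study_col is not None and use[study_col].nunique() > 1:
        clusters = use[study_col].to_numpy()
    est = ClusterRobustLogit().fit(X, y, clusters=clusters, protected=(exposure,))
    j = est.feature_names_.index(exposure)
    return ModelFit(term=exposure, estimate=float(est.coef_[j]),
                    se=float(est.bse_[j]), n=len(use), scale="logodds",
                    model=est, n_clusters=est.n_clusters_,
                    converged=est.converged_)


def fit_linear_robust(data: pd.DataFrame, outcome: str, exposure: str,
                      pcs: Sequence[str] = PC_COLUMNS,
                      study_col: Optional[str] = None,
                      clusters=None) -> ModelFit:
    """OLS with HC1 robust errors (per-study first stage: GRS → cups/day)."""
    use = _complete_rows(data, [outcome, exposure, *pcs])
    X = build_design(use, exposure, pcs, study_col)
    y = use[outcome].astype(float).to_numpy()
    est = RobustOLS().fit(X, y, clusters=clusters, protected=(exposure,))
    j = est.feature_names_.index(exposure)
    return ModelFit(term=exposure, estimate=float(est.coef_[j]),
                    se=float(est.bse_[j]), n=len(use), scale="linear", model=est)


def cluster_robust_cov(fit: ModelFit, cluster_ids) -> np.ndarray:
    """Re-derive the study-clustered sandwich covariance for a fitted model.

    Uses the per-observation score rows stored on the underlying estimator;
    sandwich is A⁻¹ B A⁻¹ with B built from per-cluster score sums scaled by
    G/(G−1). With a single cluster this is undefined and an error advises the
    unclustered robust variance instead.
    """
    est = fit.model
    if est is None or not hasattr(est, "_score_rows_"):
        raise ValueError("fit does not carry per-observation scores")
    cov = cluster_sandwich(est._info_, est._score_rows_, cluster_ids)
    full = np.full_like(est.cov_model_, np.nan)
    keep = est._keep_idx_
    full[np.ix_(keep, keep)] = cov
    return full


def subgroup_interaction(data: pd.DataFrame, outcome: str, exposure: str,
                         stratum_col: str = "smoking",
                         strata=("ever", "never"),
                         pcs: Sequence[str] = PC_COLUMNS,
                         study_col: Optional[str] = "study") -> dict:
    """Stratum-specific fits plus a product-term interaction test.

    Fits the adjusted logistic model within each stratum, then a pooled model
    adding an exposure × stratum product term, and reports the product term's
    Wald p-value. A stratum whose outcome does not vary is skipped with a
    warning.
    """
    out = {"strata": {}, "interaction_p": None}
    kept = []
    for s in strata:
        sub = data[data[stratum_col] == s]
        if len(sub) == 0:
            warnings.warn(f"stratum {s!r} is empty; skipped", stacklevel=2)
            continue
        if sub[outcome].nunique() < 2:
            warnings.warn(f"stratum {s!r} has a single outcome class; skipped",
                          stacklevel=2)
            continue
        out["strata"][s] = fit_logistic(sub, outcome, exposure, pcs, study_col)
        kept.append(s)
    if len(kept) == 2:
        pooled = data[data[stratum_col].isin(kept)].copy()
        ind = (pooled[stratum_col] == kept[1]).astype(float)
        pooled["_stratum"] = ind
        pooled["_interaction"] = pooled[exposure] * ind
        use = _complete_rows(pooled, [outcome, exposure, *pcs])
        X = build_design(use, exposure, pcs, study_col)
        X["_stratum"] = use["_stratum"].to_numpy()
        X["_interaction"] = use["_interaction"].to_numpy()
        y = use[outcome].astype(float).to_numpy()
        clusters = (use[study_col].to_numpy()
                    if study_col is not None and use[study_col].nunique() > 1 else None)
        est = ClusterRobustLogit().fit(X, y, clusters=clusters,
                                       protected=(exposure, "_interaction"))
        j = est.feature_names_.index("_interaction")
        se = est.bse_[j]
        out["interaction_p"] = float(2.0 * stats.norm.sf(abs(est.coef_[j]) / se))
        out["interaction_coef"] = float(est.coef_[j])
        out["interaction_se"] = float(se)
    return out
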