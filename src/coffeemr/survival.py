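"""Survival analysis of prostate cancer cases on the age timescale.

Cases enter the risk set at their age at diagnosis (delayed entry / left
truncation) and exit at death or last follow-up. The Cox model is fitted by
:class:`coffeemr.models.LeftTruncatedCoxPH` (Efron ties, study-clustered
robust variance); :func:`ph_test` checks proportional hazards with a
Grambsch–Therneau score test on scaled Schoenfeld residuals against event age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import ModelFit, PC_COLUMNS, build_design, _complete_rows
from .models import LeftTruncatedCoxPH

__all__ = ["SurvivalRecord", "fit_cox", "ph_test"]


@dataclass(frozen=True)
class SurvivalRecord:
    """One case's follow-up interval on the age timescale."""

    entry_age: float
    exit_age: float
    event: int
    study: str

    def __post_init__(self):
        if self.exit_age < self.entry_age:
            raise ValueError("exit age before entry age")
        if self.event not in (0, 1):
            raise ValueError("event must be 0/1")


def fit_cox(data: pd.DataFrame, exposure: str, event_col: str,
            entry_col: str = "entry_age", exit_col: str = "exit_age",
            pcs: Sequence[str] = PC_COLUMNS,
            study_col: Optional[str] = "study",
            cluster: bool = True) -> ModelFit:
    """Left-truncated, PC/study-adjusted Cox model; returns the exposure term.

    Hazard ratios are per unit of ``exposure`` (per coffee-increasing allele
    for a SNP dosage or the GRS) with study-clustered robust standard errors.
    """
    use = _complete_rows(data, [exposure, event_col, entry_col, exit_col, *pcs])
    X = build_design(use, exposure, pcs, study_col)
    clusters = None
    if cluster and study_col is not None and use[study_col].nunique() > 1:
        clusters = use[study_col].to_numpy()
    est = LeftTruncatedCoxPH().fit(
        X,
        entry=use[entry_col].to_numpy(dtype=float),
        exit=use[exit_col].to_numpy(dtype=float),
        event=use[event_col].to_numpy(dtype=int),
        clusters=clusters,
        protected=(exposure,),
    )
    j = est.feature_names_.index(exposure)
    return ModelFit(term=exposure, estimate=float(est.coef_[j]),
                    se=float(est.bse_[j]), n=len(use), scale="loghazard",
                    model=est, n_clusters=est.n_clusters_,
                    n_events=est.n_events_)


def ph_test(fit: ModelFit, time_transform="identity") -> dict:
    """Proportional-hazards score test from scaled Schoenfeld residuals.

    Regresses each covariate's scaled Schoenfeld residual on (transformed)
    event age; under proportional hazards the slope is zero. Returns
    per-covariate chi-square(1) p-values and a global chi-square(p) p-value.
    The global test is skipped with a warning when there are fewer events
    than covariates.
    """
    est = fit.model
    if not isinstance(est, LeftTruncatedCoxPH):
        raise TypeError("ph_test requires a Cox model fit")
    times, resid = est.schoenfeld_residuals()
    d, p = resid.shape
    if d < 2:
        raise ValueError("need at least 2 events for the PH test")
    if time_transform == "identity":
        g = times.astype(float)
    elif time_transform == "rank":
        g = stats.rankdata(times).astype(float)
    else:
        raise ValueError(f"unknown time transform {time_transform!r}")
    gc = g - g.mean()
    gss = float(gc @ gc)
    if gss <= 0:
        raise ValueError("event ages are all tied; PH test undefined")

    keep = est._keep_idx_
    vhat = est.cov_model_[np.ix_(keep, keep)]
    u = resid.T @ gc  # (p,)
    per_term = {}
    names = [est.feature_names_[j] for j in keep]
    vu = vhat @ u
    for j, name in enumerate(names):
        chi2_j = d * vu[j] ** 2 / (vhat[j, j] * gss)
        per_term[name] = float(stats.chi2.sf(chi2_j, df=1))
    result = {"per_covariate": per_term, "global_p": None, "n_events": d}
    if d <= p:
        warnings.warn("fewer events than covariates; global PH test skipped",
                      stacklevel=2)
        return result
    chi2_g = d * float(u @ vhat @ u) / gss
    result["global_p"] = float(stats.chi2.sf(chi2_g, df=p))
    result["global_chi2"] = chi2_g
    return result


def person_years(data: pd.DataFrame, entry_col="entry_age",
                 exit_col="exit_age") -> float:
    """Total follow-up time in years."""
    return float((data[exit_col] - data[entry_col]).sum())
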