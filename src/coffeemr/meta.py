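"""Fixed-effect and DerSimonian–Laird random-effects meta-analysis.

Per-study estimates (log odds ratios, log hazard ratios, or cups/day slopes)
are pooled with inverse-variance weights. Heterogeneity is summarised by
Cochran's Q, the DL between-study variance τ², and I² = max(0, (Q−(k−1))/Q)·100.
Normal-approximation confidence intervals throughout (no Knapp–Hartung).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .models import Z_95

__all__ = [
    "StudyEstimate",
    "MetaResult",
    "FixedEffectMeta",
    "DerSimonianLairdMeta",
    "fixed_effect",
    "random_effects_dl",
    "heterogeneity",
    "forest_table",
]


@dataclass(frozen=True)
class StudyEstimate:
    """One study's effect estimate with its standard error."""

    label: str
    estimate: float
    se: float
    n: Optional[int] = None

    def __post_init__(self):
        if not np.isfinite(self.estimate):
            raise ValueError(f"study {self.label}: non-finite estimate")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValueError(f"study {self.label}: SE must be positive")


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate with heterogeneity statistics."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    q: float
    tau2: float
    i2: float
    model: str
    k: int
    weights: tuple = field(default=(), repr=False)

    def as_dict(self):
        return {k: getattr(self, k) for k in
                ("estimate", "se", "ci_low", "ci_high", "q", "tau2", "i2", "model", "k")}


def _unpack(estimates: Sequence[StudyEstimate]):
    beta = np.array([e.estimate for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    return beta, se


def _q_stat(beta, se):
    w = 1.0 / se**2
    pooled = float(w @ beta / w.sum())
    q = float(w @ (beta - pooled) ** 2)
    return q, pooled, w


class FixedEffectMeta(BaseEstimator):
    """Inverse-variance fixed-effect pooling."""

    def fit(self, estimates: Sequence[StudyEstimate]):
        beta, se = _unpack(estimates)
        k = beta.size
        if k < 1:
            raise ValueError("need at least one study")
        q, pooled, w = _q_stat(beta, se)
        pooled_se = float(w.sum() ** -0.5)
        i2 = _i2_from_q(q, k)
        self.result_ = MetaResult(
            estimate=pooled, se=pooled_se,
            ci_low=pooled - Z_95 * pooled_se, ci_high=pooled + Z_95 * pooled_se,
            q=q, tau2=0.0, i2=i2, model="fixed", k=k,
            weights=tuple(w / w.sum()))
        return self


class DerSimonianLairdMeta(BaseEstimator):
    """DerSimonian–Laird random-effects pooling."""

    def fit(self, estimates: Sequence[StudyEstimate]):
        beta, se = _unpack(estimates)
        k = beta.size
        if k < 2:
            raise ValueError("random-effects pooling needs k >= 2; use fixed_effect")
        q, _, w = _q_stat(beta, se)
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom)
        w_re = 1.0 / (se**2 + tau2)
        pooled = float(w_re @ beta / w_re.sum())
        pooled_se = float(w_re.sum() ** -0.5)
        self.result_ = MetaResult(
            estimate=pooled, se=pooled_se,
            ci_low=pooled - Z_95 * pooled_se, ci_high=pooled + Z_95 * pooled_se,
            q=q, tau2=tau2, i2=_i2_from_q(q, k), model="random", k=k,
            weights=tuple(w_re / w_re.sum()))
        return self


def _i2_from_q(q: float, k: int) -> float:
    if k < 2 or q <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / q) * 100.0


def fixed_effect(estimates: Sequence[StudyEstimate]) -> MetaResult:
    """Inverse-variance fixed-effect meta-analysis."""
    return FixedEffectMeta().fit(estimates).result_


def random_effects_dl(estimates: Sequence[StudyEstimate]) -> MetaResult:
    """DerSimonian–Laird random-effects meta-analysis."""
    return DerSimonianLairdMeta().fit(estimates).result_


def heterogeneity(estimates: Sequence[StudyEstimate]):
    """Cochran's Q and I² (%); (nan, nan) when k < 2."""
    beta, se = _unpack(estimates)
    k = beta.size
    if k < 2:
        return float("nan"), float("nan")
    q, _, _ = _q_stat(beta, se)
    return q, _i2_from_q(q, k)


def plot_forest(table: pd.DataFrame, path, xlabel="estimate",
                ref_line: float = 0.0):
    """Render a forest plot from a :func:`forest_table` frame (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.5 * len(table) + 1.5))
    ys = np.arange(len(table))[::-1]
    for y, (_, row) in zip(ys, table.iterrows()):
        pooled = str(row["study"]).startswith("pooled")
        ax.plot([row["ci_low"], row["ci_high"]], [y, y],
                color="0.2", lw=1.2)
        ax.plot(row["estimate"], y, "D" if pooled else "s",
                color="tab:red" if pooled else "0.2",
                markersize=7 if pooled else 5)
    ax.axvline(ref_line, color="0.6", ls="--", lw=0.8)
    ax.set_yticks(ys)
    ax.set_yticklabels(table["study"])
    ax.set_xlabel(xlabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def forest_table(estimates: Sequence[StudyEstimate], result: MetaResult,
                 exponentiate: bool = False) -> pd.DataFrame:
    """Per-study rows plus a pooled row, suitable for forest plotting."""
    rows = []
    tf = np.exp if exponentiate else (lambda x: x)
    for e, w in zip(estimates, result.weights):
        rows.append({
            "study": e.label,
            "estimate": tf(e.estimate),
            "ci_low": tf(e.estimate - Z_95 * e.se),
            "ci_high": tf(e.estimate + Z_95 * e.se),
            "weight_pct": 100.0 * w,
            "n": e.n,
        })
    rows.append({
        "study": f"pooled ({result.model})",
        "estimate": tf(result.estimate),
        "ci_low": tf(result.ci_low),
        "ci_high": tf(result.ci_high),
        "weight_pct": 100.0,
        "n": sum(e.n for e in estimates if e.n is not None) or None,
    })
    return pd.DataFrame(rows)
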