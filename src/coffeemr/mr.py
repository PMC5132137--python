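"""Mendelian-randomization computations: scaling, Wald ratio, power.

Three small, closed-form pieces that sit on top of the association models:

* :func:`scale_categorical_or` converts an extreme-category odds ratio from
  the observational literature (e.g. ≥4 vs <1 cups/day) to a per-unit OR
  assuming log-linearity in cups;
* :func:`wald_ratio` forms the causal log OR per cup as the reduced-form
  coefficient divided by the first-stage (GRS → cups/day) coefficient, with a
  first-order delta-method standard error;
* :func:`detectable_or` gives the minimal detectable per-allele OR of a
  case-control analysis from the Wald-test approximation
  SE(β̂) ≈ 1/√(N φ(1−φ) σ²_G).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerInputs",
    "scale_categorical_or",
    "wald_ratio",
    "detectable_or",
    "grs_variance",
    "scaling_sensitivity_table",
    "WEAK_INSTRUMENT_F",
]

# weak-instrument rule of thumb: first-stage F (= (γ/SE)²) below 10
WEAK_INSTRUMENT_F = 10.0


@dataclass(frozen=True)
class PowerInputs:
    """Sample-size and instrument inputs for the minimal-detectable-OR formula."""

    n_cases: int
    n_controls: int
    var_grs: float                 # σ²_G of the instrument
    gamma: float = 0.10            # first-stage cups/day per allele
    alpha: float = 0.05            # two-sided
    power: float = 0.80

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if self.var_grs <= 0:
            raise ValueError("instrument variance must be positive")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must be in (0, 1)")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


def grs_variance(freqs) -> float:
    """Variance of the risk score from allele frequencies: Σ 2f(1−f)."""
    f = np.asarray(freqs, dtype=float)
    return float(np.sum(2.0 * f * (1.0 - f)))


def scale_categorical_or(or_extreme: float, contrast_cups: float,
                         per_unit_cups: float) -> float:
    """Rescale an extreme-category OR to an OR per ``per_unit_cups``.

    ``exp(ln(OR) · per_unit / contrast)`` under log-linearity in cups/day.
    """
    if or_extreme <= 0 or contrast_cups <= 0 or per_unit_cups <= 0:
        raise ValueError("all inputs must be positive")
    return float(np.exp(np.log(or_extreme) * per_unit_cups / contrast_cups))


def scaling_sensitivity_table(or_extreme: float, per_unit_cups: float,
                              contrasts=(2.5, 3.0, 3.5, 4.0, 5.0, 6.0)) -> pd.DataFrame:
    """Per-unit OR across plausible extreme-category contrasts (cups/day)."""
    rows = [{"contrast_cups": c,
             "or_per_unit": scale_categorical_or(or_extreme, c, per_unit_cups)}
            for c in contrasts]
    return pd.DataFrame(rows)


def wald_ratio(beta_reduced: float, se_reduced: float,
               gamma: float, se_gamma: float) -> dict:
    """Wald-ratio causal estimate: log OR per cup = β_reduced / γ.

    First-order delta-method SE: √(SE_r²/γ² + β_r²·SE_γ²/γ⁴). Flags a
    weak-instrument warning when the first-stage F statistic (γ/SE_γ)² < 10.
    """
    if gamma == 0:
        raise ValueError("first-stage coefficient is zero; ratio undefined")
    est = beta_reduced / gamma
    var = se_reduced**2 / gamma**2 + beta_reduced**2 * se_gamma**2 / gamma**4
    se = float(np.sqrt(var))
    weak = False
    if se_gamma > 0:
        f_stat = (gamma / se_gamma) ** 2
        weak = f_stat < WEAK_INSTRUMENT_F
        if weak:
            warnings.warn(
                f"weak instrument: first-stage F = {f_stat:.2f} < "
                f"{WEAK_INSTRUMENT_F:g}", stacklevel=2)
    z = abs(est) / se if se > 0 else np.inf
    return {
        "log_or_per_cup": float(est),
        "se": se,
        "or_per_cup": float(np.exp(est)),
        "ci_low": float(np.exp(est - 1.959963984540054 * se)),
        "ci_high": float(np.exp(est + 1.959963984540054 * se)),
        "p": float(2.0 * stats.norm.sf(z)),
        "weak_instrument": weak,
    }


def detectable_or(inputs: PowerInputs) -> dict:
    """Minimal detectable per-allele OR (< 1 side) of the reduced-form test.

    With N = cases + controls and case fraction φ, the per-allele log-odds SE
    is approximately 1/√(N φ(1−φ) σ²_G); the detectable effect magnitude is
    (z_{1−α/2} + z_{power})·SE. Also reported on the per-cup and per-0.06-cup
    scales via the first-stage γ.
    """
    phi = inputs.case_fraction
    if phi <= 0.0 or phi >= 1.0:
        raise ValueError("degenerate case fraction")
    se = 1.0 / np.sqrt(inputs.n_total * phi * (1.0 - phi) * inputs.var_grs)
    z_a = stats.norm.ppf(1.0 - inputs.alpha / 2.0)
    z_p = stats.norm.ppf(inputs.power)
    beta = (z_a + z_p) * se
    out = {
        "se_per_allele": float(se),
        "detectable_log_or_per_allele": float(beta),
        "detectable_or_per_allele": float(np.exp(-beta)),
    }
    if inputs.gamma:
        out["detectable_or_per_cup"] = float(np.exp(-beta / inputs.gamma))
        out["detectable_or_per_0.06_cups"] = float(
            np.exp(-beta * 0.06 / inputs.gamma))
    return out
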