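"""Variant QC, allele orientation and genetic risk score construction.

The instrument is a two-SNP genetic risk score (GRS) for caffeine intake:
rs4410790 (AHR) and rs2472297 (CYP1A1/2). Imputed allele dosages (continuous
in [0, 2]) are oriented to count coffee-consumption-increasing alleles — the
major allele for rs4410790 and the minor allele for rs2472297 — and summed
under an additive model, giving a score in [0, 4].

Variant QC mirrors consortium genotyping practice: call rate >= 95 %,
Hardy–Weinberg equilibrium in controls at p >= 1e-7, imputation R² >= 0.3.
Thresholds are applied inclusively (a variant sitting exactly on a threshold
passes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantSpec",
    "VariantQCReport",
    "DEFAULT_VARIANTS",
    "orient_dosage",
    "compute_grs",
    "hwe_test",
    "qc_variants",
    "CALL_RATE_MIN",
    "HWE_P_MIN",
    "IMPUTATION_R2_MIN",
]

CALL_RATE_MIN = 0.95
HWE_P_MIN = 1e-7
IMPUTATION_R2_MIN = 0.3


@dataclass(frozen=True)
class VariantSpec:
    """Identity and allele orientation of one instrument SNP.

    ``counted_allele`` is the allele whose dosage the genotype file stores;
    ``coffee_increasing_allele`` the allele to be counted in the risk score.
    Orientation comes from this spec, never re-derived from sample
    frequencies, so it cannot flip between datasets.
    """

    rsid: str
    counted_allele: str
    coffee_increasing_allele: str
    other_allele: str
    locus: str
    chrom: str = "0"
    pos: int = 0

    def __post_init__(self):
        alleles = {self.counted_allele, self.other_allele}
        if len(alleles) != 2:
            raise ValueError(f"{self.rsid}: counted and other allele must differ")
        if self.coffee_increasing_allele not in alleles:
            raise ValueError(
                f"{self.rsid}: coffee-increasing allele "
                f"{self.coffee_increasing_allele!r} is not one of {sorted(alleles)}")
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        if comp.get(self.counted_allele) == self.other_allele:
            raise ValueError(
                f"{self.rsid}: A/T or C/G variant is strand-ambiguous; "
                "resolve orientation upstream")

    @property
    def needs_flip(self) -> bool:
        return self.counted_allele != self.coffee_increasing_allele


# The two caffeine-intake loci. Alleles follow dbSNP (rs4410790 T/C with C the
# major, coffee-increasing allele; rs2472297 C/T with T the minor,
# coffee-increasing allele); genotype files here store the ALT (minor) dosage.
DEFAULT_VARIANTS = (
    VariantSpec(rsid="rs4410790", counted_allele="T", other_allele="C",
                coffee_increasing_allele="C", locus="AHR", chrom="7", pos=17284577),
    VariantSpec(rsid="rs2472297", counted_allele="T", other_allele="C",
                coffee_increasing_allele="T", locus="CYP1A1/2", chrom="15",
                pos=75027880),
)


@dataclass(frozen=True)
class VariantQCReport:
    """QC outcome for one variant; pass requires all three criteria."""

    rsid: str
    call_rate: float
    hwe_p: Optional[float]
    imputation_r2: float
    passed: bool
    failure_reasons: tuple = field(default=())


def orient_dosage(dosage, spec: VariantSpec):
    """Re-express a stored dosage as the coffee-increasing-allele dosage.

    Identity when the counted allele is the increasing allele, else the
    reflection 2 − d. NaN propagates.
    """
    d = np.asarray(dosage, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (d < 0) | (d > 2)
    if np.any(bad & ~np.isnan(d)):
        raise ValueError(f"{spec.rsid}: dosage outside [0, 2]")
    out = (2.0 - d) if spec.needs_flip else d
    if np.isscalar(dosage):
        return float(out)
    return out


def compute_grs(*oriented_dosages):
    """Sum oriented dosages into the risk score; missing propagates to missing.

    Accepts one array per variant (or a single 2-D array with variants in
    columns). The score is never imputed: any missing component dosage makes
    the score missing.
    """
    if len(oriented_dosages) == 1 and np.asarray(oriented_dosages[0]).ndim == 2:
        mat = np.asarray(oriented_dosages[0], dtype=float)
    else:
        mat = np.column_stack([np.asarray(d, dtype=float) for d in oriented_dosages])
    return mat.sum(axis=1)  # nan propagates through sum


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Chi-square (1 df) Hardy–Weinberg goodness-of-fit p-value.

    Applied to hard-called genotype counts (controls only, upstream).
    Monomorphic input returns p = 1 with a warning.
    """
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("no genotypes supplied")
    p_alt = (counts[2] * 2 + counts[1]) / (2 * n)
    if p_alt in (0.0, 1.0):
        warnings.warn("monomorphic variant; HWE test degenerate, p = 1", stacklevel=2)
        return 1.0
    expected = n * np.array([(1 - p_alt) ** 2, 2 * p_alt * (1 - p_alt), p_alt**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hard_calls(dosage):
    return np.round(dosage).astype(int)


def qc_variants(dosages: pd.DataFrame, is_case, specs: Sequence[VariantSpec],
                imputation_r2: dict) -> list[VariantQCReport]:
    """One QC report per variant.

    ``dosages`` has one column per rsid (stored-allele scale, NaN = missing);
    ``is_case`` aligns with rows; ``imputation_r2`` maps rsid to the imputation
    quality. HWE is evaluated on hard-called genotypes among controls, and only
    when the dosages are effectively hard calls (r² = 1); otherwise it is
    skipped with a warning and does not fail the variant.
    """
    is_case = np.asarray(is_case, dtype=bool)
    if is_case.size != len(dosages):
        raise ValueError("case/control labels do not align with dosage rows")
    reports = []
    any_controls = bool(np.any(~is_case))
    if not any_controls:
        warnings.warn("no controls present; HWE not assessable", stacklevel=2)
    for spec in specs:
        d = np.asarray(dosages[spec.rsid], dtype=float)
        call_rate = float(np.mean(~np.isnan(d)))
        r2 = float(imputation_r2[spec.rsid])
        reasons = []
        if call_rate < CALL_RATE_MIN:
            reasons.append("call_rate")
        if r2 < IMPUTATION_R2_MIN:
            reasons.append("imputation_r2")
        hwe_p = None
        if any_controls and r2 >= 1.0:
            dc = d[~is_case]
            dc = dc[~np.isnan(dc)]
            if dc.size:
                g = _hard_calls(dc)
                hwe_p = hwe_test(int(np.sum(g == 0)), int(np.sum(g == 1)),
                                 int(np.sum(g == 2)))
                if hwe_p < HWE_P_MIN:
                    reasons.append("hwe")
        elif any_controls:
            warnings.warn(
                f"{spec.rsid}: dosages are imputed (r2={r2:g} < 1); "
                "HWE test on hard calls skipped", stacklevel=2)
        reports.append(VariantQCReport(
            rsid=spec.rsid, call_rate=call_rate, hwe_p=hwe_p,
            imputation_r2=r2, passed=not reasons,
            failure_reasons=tuple(reasons)))
    return reports
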