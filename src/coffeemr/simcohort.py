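"""Synthetic multi-study case-control consortium generator.

Emulates the data structure of a 25-study prostate cancer consortium of
~46,687 men: imputed dosages at the two caffeine-intake loci, coffee/tea
consumption confounded by smoking, case status with a per-allele effect of
the genetic risk score (GRS), stage and grade among cases, and mortality
follow-up with administrative censoring of varying completeness.

Generative model, per study (one independent random stream per study, spawned
from the master seed so adding a study never perturbs earlier studies):

* hard genotypes Binomial(2, f) per variant, blended with Gaussian noise so
  that corr(dosage, hard call)² ≈ the configured imputation r² and clipped to
  [0, 2] (dosage variance shrinks with r², as with imputed dosages);
* smoking U ~ Bernoulli(confounder_prev);
* cups/day = study mean + γ·GRS + confounder effect·U + mean-centred gamma
  noise (right-skewed with a bounded left tail, so the zero-truncation never
  binds and the generative slope is exact); the combined coffee+tea slope is
  ``gamma_coffee``, split between beverages by ``coffee_share``;
* case status Bernoulli with logit = α + θ·GRS + confounder_logor·U, α solved
  so the expected case fraction equals the configured φ;
* among cases: nonlocalised stage and high grade Bernoulli with per-allele
  log-odds, re-expressed as TNM strings (odd-numbered studies) or SEER labels
  (even-numbered) and Gleason integers;
* mortality on the AGE timescale: entry at diagnosis age ~ Normal, death age
  from a left-truncated Weibull whose prostate-cancer and other-cause
  components carry ``loghr_pca`` and ``loghr_allcause`` per GRS allele
  respectively (setting both equal gives that all-cause hazard ratio);
  administrative censoring ``followup_years`` after diagnosis; the Weibull
  scale can be calibrated to an expected death fraction;
* eight principal components as pure standard-normal noise covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import io as cio
from .genetics import DEFAULT_VARIANTS, VariantSpec

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "calibrate_weibull_scale",
]

_TNM_LOCALISED = ("T1 N0 M0", "T2 N0 M0", "T1 NX MX", "T2 N0 MX")
_TNM_NONLOCALISED = ("T3 N0 M0", "T4 N0 M0", "T2 N1 M0", "T2 N0 M1")


@dataclass
class SimulationConfig:
    """All generative parameters for one synthetic consortium.

    Defaults describe a consortium of the published size and composition:
    25 studies, ~46,687 men, two of the studies case-only, four studies with
    coffee/tea questionnaire data, per-allele effects at the published point
    estimates. Allele frequencies (0.63, 0.26) are implementation defaults —
    the source tables never print frequencies — and are configurable.
    """

    n_studies: int = 25
    study_sizes: Optional[Sequence[int]] = None          # default: even split
    total_n: int = 46687
    case_fraction: float | Sequence[float] = 0.4966      # φ per study (1.0 = case-only)
    case_only_studies: Sequence[int] = (23, 24)          # 0-based indices
    n_coffee_studies: int = 4                            # leading studies with cups data

    freq_increasing: Sequence[float] = (0.63, 0.26)      # per variant
    imputation_r2: Sequence[float] = (0.9, 0.9)

    gamma_coffee: float = 0.10          # combined coffee+tea cups/day per allele
    coffee_share: float = 0.6           # fraction of gamma on coffee (rest on tea)
    coffee_mean: float = 1.8            # study-mean cups of coffee/day
    tea_mean: float = 1.4
    coffee_noise_sd: float = 0.9        # sd of the right-skewed residual
    tea_noise_sd: float = 0.8

    confounder_prev: float = 0.55       # smoking (ever) prevalence
    confounder_coffee_effect: float = 0.5   # cups/day added for smokers
    confounder_logor: float = 0.182         # smoking → case status log-odds

    theta_reduced: float = float(np.log(1.01))   # GRS → case status
    stage_logor: float = float(np.log(1.03))     # GRS → nonlocalised (cases)
    grade_logor: float = float(np.log(1.01))     # GRS → high grade (cases)
    nonlocalised_frac: float = 0.2455
    high_grade_frac: float = 0.491

    loghr_pca: float = float(np.log(1.03))   # GRS → prostate-cancer death hazard
    loghr_allcause: float = 0.0              # GRS → other-cause death hazard
    death_frac: float = 0.2624               # expected deaths / cases before censoring
    pca_death_share: float = 0.48            # expected share of deaths from PCa
    baseline_hazard_shape: float = 1.2       # Weibull shape (age timescale)
    baseline_hazard_scale: Optional[float] = None   # None → calibrated to death_frac
    followup_years: float = 9.0              # administrative censoring horizon
    entry_age_mean: float = 65.0
    entry_age_sd: float = 8.0

    unknown_vital_rate: float = 0.03
    unknown_cause_rate: float = 0.05
    missing_smoking_rate: float = 0.05

    seed: int = 20160701

    def __post_init__(self):
        if self.study_sizes is None:
            base, rem = divmod(int(self.total_n), int(self.n_studies))
            self.study_sizes = [base + (1 if i < rem else 0)
                                for i in range(self.n_studies)]
        self.study_sizes = [int(s) for s in self.study_sizes]
        if len(self.study_sizes) != self.n_studies:
            raise ValueError("study_sizes length must equal n_studies")
        if any(s <= 0 for s in self.study_sizes):
            raise ValueError("study sizes must be positive")
        phi = self.case_fraction
        if np.isscalar(phi):
            phi = [float(phi)] * self.n_studies
        phi = [float(p) for p in phi]
        for i in self.case_only_studies:
            if 0 <= i < self.n_studies:
                phi[i] = 1.0
        self.case_fraction = phi
        for p in phi:
            if not (0.0 < p <= 1.0):
                raise ValueError(f"case fraction {p} outside (0, 1]")
        for f in self.freq_increasing:
            if not (0.0 < f < 1.0):
                raise ValueError(f"allele frequency {f} outside (0, 1)")
        for r in self.imputation_r2:
            if not (0.0 < r <= 1.0):
                raise ValueError(f"imputation r2 {r} outside (0, 1]")
        if not (0.0 <= self.coffee_share <= 1.0):
            raise ValueError("coffee_share must be in [0, 1]")

    def as_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**d)


def simulate_genotypes(n: int, freq: float, r2: float, rng) -> np.ndarray:
    """Imputed dosages of the increasing allele for ``n`` individuals.

    Hard genotypes Binomial(2, freq) blended as
    ``d = 2f + r2 (g − 2f) + sqrt(r2 (1 − r2)) σ_g z`` and clipped to [0, 2],
    so corr(d, g)² ≈ r2 and the mean stays 2f; r2 = 1 returns hard calls.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0.0 < freq < 1.0):
        raise ValueError("freq must be in (0, 1)")
    if not (0.0 < r2 <= 1.0):
        raise ValueError("r2 must be in (0, 1]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    g = rng.binomial(2, freq, size=n).astype(float)
    if r2 >= 1.0:
        return g
    mu = 2.0 * freq
    sigma_g = np.sqrt(2.0 * freq * (1.0 - freq))
    z = rng.standard_normal(n)
    d = mu + r2 * (g - mu) + np.sqrt(r2 * (1.0 - r2)) * sigma_g * z
    return np.clip(d, 0.0, 2.0)


def _solve_intercept(target: float, offsets: np.ndarray, what: str) -> float:
    """Intercept a with mean(expit(a + offsets)) = target."""
    def f(a):
        return float(np.mean(special.expit(a + offsets))) - target
    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"unattainable {what} fraction {target} given effects")
    return optimize.brentq(f, lo, hi, xtol=1e-10)


def calibrate_weibull_scale(entry_ages: np.ndarray, hazard_weights: np.ndarray,
                            shape: float, followup_years: float,
                            target_frac: float) -> float:
    """Weibull scale λ giving an expected pre-censoring death fraction.

    Solves mean over subjects of
    ``1 − exp(−w_i [((a0_i+F)/λ)^k − (a0_i/λ)^k])`` = ``target_frac``.
    """
    if not (0.0 < target_frac < 1.0):
        raise ValueError("target death fraction must be in (0, 1)")
    a0 = np.asarray(entry_ages, dtype=float)
    w = np.asarray(hazard_weights, dtype=float)

    def frac(log_scale):
        lam = np.exp(log_scale)
        dh = w * (((a0 + followup_years) / lam) ** shape - (a0 / lam) ** shape)
        return float(np.mean(-np.expm1(-dh))) - target_frac

    return float(np.exp(optimize.brentq(frac, np.log(1e-2), np.log(1e6),
                                        xtol=1e-10)))


def _skew_noise(rng, n: int, sd: float) -> np.ndarray:
    """Mean-zero right-skewed residual: Gamma(2, sd/√2) − mean (left tail ≥ −2·sd/√2)."""
    theta = sd / np.sqrt(2.0)
    return rng.gamma(2.0, theta, size=n) - 2.0 * theta


def _simulate_study(idx: int, n: int, phi: float, cfg: SimulationConfig,
                    rng: np.random.Generator,
                    specs: Sequence[VariantSpec]) -> pd.DataFrame:
    label = f"S{idx + 1:02d}"
    # dosages on the coffee-increasing-allele scale
    inc = [simulate_genotypes(n, f, r2, rng)
           for f, r2 in zip(cfg.freq_increasing, cfg.imputation_r2)]
    grs = np.sum(inc, axis=0)
    smoker = rng.binomial(1, cfg.confounder_prev, size=n).astype(float)

    has_cups = idx < cfg.n_coffee_studies
    coffee = np.full(n, np.nan)
    tea = np.full(n, np.nan)
    if has_cups:
        g_cof = cfg.gamma_coffee * cfg.coffee_share
        g_tea = cfg.gamma_coffee * (1.0 - cfg.coffee_share)
        coffee = (cfg.coffee_mean + g_cof * grs
                  + cfg.confounder_coffee_effect * cfg.coffee_share * smoker
                  + _skew_noise(rng, n, cfg.coffee_noise_sd))
        tea = (cfg.tea_mean + g_tea * grs
               + cfg.confounder_coffee_effect * (1.0 - cfg.coffee_share) * smoker
               + _skew_noise(rng, n, cfg.tea_noise_sd))
        coffee = np.maximum(coffee, 0.0)
        tea = np.maximum(tea, 0.0)

    offsets = cfg.theta_reduced * grs + cfg.confounder_logor * smoker
    if phi >= 1.0:
        is_case = np.ones(n, dtype=int)
    else:
        alpha = _solve_intercept(phi, offsets, "case")
        is_case = rng.binomial(1, special.expit(alpha + offsets)).astype(int)

    df = pd.DataFrame({
        "sample_id": [f"{label}_{i:05d}" for i in range(n)],
        "study": label,
        "is_case": is_case,
        "coffee_cups": np.round(coffee, 3),
        "tea_cups": np.round(tea, 3),
    })
    # stored (counted-allele) dosage per variant; flip where counted != increasing
    for spec, d_inc in zip(specs, inc):
        stored = 2.0 - d_inc if spec.needs_flip else d_inc
        df[f"dosage_{spec.rsid}"] = np.round(stored, 4)

    case = is_case == 1
    n_case = int(case.sum())
    tnm = np.full(n, np.nan, dtype=object)
    seer = np.full(n, np.nan, dtype=object)
    gleason = np.full(n, np.nan)
    entry_age = np.full(n, np.nan)
    exit_age = np.full(n, np.nan)
    vital = np.full(n, np.nan, dtype=object)
    cause = np.full(n, np.nan, dtype=object)

    if n_case:
        g_case = grs[case]
        a_stage = _solve_intercept(cfg.nonlocalised_frac,
                                   cfg.stage_logor * g_case, "nonlocalised")
        nonloc = rng.binomial(1, special.expit(
            a_stage + cfg.stage_logor * g_case)).astype(bool)
        a_grade = _solve_intercept(cfg.high_grade_frac,
                                   cfg.grade_logor * g_case, "high-grade")
        high = rng.binomial(1, special.expit(
            a_grade + cfg.grade_logor * g_case)).astype(bool)

        use_tnm = (idx % 2) == 0   # odd-numbered study labels (S01, S03, ...)
        stage_strings = np.where(
            nonloc,
            rng.choice(_TNM_NONLOCALISED, size=n_case),
            rng.choice(_TNM_LOCALISED, size=n_case))
        seer_labels = np.where(
            nonloc, rng.choice(("regional", "distant"), size=n_case), "local")
        if use_tnm:
            tnm[case] = stage_strings
        else:
            seer[case] = seer_labels
        gleason[case] = np.where(high, rng.integers(7, 10, size=n_case),
                                 rng.integers(5, 7, size=n_case)).astype(float)

        a0 = np.clip(rng.normal(cfg.entry_age_mean, cfg.entry_age_sd, size=n_case),
                     40.0, 90.0)
        k = cfg.baseline_hazard_shape
        p_share = cfg.pca_death_share
        w_pca = p_share * np.exp(cfg.loghr_pca * g_case)
        w_oth = (1.0 - p_share) * np.exp(cfg.loghr_allcause * g_case)
        w = w_pca + w_oth
        lam = cfg.baseline_hazard_scale
        if lam is None:
            lam = calibrate_weibull_scale(a0, w, k, cfg.followup_years,
                                          cfg.death_frac)
        e = rng.exponential(size=n_case)
        death_age = lam * ((a0 / lam) ** k + e / w) ** (1.0 / k)
        censor_age = a0 + cfg.followup_years
        died = death_age <= censor_age
        a1 = np.minimum(death_age, censor_age)
        is_pca = rng.random(n_case) < (w_pca / w)

        v = np.where(died, "dead", "alive").astype(object)
        c = np.full(n_case, np.nan, dtype=object)
        c[died & is_pca] = "prostate cancer"
        c[died & ~is_pca] = "other"
        if cfg.unknown_vital_rate > 0:
            unk = rng.random(n_case) < cfg.unknown_vital_rate
            v[unk] = "unknown"
            c[unk] = np.nan
        if cfg.unknown_cause_rate > 0:
            dead_known = (v == "dead")
            unk_c = dead_known & (rng.random(n_case) < cfg.unknown_cause_rate)
            c[unk_c] = "unknown"

        entry_age[case] = np.round(a0, 3)
        exit_age[case] = np.round(np.maximum(a1, a0 + 1e-3), 3)
        vital[case] = v
        cause[case] = c

    df["tnm_stage"] = tnm
    df["seer_stage"] = seer
    df["gleason"] = gleason
    df["entry_age"] = entry_age
    df["vital_status"] = vital
    df["cause_of_death"] = cause
    df["exit_age"] = exit_age
    smoking = np.where(smoker == 1.0, "ever", "never").astype(object)
    if cfg.missing_smoking_rate > 0:
        smoking[rng.random(n) < cfg.missing_smoking_rate] = np.nan
    df["smoking"] = smoking
    pcs = np.round(rng.standard_normal((n, 8)), 4)
    for j in range(8):
        df[f"pc{j + 1}"] = pcs[:, j]
    return df


def simulate_cohort(config: SimulationConfig,
                    specs: Sequence[VariantSpec] = DEFAULT_VARIANTS) -> pd.DataFrame:
    """Generate the full consortium table (one row per individual).

    Column schema matches :data:`coffeemr.io.PHENOTYPE_COLUMNS` plus one
    ``dosage_<rsid>`` column per variant on the stored (counted-allele) scale.
    Each study draws from its own stream spawned from ``config.seed``.
    """
    if len(specs) != len(config.freq_increasing):
        raise ValueError("one allele frequency needed per variant")
    children = np.random.SeedSequence(config.seed).spawn(config.n_studies)
    frames = []
    for idx, (n, phi, ss) in enumerate(zip(config.study_sizes,
                                           config.case_fraction, children)):
        rng = np.random.default_rng(ss)
        frames.append(_simulate_study(idx, n, phi, config, rng, specs))
    return pd.concat(frames, ignore_index=True)


def write_cohort(cohort: pd.DataFrame, genotype_path, phenotype_path,
                 specs: Sequence[VariantSpec] = DEFAULT_VARIANTS,
                 imputation_r2: Optional[dict] = None):
    """Write the cohort as a dosage VCF plus a phenotype TSV."""
    dos_cols = {s.rsid: f"dosage_{s.rsid}" for s in specs}
    dosages = cohort[[*dos_cols.values()]].copy()
    dosages.columns = list(dos_cols)
    dosages.index = pd.Index(cohort["sample_id"].astype(str), name="sample_id")
    if imputation_r2 is None:
        imputation_r2 = {s.rsid: 1.0 for s in specs}
    vcf = cio.write_vcf(dosages, specs, imputation_r2, genotype_path)
    pheno = cio.write_phenotypes(cohort.drop(columns=list(dos_cols.values())),
                                 phenotype_path)
    return vcf, pheno


def read_cohort(genotype_path, phenotype_path,
                specs: Sequence[VariantSpec] = DEFAULT_VARIANTS):
    """Read back a (VCF, TSV) pair; returns (cohort DataFrame, {rsid: r2})."""
    dosages, r2 = cio.read_vcf(genotype_path, specs)
    pheno = cio.read_phenotypes(phenotype_path)
    merged = pheno.merge(dosages.rename(columns={s.rsid: f"dosage_{s.rsid}"
                                                 for s in specs}),
                         left_on="sample_id", right_index=True, how="left",
                         validate="one_to_one")
    return merged, r2
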