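# Methods

## Design

The package implements a reduced-form Mendelian randomization (MR) design:
a two-SNP caffeine-intake genetic risk score (GRS) instruments coffee
consumption, and the association of the GRS with prostate cancer outcomes is
estimated directly (the "reduced form"), with the first-stage GRS → cups/day
regression used for scaling and power rather than for a two-stage fit. The
causal per-cup odds ratio, when wanted, is the Wald ratio
β_reduced / γ_first-stage with a first-order delta-method standard error
√(SE_r²/γ² + β_r² SE_γ²/γ⁴); for one instrument this equals two-stage least
squares. MR validity rests on the usual assumptions: the instrument is
associated with the exposure, shares no unmeasured confounder with the
outcome, and affects the outcome only through the exposure (no pleiotropy).
The package tests none of these biological assumptions; it implements the
estimation machinery.

## Estimators

All core estimators are written from first principles against numpy and are
cross-checked in the test suite against independent oracles (likelihood grid
searches, hand-computed formulas) and established implementations
(statsmodels, lifelines), which are never used in the analysis path.

**Logistic regression** (`ClusterRobustLogit`) uses IRLS with step-halving;
convergence when the max absolute score < 1e-8 or the relative
log-likelihood change < 1e-10, at most 50 iterations. Diverging coefficients
(scaled magnitude > 40) raise a separation error naming the offending term.
Linearly dependent design columns are detected by greedy Gram–Schmidt in
column order and dropped, so a redundant study indicator disappears while
the exposure column is protected.

**Cluster-robust variance** is the sandwich A⁻¹BA⁻¹ with A the observed
information and B the sum over studies of outer products of within-study
score sums, scaled by G/(G−1). With one observation per cluster this reduces
to the HC0 sandwich times G/(G−1). Confidence intervals use the normal 1.96
quantile on the log scale and are exponentiated, so OR/HR interval bounds
are exactly exp of the log-scale bounds. With few clusters (G ≈ 10–25, as in
a consortium) this interval is known to undercover mildly — about 92 % at
G = 15 under the null in our 200-replicate simulations — which is the
behaviour of the standard estimator (z quantiles with a clustered sandwich),
not a defect of the implementation; a t_{G−1} quantile would repair most of
it but is not what consortium analyses of this design report.

**Linear first stage** (`RobustOLS`) is OLS with HC1 robust errors
(cups/day outcomes are right-skewed, so model-based OLS errors are not
trusted); a cluster option reuses the same sandwich.

**Cox regression** (`LeftTruncatedCoxPH`) maximises the Efron-tie partial
likelihood on the age timescale with delayed entry: the risk set at event
age t is {entry < t ≤ exit}, entry being age at diagnosis. Risk-set sums are
computed as differences of prefix sums over exit-sorted and entry-sorted
arrays, and the information matrix uses the identity
Σ_{j,l} S2_j/D_jl = Xᵀdiag(r·c)X (c the per-subject accumulated inverse
denominators), so no n×p×p intermediate is ever formed and fits at n ≈ 15,000
with ~25 covariates take well under a second. Newton–Raphson with
step-halving; score tolerance 1e-8. Records with exit = entry are shifted by
one day (1/365.25 y) with a warning. Robust variance uses Lin–Wei score
residuals (Breslow form — with the near-continuous ages of the simulations
the Efron/Breslow difference is negligible) aggregated by study. Efron was
chosen for ties because real consortium ages are recorded in years and tie
heavily; the implementation matches lifelines to ~7 decimals on both untied
and heavily tied data, with and without delayed entry.

**Proportional hazards diagnostic** is the Grambsch–Therneau score test:
scaled Schoenfeld residuals regressed on event age (identity transform by
default), per-covariate χ²(1) and a global χ²(p); the global test is skipped
when events ≤ covariates.

**Meta-analysis** is inverse-variance fixed-effect and DerSimonian–Laird
random effects: Q = Σw(β−β_FE)², τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw)),
I² = max(0, (Q−(k−1))/Q)·100. No Knapp–Hartung adjustment; normal CIs. The
first stage is pooled with random effects, the per-study heterogeneity check
of outcome models with fixed effects; pooled outcome estimates come from the
one-stage clustered models, with I² reported alongside.

**Power.** The minimal detectable per-allele OR uses
SE(β̂) ≈ 1/√(N φ(1−φ) σ²_G) with σ²_G = Σ2f(1−f) from the configured allele
frequencies and detectable |β| = (z_{1−α/2}+z_{power})·SE, reported per
allele, per cup and per 0.06 cups (one allele's worth of consumption). The
sensitivity table notes that the per-0.06-cup rescaling of an
extreme-category OR of 0.96 stays within about 10⁻³ of 1 for any plausible
contrast (2.5–6 cups); at contrasts ≥ 5 it rounds to 1.000 rather than
0.999, so "≈ 0.999" is the honest statement.

## Phenotype coding

* **Stage**: any of T3/T4/N1/M1 ⇒ nonlocalised (any-token-wins — the rule
  lists sets without precedence, and this matches staging practice); else
  T1/T2 with N ∈ {N0, NX, absent} and M ∈ {M0, MX, absent} ⇒ localised;
  otherwise missing. SEER local ⇒ localised, regional/distant ⇒
  nonlocalised. Contradictory double coding ⇒ missing with a warning. NX/MX
  and absent N/M are treated alike. Verified against brute-force enumeration
  of all T×N×M combinations.
* **Grade**: Gleason ≤ 6 low, ≥ 7 high; out-of-range ⇒ missing.
* **Cups/day**: category midpoints; the default map (never 0, <1 → 0.5,
  1 → 1, 2–3 → 2.5, ≥4 → 5, i.e. lower bound + 1 for the open top) is an
  explicit stand-in — real per-study questionnaire categories are not
  public — and is overridable per study.
* **Mortality**: unknown vital status excludes the record; death with
  unknown cause counts as an all-cause but not a prostate cancer event.
  Studies qualify for mortality analyses with follow-up ≥ 90 % complete
  (fraction of cases with known vital status) and, for the cancer-specific
  model, ≥ 5 prostate cancer deaths. All QC/eligibility thresholds are
  inclusive (a value exactly at the threshold passes).

## Synthetic consortium generator

`simcohort` draws, per study (one pseudo-random stream per study spawned
from the master seed, so adding studies never perturbs earlier ones):

* **Dosages**: hard genotypes Binomial(2, f) blended as
  d = 2f + r²(g−2f) + √(r²(1−r²))σ_g z, clipped to [0, 2]; corr(d, g)² ≈ r²
  and dosage variance shrinks with r², as with real imputed dosages.
  Default increasing-allele frequencies (0.63, 0.26) are package defaults —
  the source analysis never printed frequencies — chosen near European
  values for these loci, and configurable.
* **Coffee/tea**: cups = study mean + γ·GRS + confounder effect·smoking +
  mean-centred Gamma(2, sd/√2) noise. The gamma residual gives the
  right-skew of consumption data while its bounded left tail keeps the
  zero-truncation from ever binding, so the generative slope is exact. The
  combined coffee+tea slope is `gamma_coffee` (default 0.10 cups/allele),
  split 60/40 between beverages.
* **Case status**: logit = α + θ·GRS + 0.182·smoking, with α solved by
  root-finding so the expected case fraction equals the configured φ
  (φ = 1 gives a case-only study). Smoking is independent of genotype, so
  it confounds coffee–cancer but not GRS–cancer; its non-collapsibility
  effect on the per-allele OR is < 10⁻³ at these effect sizes.
* **Stage/grade**: Bernoulli with per-allele log-odds and intercepts solved
  for the configured nonlocalised/high-grade fractions; emitted as TNM
  strings in odd-numbered studies and SEER labels in even-numbered ones so
  both coding paths are exercised end to end; Gleason 5–6 (low) or 7–9
  (high).
* **Mortality** is simulated **on the age timescale**: diagnosis age
  ~ Normal(65, 8) clipped to [40, 90]; death age from a Weibull (shape 1.2)
  conditioned on survival to diagnosis, with a prostate-cancer component
  carrying `loghr_pca` per allele and an other-cause component carrying
  `loghr_allcause` (setting both equal yields that all-cause HR; cause is
  assigned proportionally to the component hazards). Simulating time from
  diagnosis instead would break proportional hazards on the age scale and
  bias the delayed-entry Cox model. Administrative censoring at diagnosis
  + `followup_years` (default 9, giving ~7 years mean follow-up). The
  Weibull scale is calibrated by root-finding to a target pre-censoring
  death fraction. Unknown vital status (3 %) and unknown cause (5 % of
  deaths) are injected to exercise the exclusion/assignment rules.
* **PCs** are pure standard-normal noise — the generator makes no attempt at
  real population structure, linkage disequilibrium, or between-study allele
  frequency differences. Passing recovery tests therefore show the
  estimators are correct under the assumed data-generating model, not that
  real-data biases (selection, differential stage/grade definitions,
  informative censoring) are absent.

Dosages are rounded to 4 decimals, cups to 3, ages to 3 at generation so
that the VCF/TSV round trip is exact and reports are byte-reproducible.

## Recovery experiments and problem sizes

The acceptance experiments re-simulate the published sample compositions and
check that the pipeline recovers the generative effects (medians over 200
replicates): 4 studies / 4,722 men for the first stage (slope 0.10
cups/allele), 23 studies / 45,755 men for case status (OR 1.01), 19 studies
/ 19,758 cases for stage (OR 1.03), 15 studies / 15,555 cases with ~4,081
deaths for all-cause mortality (HR 1.00, with CI-coverage check), 12 studies
/ 14,010 cases with ~1,754 prostate cancer deaths for cancer-specific
mortality (HR 1.03). Study counts follow the published analyses; per-study
sizes are split evenly because they were never printed. For the
cancer-specific run the total death rate is assumed equal to the all-cause
sample's (26.2 %) and the cause-share parameter is solved so the expected
number of prostate cancer deaths matches, accounting for the HR-induced
uplift of the cancer component. The empirical power check runs 400
replicates of an unadjusted GRS logistic fit at the analytic minimal
detectable OR (the unadjusted Wald test is what the analytic formula
approximates), simulating hard genotypes so the instrument variance equals
the σ²_G in the formula — an imputed instrument has variance r²·σ²_G and
correspondingly less power, a distinction the power module makes explicit.

The null-calibration experiment also reports 95 % CI coverage of the
clustered Cox interval; at 15 studies it sits near 92 % (see the
cluster-robust variance note above), short of the nominal 95 %.

## Known limitations

* Cluster-robust CIs use normal quantiles; with ~15 studies they undercover
  by 1–2 points (see above).
* The HWE check runs on hard calls only when dosages are hard (r² = 1);
  for imputed dosages it is skipped with a warning rather than guessed.
  Chi-square was chosen over the exact test for determinism; the tests
  verify the exclusion decisions agree with an exact-test oracle.
* Score and Schoenfeld residuals use Breslow-form risk means; exact under no
  ties, an approximation under heavy ties.
* Only the two independent loci are simulated; no LD, no proxy SNPs, no
  strand-flip detection (A/T and C/G variants are rejected outright).
* Competing risks are handled as cause-specific censoring, not Fine–Gray.
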