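"""Generator properties: dosage blending, determinism, calibration, round trips."""

import numpy as np
import pandas as pd
import pytest

from coffeemr.assoc import fit_linear_robust, fit_logistic
from coffeemr.experiments import PC_COLS, add_grs
from coffeemr.simcohort import (SimulationConfig, read_cohort,
                                simulate_cohort, simulate_genotypes,
                                write_cohort)
from coffeemr.survival import fit_cox


class TestSimulateGenotypes:
    def test_r2_one_reproduces_hard_calls(self, rng):
        d = simulate_genotypes(100_000, 0.26, 1.0, rng)
        assert np.all(d == np.round(d))
        assert d.mean() == pytest.approx(0.52, abs=0.01)

    def test_blending_hits_target_r2(self, rng):
        n = 100_000
        master = np.random.default_rng(5)
        hard = master.binomial(2, 0.5, n).astype(float)
        # re-derive the blend with the same stream to recover the hard calls
        gen = np.random.default_rng(5)
        d = simulate_genotypes(n, 0.5, 0.5, gen)
        r2 = np.corrcoef(d, hard)[0, 1] ** 2
        assert r2 == pytest.approx(0.5, abs=0.05)

    def test_seed_determinism(self):
        a = simulate_genotypes(5, 0.26, 0.3, 42)
        b = simulate_genotypes(5, 0.26, 0.3, 42)
        assert np.array_equal(a, b)

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            simulate_genotypes(0, 0.5, 1.0, rng)
        with pytest.raises(ValueError):
            simulate_genotypes(10, 1.0, 1.0, rng)
        with pytest.raises(ValueError):
            simulate_genotypes(10, 0.5, 0.0, rng)


def test_fixed_seed_byte_identical_cohort():
    cfg = SimulationConfig(n_studies=3, total_n=900, seed=7, case_only_studies=())
    a = simulate_cohort(cfg).to_csv(index=False)
    b = simulate_cohort(cfg).to_csv(index=False)
    assert a == b


def test_adding_a_study_preserves_earlier_studies():
    small = SimulationConfig(n_studies=3, study_sizes=[300, 300, 300],
                             case_only_studies=(), seed=11)
    big = SimulationConfig(n_studies=4, study_sizes=[300, 300, 300, 300],
                           case_only_studies=(), seed=11)
    a = simulate_cohort(small)
    b = simulate_cohort(big)
    pd.testing.assert_frame_equal(a, b[b["study"].isin(a["study"])].reset_index(drop=True))


def test_realized_case_fraction_close_to_configured():
    cfg = SimulationConfig(n_studies=2, total_n=20_000, case_fraction=0.35,
                           case_only_studies=(), seed=13)
    c = simulate_cohort(cfg)
    assert c["is_case"].mean() == pytest.approx(0.35, abs=0.01)


def test_first_stage_slope_unbiased_at_large_n():
    cfg = SimulationConfig(n_studies=1, total_n=100_000, case_only_studies=(),
                           n_coffee_studies=1, gamma_coffee=0.10, seed=17)
    c = add_grs(simulate_cohort(cfg))
    c["cups"] = c["coffee_cups"] + c["tea_cups"]
    fit = fit_linear_robust(c, "cups", "grs", PC_COLS, study_col=None)
    assert fit.estimate == pytest.approx(0.10, abs=0.012)  # ~2 MC SEs


def test_unattainable_fraction_reported():
    with pytest.raises(ValueError, match="case fraction"):
        SimulationConfig(n_studies=1, total_n=100, case_fraction=0.0,
                         case_only_studies=())


def test_stage_strings_alternate_tnm_and_seer():
    cfg = SimulationConfig(n_studies=2, total_n=800, case_fraction=1.0,
                           case_only_studies=(), seed=23)
    c = simulate_cohort(cfg)
    s1 = c[c["study"] == "S01"]
    s2 = c[c["study"] == "S02"]
    assert s1["tnm_stage"].notna().all() and s1["seer_stage"].isna().all()
    assert s2["seer_stage"].notna().all() and s2["tnm_stage"].isna().all()


def test_write_read_round_trip_including_missing(tmp_path):
    cfg = SimulationConfig(n_studies=2, total_n=80, case_only_studies=(), seed=29)
    c = simulate_cohort(cfg)
    c.loc[c.index[3], "gleason"] = np.nan
    r2 = {"rs4410790": 0.9, "rs2472297": 0.9}
    write_cohort(c, tmp_path / "g.vcf", tmp_path / "p.tsv", imputation_r2=r2)
    back, r2_back = read_cohort(tmp_path / "g.vcf", tmp_path / "p.tsv")
    for col in ("dosage_rs4410790", "dosage_rs2472297"):
        np.testing.assert_array_equal(back[col].to_numpy(), c[col].to_numpy())
    assert np.isnan(back["gleason"].iloc[3])
    assert back["vital_status"].equals(c["vital_status"])
    assert r2_back["rs4410790"] == pytest.approx(0.9, abs=1e-4)


def test_vcf_structure(tmp_path):
    cfg = SimulationConfig(n_studies=1, total_n=5, case_only_studies=(), seed=31)
    c = simulate_cohort(cfg)
    vcf, _ = write_cohort(c, tmp_path / "g.vcf", tmp_path / "p.tsv")
    lines = [l for l in vcf.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == 2                       # two variant records
    assert all(len(l.split("\t")) == 9 + 5 for l in lines)  # five samples


def test_null_generative_model_type_i_error_calibrated():
    """With every effect zero, each downstream estimator rejects at ~5%.

    200 small replicates; the acceptance band is the exact binomial 99.7%
    envelope around 0.05 (±3 binomial SEs ≈ ±0.046).
    """
    n_reps = 200
    null = dict(n_studies=25, total_n=3000, case_only_studies=(),
                n_coffee_studies=25, gamma_coffee=0.0, theta_reduced=0.0,
                loghr_pca=0.0, loghr_allcause=0.0, confounder_logor=0.0,
                unknown_vital_rate=0.0, unknown_cause_rate=0.0)
    seeds = np.random.default_rng(99).integers(0, 2**31 - 1, size=n_reps)
    rej = {"logistic": 0, "linear": 0, "cox": 0}
    cover = 0
    for s in seeds:
        cfg = SimulationConfig(**null, seed=int(s))
        c = add_grs(simulate_cohort(cfg))
        c["cups"] = c["coffee_cups"] + c["tea_cups"]
        lin = fit_linear_robust(c, "cups", "grs", PC_COLS, study_col=None)
        logi = fit_logistic(c, "is_case", "grs", PC_COLS, "study")
        cases = c[c["is_case"] == 1].copy()
        cases["event"] = (cases["vital_status"] == "dead").astype(int)
        cox = fit_cox(cases, "grs", "event", pcs=(), study_col="study")
        rej["linear"] += lin.p < 0.05
        rej["logistic"] += logi.p < 0.05
        rej["cox"] += cox.p < 0.05
        lo, hi = logi.ci
        cover += lo <= 1.0 <= hi
    for name, k in rej.items():
        assert 0.004 <= k / n_reps <= 0.096, (name, k / n_reps)
    assert 0.904 <= cover / n_reps <= 0.996
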