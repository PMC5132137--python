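"""Orientation, risk score, Hardy–Weinberg and variant QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from coffeemr.genetics import (DEFAULT_VARIANTS, VariantSpec, compute_grs,
                               hwe_test, orient_dosage, qc_variants)
from coffeemr.simcohort import simulate_genotypes

SPEC_SAME = VariantSpec("rs2472297", "T", "T", "C", "CYP1A1/2")
SPEC_FLIP = VariantSpec("rs4410790", "T", "C", "C", "AHR")


def test_orientation_identity_and_reflection():
    assert orient_dosage(0.5, SPEC_SAME) == 0.5
    assert orient_dosage(0.5, SPEC_FLIP) == 1.5


def test_orientation_is_involution(rng):
    d = rng.uniform(0, 2, 100)
    assert orient_dosage(orient_dosage(d, SPEC_FLIP), SPEC_FLIP) == pytest.approx(d)


def test_orientation_preserves_variance(rng):
    d = rng.uniform(0, 2, 500)
    assert np.var(orient_dosage(d, SPEC_FLIP)) == pytest.approx(np.var(d))


def test_orientation_rejects_out_of_range():
    with pytest.raises(ValueError, match="outside"):
        orient_dosage(2.4, SPEC_SAME)


def test_strand_ambiguous_variant_rejected():
    with pytest.raises(ValueError, match="ambiguous"):
        VariantSpec("rsX", "A", "A", "T", "L")


@pytest.mark.parametrize("d1, d2, expected",
                         [(2.0, 2.0, 4.0), (0.0, 0.0, 0.0), (1.2, 0.4, 1.6)])
def test_grs_additivity(d1, d2, expected):
    assert compute_grs([d1], [d2])[0] == pytest.approx(expected)


def test_grs_order_invariant_and_missing_propagates(rng):
    a, b = rng.uniform(0, 2, 50), rng.uniform(0, 2, 50)
    assert compute_grs(a, b) == pytest.approx(compute_grs(b, a))
    a[3] = np.nan
    assert np.isnan(compute_grs(a, b)[3])
    assert not np.isnan(compute_grs(a, b)[4])


def test_population_grs_mean_converges(rng):
    n = 200_000
    g1 = simulate_genotypes(n, 0.63, 1.0, rng)
    g2 = simulate_genotypes(n, 0.26, 1.0, rng)
    assert compute_grs(g1, g2).mean() == pytest.approx(2 * (0.63 + 0.26),
                                                       abs=0.01)
    # imputed dosages: clipping to [0, 2] may shift the mean only slightly
    d1 = simulate_genotypes(n, 0.63, 0.9, rng)
    d2 = simulate_genotypes(n, 0.26, 0.9, rng)
    assert compute_grs(d1, d2).mean() == pytest.approx(2 * (0.63 + 0.26),
                                                       abs=0.03)


# --- Hardy–Weinberg ---------------------------------------------------------

def _hwe_exact_p(n_aa, n_ab, n_bb):
    """Exact HWE test (conditional on allele counts), written independently."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def logprob(nab):
        naa = (n_a - nab) // 2
        nbb = n - naa - nab
        return (gammaln(n + 1) - gammaln(naa + 1) - gammaln(nab + 1)
                - gammaln(nbb + 1) + nab * np.log(2)
                + gammaln(n_a + 1) + gammaln(2 * n - n_a + 1) - gammaln(2 * n + 1))

    hets = range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    probs = {h: np.exp(logprob(h)) for h in hets}
    total = sum(probs.values())
    p_obs = probs[n_ab]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs + 1e-12) / total)


def test_hwe_exact_proportions_give_p_one():
    assert hwe_test(25, 50, 25) == pytest.approx(1.0)


def test_hwe_complete_het_deficit_extreme():
    p_chi = hwe_test(50, 0, 50)
    p_exact = _hwe_exact_p(50, 0, 50)
    assert p_chi < 1e-7
    assert p_exact < 1e-7


@pytest.mark.parametrize("counts", [(30, 40, 30), (80, 15, 5), (60, 20, 20),
                                    (45, 50, 5), (90, 8, 2)])
def test_hwe_chi_square_tracks_exact_oracle(counts):
    """Chi-square and the exact test agree on the 1e-7 exclusion decision and
    are of comparable magnitude away from the deep tail."""
    p_chi = hwe_test(*counts)
    p_exact = _hwe_exact_p(*counts)
    assert (p_chi < 1e-7) == (p_exact < 1e-7)
    if p_exact > 1e-4:
        assert np.log10(p_chi) == pytest.approx(np.log10(p_exact), abs=1.0)


def test_hwe_monomorphic_warns_p_one():
    with pytest.warns(UserWarning, match="monomorphic"):
        assert hwe_test(0, 0, 100) == 1.0


def test_hwe_input_validation():
    with pytest.raises(ValueError):
        hwe_test(-1, 2, 3)
    with pytest.raises(ValueError):
        hwe_test(0, 0, 0)


# --- variant QC -------------------------------------------------------------

def _qc_frame(rng, n=400, call_rate=1.0):
    import pandas as pd
    d = {s.rsid: simulate_genotypes(n, f, 1.0, rng)
         for s, f in zip(DEFAULT_VARIANTS, (0.37, 0.26))}
    df = pd.DataFrame(d)
    n_miss = int(round((1 - call_rate) * n))
    if n_miss:
        df.iloc[:n_miss, 0] = np.nan
    return df


def test_qc_call_rate_failure(rng):
    df = _qc_frame(rng, n=400, call_rate=0.94)
    is_case = np.zeros(400, dtype=bool)
    reps = qc_variants(df, is_case, DEFAULT_VARIANTS,
                       {s.rsid: 1.0 for s in DEFAULT_VARIANTS})
    rep = {r.rsid: r for r in reps}["rs4410790"]
    assert not rep.passed and "call_rate" in rep.failure_reasons


def test_qc_imputation_r2_failure(rng):
    df = _qc_frame(rng)
    reps = qc_variants(df, np.zeros(len(df), dtype=bool), DEFAULT_VARIANTS,
                       {"rs4410790": 0.29, "rs2472297": 0.9})
    rep = {r.rsid: r for r in reps}["rs4410790"]
    assert not rep.passed and rep.failure_reasons == ("imputation_r2",)


def test_qc_thresholds_inclusive(rng):
    df = _qc_frame(rng, n=400, call_rate=0.95)
    reps = qc_variants(df, np.zeros(400, dtype=bool), DEFAULT_VARIANTS,
                       {s.rsid: 0.3 for s in DEFAULT_VARIANTS})
    assert all(r.passed for r in reps)


def test_qc_no_controls_warns(rng):
    df = _qc_frame(rng)
    with pytest.warns(UserWarning, match="no controls"):
        reps = qc_variants(df, np.ones(len(df), dtype=bool), DEFAULT_VARIANTS,
                           {s.rsid: 1.0 for s in DEFAULT_VARIANTS})
    assert all(r.hwe_p is None for r in reps)


def test_qc_hwe_failure_on_hard_calls(rng):
    import pandas as pd
    bad = np.r_[np.zeros(100), np.full(100, 2.0)]  # het deficit
    good = simulate_genotypes(200, 0.26, 1.0, rng)
    df = pd.DataFrame({"rs4410790": bad, "rs2472297": good})
    reps = qc_variants(df, np.zeros(200, dtype=bool), DEFAULT_VARIANTS,
                       {s.rsid: 1.0 for s in DEFAULT_VARIANTS})
    rep = {r.rsid: r for r in reps}["rs4410790"]
    assert "hwe" in rep.failure_reasons


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.floats(0.01, 2.0), st.floats(0.0, 2.0))
def test_orient_dosage_bounds_preserved(scale, shift):
    d = np.clip(np.array([0.0, 0.5, 1.0, 1.5, 2.0]) * scale + shift, 0, 2)
    o = orient_dosage(d, SPEC_FLIP)
    assert np.all((o >= 0) & (o <= 2))
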