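"""Blot calibration, stoichiometry ratios and turnover-rate arithmetic."""

import numpy as np
import pytest

from psiirepair import NoiseModel, make_preset
from psiirepair.proteins import (accumulation_rate, calibrate_blots,
                                 fit_standard_curve, hexamer_content,
                                 protein_rates, protein_rates_summary,
                                 qc_flag_extracts, quantify,
                                 removal_rate, removal_rate_constant,
                                 stoichiometry, synthesis_rate)
from psiirepair.synth import generate_blots


# ---------------------------------------------------------------- calibration


def test_exact_line_recovered():
    fmol = np.array([10.0, 25.0, 50.0, 100.0, 200.0])
    curve = fit_standard_curve(fmol, 2.0 * fmol)
    assert curve.slope == pytest.approx(2.0)
    assert curve.intercept == pytest.approx(0.0, abs=1e-9)
    assert curve.r_squared == pytest.approx(1.0)


def test_standard_curve_validation():
    with pytest.raises(ValueError):
        fit_standard_curve([10.0, 100.0], [1.0, 2.0])  # under-determined
    with pytest.raises(ValueError, match="order of magnitude"):
        fit_standard_curve([10.0, 20.0, 40.0], [1.0, 2.0, 4.0])
    with pytest.raises(ValueError, match="non-responsive"):
        fit_standard_curve([10.0, 50.0, 200.0], [5.0, 3.0, 1.0])


def test_quantify_inverts_calibration():
    fmol = np.array([10.0, 25.0, 50.0, 100.0, 200.0])
    curve = fit_standard_curve(fmol, 3.0 * fmol + 12.0)
    signal_at_50 = 3.0 * 50.0 + 12.0
    res = quantify(signal_at_50, curve, load_ug=2.0)
    assert res.content == pytest.approx(25.0, rel=1e-9)
    assert not res.extrapolated
    assert quantify(curve.intercept, curve, 1.0).content == pytest.approx(0.0, abs=1e-9)
    assert quantify(3.0 * 500.0 + 12.0, curve, 1.0).extrapolated


def test_slope_mean_unbiased_with_lognormal_standard_noise():
    """200-seed Monte Carlo; mean slope within 2 MC SE of truth (mean-one
    multiplicative noise keeps OLS on standards unbiased)."""
    fmol = np.array([10.0, 25.0, 50.0, 100.0, 200.0])
    rng = np.random.default_rng(5)
    s = np.sqrt(np.log1p(0.05 ** 2))
    slopes = []
    for _ in range(200):
        noise = np.exp(rng.normal(-s * s / 2, s, fmol.size))
        slopes.append(fit_standard_curve(fmol, 2.0 * fmol * noise).slope)
    v = np.asarray(slopes)
    se = v.std(ddof=1) / np.sqrt(v.size)
    assert abs(v.mean() - 2.0) < 2 * se


# ---------------------------------------------------------------- ratios


def test_hexamer_content_is_monomer_over_six():
    assert hexamer_content(6.0) == 1.0
    assert hexamer_content(0.0) == 0.0
    with pytest.raises(ValueError):
        hexamer_content(-1.0)


@pytest.mark.parametrize("ratio, expected", [
    (0.030, 33), (0.092, 11), (0.097, 10), (0.293, 3), (0.15, 7),
])
def test_psii_per_hexamer_matches_reported_integer_counts(ratio, expected):
    res = stoichiometry(psba=1.0, psbd=0.5, ftsh_hexamer=ratio)
    assert res.psii_per_hexamer == expected


def test_stoichiometry_undefined_markers_not_nan():
    res = stoichiometry(psba=1.0, psbd=0.0, ftsh_hexamer=0.0)
    assert res.psba_psbd_ratio is None
    assert res.psii_per_hexamer is None
    assert stoichiometry(2.0, 2.0, 0.1).psba_psbd_ratio == pytest.approx(1.0)


def test_exact_inverse_ratio_round_trips_for_integers():
    for n in (3, 7, 10, 11, 33):
        res = stoichiometry(psba=1.0, psbd=0.5, ftsh_hexamer=1.0 / n)
        assert res.psii_per_hexamer == n


def test_med4_hl_preset_reproduces_printed_hexamer_ratio():
    p = make_preset("MED4_260")
    assert hexamer_content(p.ftsh_monomer0) / p.psba0 == pytest.approx(0.293)


# ---------------------------------------------------------------- rates


def test_removal_rate_constant_identities():
    assert removal_rate_constant(100.0, 100.0, 2640.0) == 0.0
    k = removal_rate_constant(100.0, 100.0 * np.exp(-1.0), 2640.0)
    assert k == pytest.approx(1.0 / 2640.0, rel=1e-12)
    # content rose under lincomycin: negative constant (accumulation)
    assert removal_rate_constant(80.0, 120.0, 2640.0) < 0
    with pytest.raises(ValueError):
        removal_rate_constant(0.0, 50.0, 2640.0)


def test_removal_constant_inverts_forward_decay():
    k_true, c0, T = 1.7e-4, 100.0, 2640.0
    c_t = c0 * np.exp(-k_true * T)
    assert removal_rate_constant(c0, c_t, T) == pytest.approx(k_true, rel=1e-12)


def test_removal_rate_linearity_and_sign():
    assert removal_rate(0.0, 120.0) == 0.0
    assert removal_rate(2e-4, 120.0) == pytest.approx(2 * removal_rate(2e-4, 60.0))
    assert removal_rate(-2e-4, 85.0) < 0


def test_synthesis_and_accumulation_worked_values():
    assert synthesis_rate(60.0, 33.6, 2640.0) == pytest.approx(0.01, rel=1e-12)
    assert synthesis_rate(50.0, 50.0, 2640.0) == 0.0
    assert accumulation_rate(50.0, 50.0, 2640.0) == 0.0
    assert accumulation_rate(110.3, 85.0, 2640.0) == pytest.approx(
        (110.3 - 85.0) / 2640.0)


def test_qc_boundary_inclusive():
    assert qc_flag_extracts(psba=100.0, psii_active=50.0) == "keep"
    assert qc_flag_extracts(psba=100.0, psii_active=300.0) == "flag"
    assert qc_flag_extracts(psba=100.0, psii_active=100.0) == "keep"


# ---------------------------------------------------------------- round trip


@pytest.mark.parametrize("name", ["MED4_30", "MIT9313_30"])
def test_zero_noise_blots_reproduce_preset_rates_exactly(name):
    """Full blot pipeline on noise-free lanes returns the generating rates
    (including the negative MIT 9313 low-light entries) to 1e-6 relative."""
    p = make_preset(name)
    rng = np.random.default_rng(3)
    blots = generate_blots(p, NoiseModel.zero(), 3, rng)
    rates = protein_rates(calibrate_blots(blots))
    summary = protein_rates_summary(rates)
    for target, k_true, rem_true, syn_true in (
            ("PsbA", p.k_psba, p.psba_removal_rate, p.psba_synthesis_rate),
            ("PsbD", p.k_psbd, p.psbd_removal_rate, p.psbd_synthesis_rate)):
        row = summary[summary["target"] == target].iloc[0]
        assert row["k_removal_mean"] == pytest.approx(k_true, rel=1e-6)
        assert row["removal_rate_mean"] == pytest.approx(rem_true, rel=1e-6)
        assert row["synthesis_rate_mean"] == pytest.approx(syn_true, rel=1e-6)
        assert row["removal_rate_sem"] == pytest.approx(0.0, abs=1e-12)
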