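"""FRR induction/relaxation simulation and fitting; quenching parameters."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from psiirepair.frr import (FRRFit, FRRProtocol, fit_induction,
                            fit_relaxation, fraction_open, quantum_yield,
                            simulate_induction, simulate_relaxation)


def _truth(f0=0.2, fm=0.6, sigma=0.05, p=0.3):
    return FRRFit(f0=f0, fm=fm, sigma_psii=sigma, connectivity_p=p,
                  residual_ss=0.0, converged=True)


def test_protocol_train_span_is_128_us():
    proto = FRRProtocol()
    assert proto.n_flashlets == 40
    assert proto.train_span_us == pytest.approx(128.0)


def test_zero_cross_section_gives_flat_trace_at_f0():
    trace = simulate_induction(FRRProtocol(), _truth(sigma=0.0))
    np.testing.assert_allclose(trace.fluorescence, 0.2)


def test_saturating_dose_reaches_fm_without_connectivity():
    trace = simulate_induction(FRRProtocol(flashlet_dose=1.0),
                               _truth(sigma=50.0, p=0.0))
    assert trace.fluorescence[0] == pytest.approx(0.2)
    assert trace.fluorescence[-1] == pytest.approx(0.6, rel=1e-9)


@given(sigma=st.floats(0.005, 0.5), p=st.floats(0.0, 0.9))
def test_induction_yields_monotone_nondecreasing(sigma, p):
    trace = simulate_induction(FRRProtocol(), _truth(sigma=sigma, p=p))
    assert np.all(np.diff(trace.fluorescence) >= -1e-12)


def test_fit_recovers_simulated_parameters_exactly():
    truth = _truth(f0=0.2, fm=0.6, sigma=0.05, p=0.3)
    fit = fit_induction(simulate_induction(FRRProtocol(), truth))
    assert fit.converged
    assert fit.f0 == pytest.approx(0.2, rel=1e-6)
    assert fit.fm == pytest.approx(0.6, rel=1e-6)
    assert fit.sigma_psii == pytest.approx(0.05, rel=1e-6)
    assert fit.connectivity_p == pytest.approx(0.3, rel=1e-5)


def test_flat_trace_is_flagged_unconverged_with_zero_sigma():
    proto = FRRProtocol()
    trace = simulate_induction(proto, _truth(sigma=0.0))
    fit = fit_induction(trace)
    assert not fit.converged
    assert fit.sigma_psii == 0.0
    assert "flat_trace" in fit.flags


def test_sigma_estimate_unbiased_under_one_percent_noise():
    """200-seed Monte Carlo at 1% additive noise; mean sigma within
    max(2 MC SE, 2% relative) of truth."""
    proto = FRRProtocol()
    truth = _truth(sigma=0.05)
    base = simulate_induction(proto, truth)
    rng = np.random.default_rng(77)
    estimates = []
    for _ in range(200):
        noisy = simulate_induction(proto, truth)
        noisy.fluorescence = base.fluorescence + rng.normal(
            0.0, 0.01 * truth.fm, base.fluorescence.size)
        estimates.append(fit_induction(noisy).sigma_psii)
    v = np.asarray(estimates)
    se = v.std(ddof=1) / np.sqrt(v.size)
    assert abs(v.mean() - 0.05) < max(2 * se, 0.02 * 0.05)


# ---------------------------------------------------------------- relaxation


def test_relaxation_recovers_biexponential_lifetimes():
    t = np.linspace(0.0, 25.0, 60)
    y = simulate_relaxation(0.2, (0.25, 0.15), (0.5, 5.0), t)
    fit = fit_relaxation(t, y)
    assert fit.tau1_ms == pytest.approx(0.5, rel=1e-6)
    assert fit.tau2_ms == pytest.approx(5.0, rel=1e-6)
    assert fit.amplitudes[0] == pytest.approx(0.25, rel=1e-5)
    assert fit.tau1_ms <= fit.tau2_ms


def test_single_exponential_data_prefer_reduced_model():
    t = np.linspace(0.0, 25.0, 60)
    y = 0.2 + 0.4 * np.exp(-t / 2.0)
    fit = fit_relaxation(t, y)
    assert min(fit.amplitudes) / sum(fit.amplitudes) < 1e-3 \
        or abs(fit.tau1_ms - fit.tau2_ms) / fit.tau2_ms < 1e-3
    total = fit.amplitudes[0] * np.exp(-t / fit.tau1_ms) \
        + fit.amplitudes[1] * np.exp(-t / fit.tau2_ms) + fit.f0
    np.testing.assert_allclose(total, y, atol=1e-8)


def test_equal_lifetimes_yield_sorted_output_matching_data():
    t = np.linspace(0.0, 25.0, 60)
    y = simulate_relaxation(0.2, (0.2, 0.2), (3.0, 3.0), t)
    fit = fit_relaxation(t, y)
    assert fit.tau1_ms <= fit.tau2_ms
    pred = simulate_relaxation(fit.f0, fit.amplitudes,
                               (fit.tau1_ms, fit.tau2_ms), t)
    np.testing.assert_allclose(pred, y, atol=1e-8)


def test_too_few_relaxation_points_rejected():
    with pytest.raises(ValueError):
        fit_relaxation(np.arange(5.0), np.ones(5))


# ---------------------------------------------------------------- quenching


@pytest.mark.parametrize("f0p, fmp, expected", [
    (0.0, 1.0, 1.0),
    (0.5, 0.5, 0.0),
    (0.4, 0.65, 0.25 / 0.65),
])
def test_quantum_yield_printed_formula(f0p, fmp, expected):
    assert quantum_yield(f0p, fmp) == pytest.approx(expected, rel=1e-12)


@given(f0p=st.floats(0.01, 0.5), fmp=st.floats(0.51, 2.0),
       c=st.floats(0.1, 100.0))
def test_quantum_yield_scale_invariant(f0p, fmp, c):
    assert quantum_yield(c * f0p, c * fmp) == pytest.approx(
        quantum_yield(f0p, fmp), rel=1e-9)


def test_quantum_yield_error_and_warning_paths():
    with pytest.raises(ValueError):
        quantum_yield(0.2, 0.0)
    with pytest.warns(UserWarning):
        assert quantum_yield(0.7, 0.6) < 0


def test_fraction_open_boundaries_and_worked_example():
    assert fraction_open(0.4, 0.4, 0.65).value == pytest.approx(1.0)
    assert fraction_open(0.65, 0.4, 0.65).value == pytest.approx(0.0)
    res = fraction_open(0.5, 0.4, 0.65)
    assert res.value == pytest.approx(0.6, rel=1e-12)
    assert not res.clamped


def test_fraction_open_clamps_out_of_range_with_flag():
    res = fraction_open(0.3, 0.4, 0.65)  # F' below F0': qp > 1
    assert res.value == 1.0
    assert res.clamped
    with pytest.raises(ValueError):
        fraction_open(0.5, 0.7, 0.6)
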