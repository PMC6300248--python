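"""Photoinactivation/repair model: closed form, fits, pairing bookkeeping."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from psiirepair import (FluorDecaySeries, NoiseModel, fit_photoinactivation,
                        fit_repair, make_preset, pair_and_fit, predict_active)
from psiirepair.protocol import decay_times
from psiirepair.synth import generate_decay_pairs

from conftest import PRESET_NAMES


# ---------------------------------------------------------------- predict


def test_predict_active_initial_condition_and_repair_free_limit():
    t = decay_times()
    assert predict_active(0.6, 1e-4, 5e-4, 0.0) == pytest.approx(0.6)
    np.testing.assert_allclose(predict_active(0.6, 1e-4, 0.0, t),
                               0.6 * np.exp(-1e-4 * t), rtol=0, atol=0)
    # zero total rate: stationary pool
    assert predict_active(0.37, 0.0, 0.0, 1e6) == 0.37


def test_predict_active_plateau_fraction():
    k_pi, k_rec = 1.2e-4, 1.1e-3
    plateau = predict_active(1.0, k_pi, k_rec, 1e9)
    assert plateau == pytest.approx(k_rec / (k_pi + k_rec), rel=1e-12)
    assert plateau == pytest.approx(0.9016, abs=5e-5)


def _ode_solution(a0, k_pi, k_rec, t):
    sol = solve_ivp(lambda _, a: -k_pi * a + k_rec * (a0 - a),
                    (0.0, float(t[-1])), [a0], t_eval=t,
                    rtol=1e-11, atol=1e-14, method="LSODA")
    return sol.y[0]


@pytest.mark.parametrize("name", PRESET_NAMES)
def test_closed_form_agrees_with_ode_integration(name):
    p = make_preset(name)
    t = np.linspace(0.0, 2640.0, 25)
    np.testing.assert_allclose(predict_active(0.6, p.k_pi, p.k_rec, t),
                               _ode_solution(0.6, p.k_pi, p.k_rec, t),
                               rtol=0, atol=1e-8)


@given(k_rec=st.floats(0.0, 5e-3), k_pi=st.floats(1e-6, 5e-3))
def test_plateau_monotonic_in_both_rates(k_pi, k_rec):
    plateau = k_rec / (k_pi + k_rec)
    assert plateau <= (k_rec + 1e-4) / (k_pi + k_rec + 1e-4)  # inc. in k_rec
    assert plateau >= k_rec / (k_pi + 1e-4 + k_rec)           # dec. in k_pi


# ---------------------------------------------------------------- fits


@pytest.mark.parametrize("name", PRESET_NAMES)
def test_noiseless_recovery_all_presets(name):
    p = make_preset(name)
    t = decay_times()
    plus = p.fvfm0 * np.exp(-p.k_pi * t)
    minus = predict_active(p.fvfm0, p.k_pi, p.k_rec, t)
    f_pi = fit_photoinactivation((t, plus))
    assert f_pi.k_pi == pytest.approx(p.k_pi, rel=1e-6)
    f_rec = fit_repair((t, minus), k_pi_fixed=f_pi.k_pi)
    assert f_rec.k_rec == pytest.approx(p.k_rec, rel=1e-6, abs=1e-12)


def test_constant_series_reports_zero_decay():
    t = decay_times()
    fit = fit_photoinactivation((t, np.full(t.size, 0.55)))
    assert fit.k_pi == 0.0
    assert "no_decay" in fit.flags


def test_nonfinite_values_rejected():
    t = decay_times()
    y = np.full(t.size, 0.5)
    y[3] = np.nan
    with pytest.raises(ValueError):
        fit_photoinactivation((t, y))


def test_series_identical_to_pair_gives_zero_repair():
    p = make_preset("MED4_30")
    t = decay_times()
    plus = p.fvfm0 * np.exp(-p.k_pi * t)
    fit = fit_repair((t, plus), k_pi_fixed=p.k_pi)
    assert fit.k_rec == pytest.approx(0.0, abs=1e-10)


def test_flat_series_with_positive_k_pi_flags_saturated_repair():
    t = decay_times()
    fit = fit_repair((t, np.full(t.size, 0.6)), k_pi_fixed=2e-4)
    assert "repair_saturated" in fit.flags
    assert fit.k_rec > 1.0


def test_negative_repair_estimates_are_reported_not_clipped():
    p = make_preset("MIT9313_30")
    t = decay_times()
    minus = predict_active(p.fvfm0, p.k_pi, p.k_rec, t)
    fit = fit_repair((t, minus), k_pi_fixed=p.k_pi)
    assert fit.k_rec < 0
    assert "negative_k_rec" in fit.flags


def test_lincomycin_tags_are_enforced():
    t = decay_times()
    series = FluorDecaySeries("r1", "MED4", 260.0, False, t,
                              np.linspace(0.6, 0.4, t.size))
    with pytest.raises(ValueError):
        fit_photoinactivation(series)
    series_plus = dataclasses.replace(series, lincomycin=True)
    with pytest.raises(ValueError):
        fit_repair(series_plus, k_pi_fixed=1e-4)


# ---------------------------------------------------------------- pairing


def test_pair_and_fit_zero_noise_has_zero_sem(zero_noise_dataset):
    res = pair_and_fit(zero_noise_dataset.decay)
    assert len(res.fits) == 3
    assert res.summary["k_pi_sem"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert res.summary["k_rec_sem"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_unpaired_series_go_to_rejects_not_dropped(zero_noise_dataset):
    decay = zero_noise_dataset.decay
    mask = (decay["replicate_id"] == "rep2") & decay["lincomycin"]
    res = pair_and_fit(decay[~mask])
    assert len(res.fits) == 2
    assert len(res.rejects) == 1
    assert "no +lincomycin" in res.rejects["reason"].iloc[0]


# ---------------------------------------------------------------- Monte Carlo


def test_k_pi_mean_unbiased_and_k_rec_small_bias_under_noise():
    """100-seed recovery at paper-scale fluorescence noise.

    k_PI (linear-in-log, strongly identified) must sit within 2 Monte-Carlo
    SEs of truth.  The two-stage k_REC estimator carries an O(sigma^2) Jensen
    bias, so it is held to max(2 MC SE, 5% of max(|k_REC|, k_PI)).
    """
    p = make_preset("MED4_260")
    noise = NoiseModel()
    k_pi_means, k_rec_means = [], []
    for seed in range(100):
        rng = np.random.default_rng(1000 + seed)
        res = pair_and_fit(generate_decay_pairs(p, noise, 5, rng))
        k_pi_means.append(res.fits["k_pi"].mean())
        k_rec_means.append(res.fits["k_rec"].mean())
    v = np.asarray(k_pi_means)
    se = v.std(ddof=1) / 10.0
    assert abs(v.mean() - p.k_pi) < 2 * se
    w = np.asarray(k_rec_means)
    se_rec = w.std(ddof=1) / 10.0
    tol = max(2 * se_rec, 0.05 * max(abs(p.k_rec), p.k_pi))
    assert abs(w.mean() - p.k_rec) < tol
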