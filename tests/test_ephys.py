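"""Whole-cell and field-potential metrics against planted closed forms."""

import numpy as np
import pytest

from astroquant import ephys, synthetic
from astroquant.ephys import (
    fepsp_metrics,
    fit_gompertz,
    gompertz,
    isolate_fifth,
    ltp_magnitude,
    measure_ik,
)
from astroquant.synthetic import gen_traces, ltp_true_window_mean


@pytest.mark.parametrize("tau", [0.5, 2.5, 3.0, 10.0])
def test_tau_exact_on_noiseless_exponential(tau):
    t = np.arange(0.0, 12.0, 2e-4)
    trace = 40.0 * np.exp(-np.clip(t - 0.5, 0, None) / tau) * (t >= 0.5)
    m = measure_ik(t, trace, 0.5, fit_span_s=4.0)
    assert m.tau_decay == pytest.approx(tau, rel=1e-6)
    assert m.ik_amp == pytest.approx(40.0 * np.exp(-0.2 / tau), rel=1e-6)


def test_tau_unaffected_by_fast_contaminant():
    """The 200-ms readout point skips the < 100 ms field/transporter transient."""
    ts = gen_traces({"tau_s": 3.0}, 0)
    m = measure_ik(ts.time, ts.traces["ik_1"], ts.stim_times["ik"])
    assert m.tau_decay == pytest.approx(3.0, rel=0.02)


def test_flat_trace_flagged_invalid():
    t = np.arange(0.0, 5.0, 1e-3)
    m = measure_ik(t, np.zeros_like(t), 0.5)
    assert not m.valid and np.isnan(m.tau_decay)


def test_growing_tail_flagged_invalid():
    t = np.arange(0.0, 5.0, 1e-3)
    m = measure_ik(t, np.exp(t), 0.5)
    assert not m.valid


def test_fifth_stimulus_subtraction_identities(rng):
    resp4 = rng.standard_normal(1000)
    assert np.abs(isolate_fifth(resp4, resp4)).max() == 0.0
    planted = 5.0 * np.exp(-np.arange(1000) / 300.0)
    assert np.allclose(isolate_fifth(resp4 + planted, resp4), planted, atol=1e-12)
    with pytest.raises(ValueError):
        isolate_fifth(np.zeros(10), np.zeros(11))


def test_planted_ik5_ratio_recovered():
    ts = gen_traces({"ik5_ratio": 0.72, "tau_s": 2.5}, 0)
    ik1 = measure_ik(ts.time, ts.traces["ik_1"], ts.stim_times["ik"])
    fifth = isolate_fifth(ts.traces["ik_5"], ts.traces["ik_4"])
    ik5 = measure_ik(ts.time, fifth, ts.stim_times["ik_train"][4], stimulus_count=5)
    assert ik5.ik_amp / ik1.ik_amp == pytest.approx(0.72, rel=0.02)
    assert ik5.tau_decay / ik1.tau_decay == pytest.approx(1.45, rel=0.02)


# --- fEPSP -----------------------------------------------------------------


def test_linear_ramp_slope_is_analytic():
    """A 1-ms linear ramp to -1 mV has a 20-80 % slope of exactly 1 mV/ms."""
    t = np.arange(0.0, 0.1, 2e-4)
    sweep = np.zeros_like(t)
    ramp = (t >= 0.025) & (t < 0.026)
    sweep[ramp] = -(t[ramp] - 0.025) / 0.001
    sweep[t >= 0.026] = -1.0
    m = fepsp_metrics(t, sweep, [0.02])
    assert m.slope_20_80 == pytest.approx(1.0, rel=1e-6)
    assert m.amplitude == pytest.approx(1.0, rel=1e-9)


def test_paired_pulse_ratio_scaling():
    same = gen_traces({"ppr": 1.0}, 0)
    m1 = fepsp_metrics(same.traces["fepsp_time"], same.traces["fepsp"], same.stim_times["fepsp"])
    assert m1.ppr == pytest.approx(1.0, abs=0.01)
    facil = gen_traces({"ppr": 1.4}, 0)
    m2 = fepsp_metrics(facil.traces["fepsp_time"], facil.traces["fepsp"], facil.stim_times["fepsp"])
    assert m2.ppr == pytest.approx(1.4, rel=0.01)


def test_metrics_invariant_to_dc_offset():
    ts = gen_traces({}, 0)
    a = fepsp_metrics(ts.traces["fepsp_time"], ts.traces["fepsp"], ts.stim_times["fepsp"])
    b = fepsp_metrics(ts.traces["fepsp_time"], ts.traces["fepsp"] - 3.7, ts.stim_times["fepsp"])
    assert b.amplitude == pytest.approx(a.amplitude, abs=1e-9)
    assert b.ppr == pytest.approx(a.ppr, abs=1e-9)
    assert b.slope_20_80 == pytest.approx(a.slope_20_80, abs=1e-9)


# --- Gompertz input-output -------------------------------------------------


def test_gompertz_noiseless_parameters_and_max_slope():
    x = np.linspace(-2.5, 3.5, 15)
    y = gompertz(x, 4.0, 1.0, 0.5)
    fit = fit_gompertz(x, y)
    assert fit.a == pytest.approx(4.0, abs=1e-6)
    assert fit.k == pytest.approx(1.0, abs=1e-6)
    assert fit.x_c == pytest.approx(0.5, abs=1e-6)
    assert fit.max_slope == pytest.approx(4.0 / np.e, abs=1e-6)


def test_max_slope_matches_numerical_differentiation():
    fit = fit_gompertz(*_io_points())
    h = 1e-5
    xg = np.linspace(fit.x_c - 0.01, fit.x_c + 0.01, 41)
    num = np.max(
        (gompertz(xg + h, fit.a, fit.k, fit.x_c) - gompertz(xg - h, fit.a, fit.k, fit.x_c))
        / (2 * h)
    )
    assert fit.max_slope == pytest.approx(num, abs=1e-6)


def _io_points():
    ts = gen_traces({"gompertz": (4.0, 1.0, 0.5)}, 0)
    return ts.traces["io_prv"], ts.traces["io_fepsp"]


def test_flat_io_flagged_degenerate():
    fit = fit_gompertz(np.linspace(0, 1, 8), np.zeros(8))
    assert not fit.valid


def test_noisy_io_recovers_asymptote():
    ts = gen_traces({"gompertz": (4.0, 1.0, 0.5), "io_noise_frac": 0.02}, 1)
    fit = fit_gompertz(ts.traces["io_prv"], ts.traces["io_fepsp"])
    assert fit.a == pytest.approx(4.0, rel=0.05)


# --- LTP -------------------------------------------------------------------


@pytest.mark.parametrize("ratio", [1.0, 1.29, 1.73])
def test_constant_potentiation_returns_planted_ratio(ratio):
    ts = gen_traces({"ltp_ratio": ratio}, 0)
    res = ltp_magnitude(ts.traces["ltp_time_min"], ts.traces["ltp_slope"])
    assert res.magnitude == pytest.approx(ratio, abs=5e-4)


def test_decaying_potentiation_windows_match_closed_form():
    """Early (5-15 min) exceeds late (47-60 min); both match the generator's
    closed-form window means within 1 %."""
    ts = gen_traces({"ltp_profile": "decay"}, 0)
    t, y = ts.traces["ltp_time_min"], ts.traces["ltp_slope"]
    res = ltp_magnitude(t, y)
    early = y[(t >= 5) & (t <= 15)].mean()
    assert early > res.magnitude
    assert res.magnitude == pytest.approx(ltp_true_window_mean(ts.truth, 47, 60), rel=0.01)
    assert early == pytest.approx(ltp_true_window_mean(ts.truth, 5, 15), rel=0.01)


def test_missing_windows_rejected():
    t = np.arange(-5.0, 30.0, 1 / 3)  # too little baseline, too short post
    with pytest.raises(ValueError):
        ltp_magnitude(t, np.ones_like(t))
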