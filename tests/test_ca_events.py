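"""Ca2+ movie processing: dark noise, registration, dF/F, events, power laws."""

import numpy as np
import pytest
from scipy.ndimage import fourier_shift, gaussian_filter

from astroquant import ca_events, synthetic
from astroquant.ca_events import (
    CaEvent,
    DffMovie,
    compute_dff,
    detect_events,
    filter_events,
    fit_power_law,
    frequency_density,
    register_movie,
    subtract_dark_noise,
)


# --- dark noise ------------------------------------------------------------


def test_constant_dark_offset_removed(rng):
    signal = rng.random((20, 8, 8)) * 50
    dark = np.full((30, 8, 8), 10.0)
    out = subtract_dark_noise(signal + 10.0, dark)
    assert np.allclose(out, signal, atol=1e-12)


def test_zero_dark_frames_are_identity(rng):
    movie = rng.random((10, 6, 6))
    assert np.allclose(subtract_dark_noise(movie, np.zeros((30, 6, 6))), movie)


def test_per_pixel_gradient_offset_removed_exactly(rng):
    grad = np.linspace(5, 25, 36).reshape(6, 6)
    signal = rng.random((15, 6, 6)) * 40
    dark = np.tile(grad, (30, 1, 1))
    out = subtract_dark_noise(signal + grad, dark)
    assert np.abs(out - signal).max() < 1e-12


def test_dark_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        subtract_dark_noise(np.zeros((5, 8, 8)), np.zeros((30, 4, 4)))


# --- registration ----------------------------------------------------------


def _smooth_field(rng, n=64):
    return gaussian_filter(rng.random((n, n)), 2) * 100


def test_integer_planted_shift_recovered(rng):
    base = _smooth_field(rng)
    movie = np.stack([base, base, np.roll(base, (2, -3), axis=(0, 1))])
    reg, shifts = register_movie(movie)
    assert shifts[2] == pytest.approx([-2.0, 3.0], abs=0.05)  # corrective shift
    assert np.abs(reg[2] - base)[4:-4, 4:-4].max() < 1e-6


def test_static_movie_needs_no_shift(rng):
    base = _smooth_field(rng)
    _, shifts = register_movie(np.stack([base] * 4))
    assert np.abs(shifts).max() == 0.0


def test_subpixel_shift_recovered_within_tenth_pixel(rng):
    base = _smooth_field(rng)
    moved = np.fft.ifft2(fourier_shift(np.fft.fft2(base), (0.5, 0.0))).real
    _, shifts = register_movie(np.stack([base, moved]), upsample_factor=10)
    assert shifts[1][0] == pytest.approx(-0.5, abs=0.1)
    assert shifts[1][1] == pytest.approx(0.0, abs=0.1)


# --- dF/F ------------------------------------------------------------------


def test_constant_pixel_has_zero_dff():
    d = compute_dff(np.full((200, 3, 3), 80.0))
    assert np.abs(d.dff).max() < 1e-9


def test_slow_drift_absorbed_into_baseline():
    t = np.arange(300)
    trace = 100.0 * (1 + 0.001 * t)
    d = compute_dff(np.tile(trace[:, None, None], (1, 4, 4)))
    assert np.abs(d.dff).max() < 1e-6


def test_baseline_survives_planted_boxcar_transient():
    """Transient exclusion keeps F0 within 2 % of truth inside the transient."""
    trace = np.full(300, 100.0)
    trace[100:140] += 80.0
    d = compute_dff(np.tile(trace[:, None, None], (1, 3, 3)))
    assert np.abs(d.F0[100:140] - 100.0).max() / 100.0 < 0.02
    assert d.dff[100:140, 0, 0].max() == pytest.approx(0.8, abs=0.02)


def test_short_movie_rejected():
    with pytest.raises(ValueError):
        compute_dff(np.zeros((50, 4, 4)))


# --- event detection -------------------------------------------------------


def _dff_movie(dff, dt=1.0, px=0.5):
    return DffMovie(dff=dff, F0=np.ones_like(dff), frame_interval=dt, pixel_area=px**2)


def test_three_disjoint_planted_events_detected_exactly():
    dff = np.zeros((60, 40, 40))
    spots = [((5, 10), (5, 8)), ((25, 30), (20, 26)), ((32, 8), (45, 50))]
    for (cy, cx), (t0, t1) in spots:
        dff[t0:t1, cy - 3 : cy + 4, cx - 3 : cx + 4] = 1.0
    events = detect_events(_dff_movie(dff))
    assert len(events) == 3
    for ev in events:
        assert ev.s_max == pytest.approx(49 * 0.25, abs=1e-9)


def test_zero_dff_yields_no_events():
    assert detect_events(_dff_movie(np.zeros((30, 16, 16)))) == []


def test_silent_gap_splits_cofocal_events():
    """Two activations of the same footprint separated by >= 2 silent frames
    stay two events (and merge when a gap tolerance bridges them)."""
    dff = np.zeros((40, 20, 20))
    dff[5:10, 8:12, 8:12] = 1.0
    dff[12:18, 8:12, 8:12] = 1.0
    assert len(detect_events(_dff_movie(dff))) == 2
    assert len(detect_events(_dff_movie(dff), gap_frames=2)) == 1


def test_event_geometry_invariants():
    """s_max bounds any single-frame footprint; integral <= s_max * duration."""
    mv = synthetic.gen_ca_movie({"n_events": 10, "frames": 200, "fov_um": 40.0}, 3)
    clean = subtract_dark_noise(mv.movie, mv.dark_frames)
    d = compute_dff(clean, mv.frame_interval, mv.pixel_size)
    events = detect_events(d)
    assert events
    for ev in events:
        frames = ev.voxels[:, 0]
        biggest = max(np.sum(frames == f) for f in np.unique(frames))
        assert ev.s_max >= biggest * d.pixel_area - 1e-9
        assert ev.integral <= ev.s_max * ev.duration + 1e-9


@pytest.mark.parametrize(
    "integral, s_max, duration, kept",
    [
        (3.9, 50.0, 5.0, False),
        (100.0, 9.9, 5.0, False),
        (100.0, 50.0, 1.9, False),
        (4.0, 10.0, 2.0, True),
        (4.1, 10.1, 2.1, True),
    ],
)
def test_exclusion_filters_use_strict_less_than(integral, s_max, duration, kept):
    ev = CaEvent(voxels=np.zeros((1, 3), int), s_max=s_max, integral=integral,
                 duration=duration, t_start=0.0)
    assert (len(filter_events([ev])) == 1) is kept


def test_frequency_density_arithmetic():
    events = [object()] * 60
    assert frequency_density(events, 0.02, 600.0) == pytest.approx(5.0)
    assert frequency_density([], 0.02, 600.0) == 0.0
    assert frequency_density(events, 0.02, 1200.0) == pytest.approx(2.5)
    with pytest.raises(ValueError):
        frequency_density(events, 0.0, 600.0)


# --- power-law fits --------------------------------------------------------


def test_exact_power_law_quantiles_recover_exponent():
    """Deterministic quantile samples of P(x) ~ x**-3 fit to alpha = 3.00."""
    n = 100_000
    u = (np.arange(n) + 0.5) / n
    x = 10.0 * (1 - u) ** (-1.0 / 2.0)  # alpha = 3
    fit = fit_power_law(x, 10.0)
    assert fit.alpha == pytest.approx(3.0, abs=0.01)


@pytest.mark.parametrize("alpha", [2.7, 3.5])
def test_sampled_exponent_recovered_within_two_stderr(alpha):
    x = synthetic.sample_power_law(10_000, alpha, 10.0, np.random.default_rng(0))
    fit = fit_power_law(x, 10.0)
    assert abs(fit.alpha - alpha) <= 2 * fit.fit_stderr


def test_power_law_fit_needs_enough_samples(rng):
    with pytest.raises(ValueError):
        fit_power_law(synthetic.sample_power_law(10, 2.7, 10.0, rng), 10.0)


def test_pipeline_recall_and_false_positives():
    """Planted events passing the filters are found; event-free movies stay empty."""
    found = planted = 0
    for seed in range(3):
        mv = synthetic.gen_ca_movie({"n_events": 12, "frames": 300, "fov_um": 50.0}, seed)
        clean = subtract_dark_noise(mv.movie, mv.dark_frames)
        d = compute_dff(clean, mv.frame_interval, mv.pixel_size)
        kept = filter_events(detect_events(d))
        for p in mv.planted_events:
            if (
                p["footprint_area_um2"] < 10.0
                or p["duration_s"] < 2.0
                or p["footprint_area_um2"] * p["duration_s"] < 4.0
            ):
                continue  # the discretized truth itself fails the filters
            planted += 1
            t1 = p["t0"] + p["duration_s"]
            for e in kept:
                if e.t_start <= t1 and e.t_start + e.duration >= p["t0"]:
                    ys, xs = e.voxels[:, 1], e.voxels[:, 2]
                    if p["footprint"][ys, xs].any():
                        found += 1
                        break
    assert found / planted >= 0.95
    empty = synthetic.gen_ca_movie({"n_events": 0, "frames": 300, "fov_um": 50.0}, 99)
    d0 = compute_dff(subtract_dark_noise(empty.movie, empty.dark_frames))
    assert filter_events(detect_events(d0)) == []
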