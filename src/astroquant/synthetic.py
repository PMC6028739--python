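"""Synthetic inputs with known ground truth for every pipeline stage.

The study's raw material — two-photon z-stacks of dye-filled astrocytes,
confocal Ca2+ time-lapse movies, dye-coupling intensity tables and slice
electrophysiology traces — is emulated here by pure functions of
``(params, seed)``.  Each generator returns the synthetic recording together
with the exact ground truth used to build it, so every downstream stage can
be tested as a recovery problem: plant a known leaflet volume fraction,
coupling length constant, power-law exponent or decay time, run the analysis,
and compare.

Default calibrations follow the study conditions: 0.5 um/pixel, one frame
per second, 10-minute movies, 30 dark-noise frames, event-size and duration
power laws above the analysis floors (10 um^2, 2 s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticAstrocyte",
    "SyntheticCaMovie",
    "SyntheticCouplingSet",
    "SyntheticTraceSet",
    "gen_pattern",
    "gen_astrocyte",
    "gen_ca_movie",
    "gen_coupling_set",
    "gen_traces",
    "sample_power_law",
    "gompertz",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class SyntheticAstrocyte:
    image_stack: np.ndarray  # (z, y, x), arbitrary fluorescence units
    soma_center: tuple[int, int, int]  # (z, y, x) voxels
    pixel_size: float  # um / pixel
    truth: dict


@dataclass
class SyntheticCaMovie:
    movie: np.ndarray  # (t, y, x)
    dark_frames: np.ndarray  # (t, y, x)
    frame_interval: float  # s
    pixel_size: float  # um / pixel
    planted_events: list[dict]
    alpha_true_area: float
    alpha_true_duration: float


@dataclass
class SyntheticCouplingSet:
    records: list[dict]  # {"distance_um", "normalized_intensity"}
    c_lambda_true: float  # um
    noise_sd: float


@dataclass
class SyntheticTraceSet:
    time: np.ndarray  # s
    traces: dict  # name -> array
    stim_times: dict  # name -> stimulus time(s), s
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers


def sample_power_law(
    n: int, alpha: float, x_min: float, rng: np.random.Generator, x_max: float | None = None
) -> np.ndarray:
    """Draw n samples from P(x) ~ x**-alpha for x >= x_min by inverse CDF.

    With an optional truncation at x_max (samples are redrawn from the
    truncated inverse CDF, which keeps the exponent exact on the kept range).
    """
    if alpha <= 1:
        raise ValueError("power-law exponent must exceed 1")
    u = rng.random(n)
    if x_max is None:
        return x_min * (1.0 - u) ** (-1.0 / (alpha - 1.0))
    # truncated inverse CDF on [x_min, x_max]
    a = 1.0 - alpha
    lo, hi = x_min**a, x_max**a
    return (lo + u * (hi - lo)) ** (1.0 / a)


def gompertz(x: np.ndarray, a: float, k: float, x_c: float) -> np.ndarray:
    """Sigmoid y = a * exp(-exp(-k (x - x_c))); maximum slope a*k/e at x = x_c."""
    return a * np.exp(-np.exp(-k * (np.asarray(x, dtype=float) - x_c)))


# ---------------------------------------------------------------------------
# 2D calibration patterns


def gen_pattern(kind: str, size: int = 256, seed: int = 0) -> np.ndarray:
    """Generate a 2D calibration texture for the entropy-complexity plane.

    ``periodic`` — oriented stripes of a single spatial frequency (ordered,
    anisotropic: low entropy, low complexity); ``noise`` — i.i.d. pixels
    (maximal entropy, low complexity); ``branching`` — a recursive random
    tree silhouette blurred by a Gaussian point-spread kernel (structured
    randomness: intermediate entropy, high complexity).
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    rng = np.random.default_rng(seed)
    if kind == "periodic":
        theta = rng.uniform(0, np.pi)
        freq = 0.15
        x = np.arange(size)
        phase = 2 * np.pi * freq * (np.cos(theta) * x[None, :] + np.sin(theta) * x[:, None])
        return np.sin(phase + rng.uniform(0, 2 * np.pi))
    if kind == "noise":
        return rng.standard_normal((size, size))
    if kind == "branching":
        img = np.zeros((size, size))
        _draw_tree(
            img,
            y=size / 2.0,
            x=size / 2.0,
            angle=rng.uniform(0, 2 * np.pi),
            length=size * 0.28,
            depth=6,
            rng=rng,
            n_root=5,
        )
        return gaussian_filter(img, 1.5)
    raise ValueError(f"unknown pattern kind: {kind!r}")


def _draw_segment(img: np.ndarray, y0, x0, y1, x1) -> None:
    n = int(max(abs(y1 - y0), abs(x1 - x0), 1)) * 2
    ys = np.linspace(y0, y1, n).round().astype(int)
    xs = np.linspace(x0, x1, n).round().astype(int)
    h, w = img.shape
    ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    img[ys[ok], xs[ok]] = 1.0


def _draw_tree(img, y, x, angle, length, depth, rng, n_root=0) -> None:
    if depth == 0 or length < 2:
        return
    if n_root:  # trunk level: several primary branches from the root
        for i in range(n_root):
            a = 2 * np.pi * i / n_root + rng.normal(0, 0.3)
            _draw_tree(img, y, x, a, length, depth - 1, rng)
        return
    y1 = y + length * np.sin(angle)
    x1 = x + length * np.cos(angle)
    _draw_segment(img, y, x, y1, x1)
    for da in (-1, 1):
        _draw_tree(
            img,
            y1,
            x1,
            angle + da * rng.uniform(0.3, 0.8),
            length * rng.uniform(0.55, 0.75),
            depth - 1,
            rng,
        )


# ---------------------------------------------------------------------------
# astrocyte z-stacks


def gen_astrocyte(params: dict | None = None, seed: int = 0) -> SyntheticAstrocyte:
    """Branching astrocyte silhouette in a bounded domain with soma and leaflet haze.

    The soma is a bright disc; ``n_rays`` straight (optionally gently curved)
    processes emanate from it; sub-resolution leaflets appear as a uniform
    haze at fraction ``leaflet_vf`` of the soma intensity within the cell's
    domain.  The returned truth record holds the planted ray geometry and
    volume fraction.
    """
    p = {
        "n_rays": 6,
        "ray_length_um": 40.0,
        "leaflet_vf": 0.034,
        "pixel_size": 0.5,
        "noise_sd": 0.0,
        "soma_radius_um": 6.0,
        "ray_width_um": 1.5,
        "ray_intensity": 0.6,
        "domain_radius_um": None,  # default: 1.15 * ray_length
        "fov_um": None,  # default: 2.6 * ray_length
        "n_planes": 5,
        "angle_jitter": 0.0,
        "angle_offset": 0.0,
        "curvature": 0.0,
    }
    if params:
        p.update(params)
    if p["n_rays"] < 1:
        raise ValueError("n_rays must be >= 1")
    if not 0 < p["leaflet_vf"] < 1:
        raise ValueError("leaflet_vf must lie in (0, 1)")
    fov = p["fov_um"] if p["fov_um"] is not None else 2.6 * p["ray_length_um"]
    if fov < 2 * p["ray_length_um"]:
        raise ValueError("field of view smaller than twice the ray length")

    rng = np.random.default_rng(seed)
    px = p["pixel_size"]
    n = int(round(fov / px))
    n += n % 2  # even side for the shearlet stage
    cy = cx = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    r_px = np.hypot(yy - cy, xx - cx)

    soma_r = p["soma_radius_um"] / px
    domain_r = (p["domain_radius_um"] or 1.15 * p["ray_length_um"]) / px

    plane = np.zeros((n, n))
    plane[r_px <= domain_r] = p["leaflet_vf"]  # haze, fraction of soma intensity

    angles = [
        2 * np.pi * i / p["n_rays"] + p["angle_offset"] + rng.normal(0, p["angle_jitter"])
        for i in range(p["n_rays"])
    ]
    ray_len_px = p["ray_length_um"] / px
    half_w = max(p["ray_width_um"] / px / 2.0, 0.75)
    ts = np.linspace(0.0, 1.0, int(ray_len_px * 3))
    for a in angles:
        bend = p["curvature"] * rng.uniform(-1, 1)
        ang = a + bend * ts
        ry = cy + ray_len_px * ts * np.sin(ang)
        rx = cx + ray_len_px * ts * np.cos(ang)
        for oy in np.arange(-half_w, half_w + 0.5, 0.5):
            for ox in np.arange(-half_w, half_w + 0.5, 0.5):
                iy = np.clip((ry + oy).round().astype(int), 0, n - 1)
                ix = np.clip((rx + ox).round().astype(int), 0, n - 1)
                plane[iy, ix] = np.maximum(plane[iy, ix], p["ray_intensity"])
    plane[r_px <= soma_r] = 1.0  # soma brightest

    nz = int(p["n_planes"])
    stack = np.repeat(plane[None], nz, axis=0)
    if p["noise_sd"] > 0:
        stack = stack + rng.normal(0, p["noise_sd"], stack.shape)
    stack = np.clip(stack, 0.0, None)

    truth = {
        "n_primary_rays": int(p["n_rays"]),
        "ray_lengths": [p["ray_length_um"]] * p["n_rays"],
        "ray_angles": angles,
        "leaflet_vf": p["leaflet_vf"],
        "soma_radius_um": p["soma_radius_um"],
        "domain_radius_um": domain_r * px,
    }
    return SyntheticAstrocyte(
        image_stack=stack,
        soma_center=(nz // 2, cy, cx),
        pixel_size=px,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Ca2+ movies


def gen_ca_movie(params: dict | None = None, seed: int = 0) -> SyntheticCaMovie:
    """Time-lapse Ca2+ movie with planted x-y-time events on a drifting baseline.

    Event footprint areas and durations are drawn from power laws
    ``P(x) ~ x**-alpha`` above the analysis floors, so the planted exponents
    are recoverable after filtering.  Each event is an ellipse footprint whose
    amplitude rises within one frame, holds for the planted duration and then
    decays exponentially; a slow multiplicative drift and shot-like noise are
    applied on top of a flat baseline.  Dark frames (constant offset plus
    Gaussian read noise) are returned alongside, as recorded after imaging.
    """
    p = {
        "n_events": 32,
        "alpha_area": 2.7,
        "alpha_duration": 2.75,
        "area_min_um2": 10.0,
        "dur_min_s": 2.0,
        "fov_um": 100.0,
        "frames": 600,
        "baseline_drift": 0.10,
        "noise_sd": 0.04,
        "pixel_size": 0.5,
        "frame_interval": 1.0,
        "baseline_f": 100.0,
        "dark_offset": 10.0,
        "dark_noise_sd": 2.0,
        "n_dark_frames": 30,
        "amplitude_dff": 1.2,
        "decay_tau_s": 0.5,
    }
    if params:
        p.update(params)
    if p["alpha_area"] <= 1 or p["alpha_duration"] <= 1:
        raise ValueError("power-law exponents must exceed 1")
    if p["frames"] < 120:
        raise ValueError("need at least 120 frames")

    rng = np.random.default_rng(seed)
    px = p["pixel_size"]
    dt = p["frame_interval"]
    n = int(round(p["fov_um"] / px))
    T = int(p["frames"])
    fov_area = (n * px) ** 2

    n_ev = int(p["n_events"])
    events: list[dict] = []
    dff = np.zeros((T, n, n))
    if n_ev > 0:
        areas = sample_power_law(
            n_ev, p["alpha_area"], p["area_min_um2"], rng, x_max=fov_area / 8.0
        )
        durs = sample_power_law(
            n_ev, p["alpha_duration"], p["dur_min_s"], rng, x_max=T * dt / 4.0
        )
        duty = float((areas / fov_area * durs / (T * dt)).sum())
        if duty > 0.5:
            logger.warning(
                "planted events imply %.0f%% mean duty cycle; overlaps will confound truth",
                100 * duty,
            )
        yy, xx = np.mgrid[0:n, 0:n]
        for i in range(n_ev):
            area_px = areas[i] / px**2
            ecc = rng.uniform(0.6, 1.0)
            ry = np.sqrt(area_px / (np.pi * ecc))
            rx = area_px / (np.pi * ry)
            theta = rng.uniform(0, np.pi)
            my = max(ry, rx) + 2
            cy = rng.uniform(my, n - my)
            cx = rng.uniform(my, n - my)
            c, s = np.cos(theta), np.sin(theta)
            u = c * (xx - cx) + s * (yy - cy)
            v = -s * (xx - cx) + c * (yy - cy)
            fp = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
            dur_frames = max(int(round(durs[i] / dt)), 1)
            t0 = int(rng.integers(2, max(T - dur_frames - 8, 3)))
            amp = p["amplitude_dff"] * rng.uniform(0.8, 1.3)
            # plateau for the planted duration, then fast exponential decay
            for tf in range(dur_frames):
                dff[t0 + tf][fp] += amp
            tail = np.arange(1, 5)
            for tt in tail:
                t_idx = t0 + dur_frames - 1 + tt
                if t_idx < T:
                    dff[t_idx][fp] += amp * np.exp(-tt * dt / p["decay_tau_s"])
            events.append(
                {
                    "t0": t0 * dt,
                    "duration_s": dur_frames * dt,
                    "footprint_area_um2": float(fp.sum()) * px**2,
                    "amplitude_dFF": amp,
                    "footprint": fp,
                }
            )

    t = np.arange(T) * dt
    drift = 1.0 + p["baseline_drift"] * np.sin(
        2 * np.pi * t / (T * dt) + rng.uniform(0, 2 * np.pi)
    )
    F = p["baseline_f"] * drift[:, None, None] * (1.0 + dff)
    noise = rng.normal(0, 1, F.shape) * (p["noise_sd"] * p["baseline_f"]) * np.sqrt(
        np.clip(F, 1e-9, None) / p["baseline_f"]
    )
    movie = np.clip(F + noise + p["dark_offset"], 0.0, None)

    dark = p["dark_offset"] + rng.normal(
        0, p["dark_noise_sd"], (int(p["n_dark_frames"]), n, n)
    )
    return SyntheticCaMovie(
        movie=movie,
        dark_frames=np.clip(dark, 0.0, None),
        frame_interval=dt,
        pixel_size=px,
        planted_events=events,
        alpha_true_area=p["alpha_area"],
        alpha_true_duration=p["alpha_duration"],
    )


# ---------------------------------------------------------------------------
# dye-coupling records


def gen_coupling_set(
    c_lambda_um: float, n: int = 50, noise_sd: float = 0.1, seed: int = 0
) -> SyntheticCouplingSet:
    """Coupled-soma intensities decaying as I0 * exp(-d / C_lambda) with lognormal noise."""
    if c_lambda_um <= 0:
        raise ValueError("length constant must be positive")
    if n < 3:
        raise ValueError("need at least 3 coupled cells")
    rng = np.random.default_rng(seed)
    d = rng.uniform(10.0, 120.0, n)
    i0 = 0.95
    intensity = i0 * np.exp(-d / c_lambda_um)
    if noise_sd > 0:
        intensity = intensity * np.exp(rng.normal(0, noise_sd, n))
    intensity = np.minimum(intensity, 1.0)
    records = [
        {"distance_um": float(di), "normalized_intensity": float(ii)}
        for di, ii in zip(d, intensity)
    ]
    return SyntheticCouplingSet(records=records, c_lambda_true=c_lambda_um, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# electrophysiology traces


def gen_traces(truth: dict | None = None, seed: int = 0) -> SyntheticTraceSet:
    """Synthetic whole-cell and field-potential recordings with planted metrics.

    Returns labelled traces on a uniform 5 kHz grid:

    - ``ik_1``: K+ current to one stimulus — a fast contaminating transient
      (field/transporter currents, gone within 100 ms) plus the slow
      ``A * exp(-t / tau)`` potassium component;
    - ``ik_4`` / ``ik_5``: responses to 4 and 5 stimuli whose difference
      isolates the fifth-stimulus current at the planted amplitude ratio;
    - ``fepsp``: paired-pulse field sweep (negative-going) with presynaptic
      volley, 50 ms interstimulus interval;
    - ``io_prv`` / ``io_fepsp``: input-output samples on a Gompertz curve;
    - ``ltp_time_min`` / ``ltp_slope``: normalized rising-slope time series
      around a high-frequency-stimulation point at t = 0.
    """
    tr = {
        "tau_s": 2.5,
        "ik_amp_pA": 35.0,
        "tau5_s": None,  # default: tau5/tau1 = 1.45
        "ik5_ratio": 0.72,
        "gompertz": (4.0, 1.0, 0.5),
        "ltp_ratio": 1.73,
        "ltp_profile": "constant",  # or "decay"
        "ltp_early": 2.0,
        "ltp_late": 1.29,
        "fepsp_amp_mV": 1.0,
        "ppr": 1.0,
        "noise_sd": 0.0,
        "io_noise_frac": 0.0,
        "fs_hz": 5000.0,
    }
    if truth:
        tr.update(truth)
    if tr["tau_s"] <= 0:
        raise ValueError("tau_s must be positive")
    rng = np.random.default_rng(seed)
    fs = tr["fs_hz"]

    # --- K+ currents -------------------------------------------------------
    t_ik = np.arange(0.0, 12.0, 1.0 / fs)
    stim1 = 0.5
    tau1 = tr["tau_s"]
    tau5 = tr["tau5_s"] if tr["tau5_s"] is not None else 1.45 * tau1
    # amplitude convention: planted ik_amp_pA is the value read 200 ms post-stimulus
    a1 = tr["ik_amp_pA"] / np.exp(-0.2 / tau1)

    def ik_component(t0, amp, tau):
        out = np.zeros_like(t_ik)
        m = t_ik >= t0
        out[m] = amp * np.exp(-(t_ik[m] - t0) / tau)
        return out

    def fast_contaminant(t0, amp=120.0, tau=0.02):
        out = np.zeros_like(t_ik)
        m = (t_ik >= t0) & (t_ik < t0 + 0.1)
        out[m] = amp * np.exp(-(t_ik[m] - t0) / tau)
        return out

    ik1 = ik_component(stim1, a1, tau1) + fast_contaminant(stim1)
    # 4- and 5-stimulus responses at 50 Hz; the 5th adds an isolated component
    stims = stim1 + 0.02 * np.arange(5)
    base4 = sum(ik_component(s, a1 * 0.9**i, tau1) + fast_contaminant(s) for i, s in enumerate(stims[:4]))
    ik5_amp_at_200 = tr["ik5_ratio"] * tr["ik_amp_pA"]
    a5 = ik5_amp_at_200 / np.exp(-0.2 / tau5)
    ik5_component = ik_component(stims[4], a5, tau5) + fast_contaminant(stims[4])
    base5 = base4 + ik5_component
    if tr["noise_sd"] > 0:
        ik1 = ik1 + rng.normal(0, tr["noise_sd"], ik1.shape)
        base4 = base4 + rng.normal(0, tr["noise_sd"], base4.shape)
        base5 = base5 + rng.normal(0, tr["noise_sd"], base5.shape)

    # --- paired-pulse fEPSP sweep -----------------------------------------
    t_f = np.arange(0.0, 0.25, 1.0 / fs)
    f_stims = np.array([0.02, 0.07])  # 50 ms interstimulus interval

    def fepsp_wave(t0, amp):
        # synaptic delay: the field EPSP follows the fiber volley by ~3 ms
        out = np.zeros_like(t_f)
        m = t_f >= t0 + 0.003
        tt = t_f[m] - (t0 + 0.003)
        tau_r, tau_d = 0.0015, 0.008
        shape = (1 - np.exp(-tt / tau_r)) * np.exp(-tt / tau_d)
        out[m] = -amp * shape / shape.max()
        return out

    def prv_wave(t0, amp=0.3):
        out = np.zeros_like(t_f)
        m = t_f >= t0
        tt = t_f[m] - t0
        out[m] = -amp * np.exp(-((tt - 0.0008) / 0.0004) ** 2)
        return out

    sweep = (
        fepsp_wave(f_stims[0], tr["fepsp_amp_mV"])
        + fepsp_wave(f_stims[1], tr["fepsp_amp_mV"] * tr["ppr"])
        + prv_wave(f_stims[0])
        + prv_wave(f_stims[1])
    )
    if tr["noise_sd"] > 0:
        sweep = sweep + rng.normal(0, 0.002 * tr["noise_sd"], sweep.shape)

    # --- Gompertz input-output samples ------------------------------------
    a, k, x_c = tr["gompertz"]
    prv = np.linspace(max(x_c - 3.0 / k, 0.01), x_c + 3.0 / k, 12)
    io = gompertz(prv, a, k, x_c)
    if tr["io_noise_frac"] > 0:
        io = io + rng.normal(0, tr["io_noise_frac"] * a, io.shape)

    # --- LTP slope time series ---------------------------------------------
    t_min = np.arange(-20.0, 60.0, 1.0 / 3.0)  # one sweep per 20 s
    ltp = np.ones_like(t_min)
    post = t_min > 0
    if tr["ltp_profile"] == "constant":
        ltp[post] = tr["ltp_ratio"]
    elif tr["ltp_profile"] == "decay":
        tau_p = 25.0  # min
        ltp[post] = tr["ltp_late"] + (tr["ltp_early"] - tr["ltp_late"]) * np.exp(
            -t_min[post] / tau_p
        )
    else:
        raise ValueError(f"unknown ltp_profile {tr['ltp_profile']!r}")
    if tr["noise_sd"] > 0:
        ltp = ltp + rng.normal(0, 0.01 * tr["noise_sd"], ltp.shape)

    truth_out = dict(tr)
    truth_out["tau5_s"] = tau5
    truth_out["ik_a1"] = a1
    truth_out["ltp_decay_tau_min"] = 25.0

    return SyntheticTraceSet(
        time=t_ik,
        traces={
            "ik_1": ik1,
            "ik_4": base4,
            "ik_5": base5,
            "fepsp_time": t_f,
            "fepsp": sweep,
            "io_prv": prv,
            "io_fepsp": io,
            "ltp_time_min": t_min,
            "ltp_slope": ltp,
        },
        stim_times={"ik": stim1, "ik_train": stims.tolist(), "fepsp": f_stims.tolist(), "hfs_min": 0.0},
        truth=truth_out,
    )


def ltp_true_window_mean(truth: dict, t0_min: float, t1_min: float) -> float:
    """Closed-form mean of the planted post-induction slope over [t0, t1] minutes."""
    if truth["ltp_profile"] == "constant":
        return float(truth["ltp_ratio"])
    tau = truth["ltp_decay_tau_min"]
    late, early = truth["ltp_late"], truth["ltp_early"]
    integral = late * (t1_min - t0_min) + (early - late) * tau * (
        np.exp(-t0_min / tau) - np.exp(-t1_min / tau)
    )
    return float(integral / (t1_min - t0_min))
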