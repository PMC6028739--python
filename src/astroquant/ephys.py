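"""Whole-cell and field-potential metrics for hippocampal slice recordings.

Whole-cell side: the astrocytic K+ current (I_K) following Schaffer-collateral
stimulation is read 200 ms post-stimulus — past the fast field-potential and
transporter currents, which end within ~100 ms — and its decay from that
point is fitted with a mono-exponential to give tau_decay.  The current to
the fifth stimulus of a 50-Hz train is isolated by subtracting the 4-stimulus
response from the 5-stimulus response.

Field side: fEPSP amplitude (negative-going), 20-80 % rising slope, presynaptic
fiber volley, paired-pulse ratio (second/first amplitude, 50-ms interval), a
Gompertz fit of the input-output relation y = a exp(-exp(-k (x - x_c))) whose
maximum slope is a k / e, and the LTP magnitude as the ratio of the averaged
potentiated (47-60 min post-HFS) to baseline rising slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "IKMeasurement",
    "FepspMetrics",
    "GompertzFit",
    "LtpResult",
    "measure_ik",
    "isolate_fifth",
    "fepsp_metrics",
    "fit_gompertz",
    "ltp_magnitude",
    "gompertz",
]

IK_READOUT_DELAY_S = 0.2  # I_K is measured 200 ms after the stimulus


def gompertz(x, a, k, x_c):
    return a * np.exp(-np.exp(-k * (np.asarray(x, dtype=float) - x_c)))


@dataclass
class IKMeasurement:
    ik_amp: float  # pA at 200 ms post-stimulus
    tau_decay: float  # s
    stimulus_count: int = 1
    valid: bool = True
    ratios: dict = field(default_factory=dict)


@dataclass
class FepspMetrics:
    amplitude: float  # mV, magnitude of the negative deflection
    slope_20_80: float  # mV/ms, magnitude
    prv_amp: float  # mV
    ppr: float = np.nan
    amplitude2: float = np.nan
    valid: bool = True


@dataclass
class GompertzFit:
    a: float
    k: float
    x_c: float
    max_slope: float  # a * k / e
    valid: bool = True
    residual: float = np.nan


@dataclass
class LtpResult:
    baseline_mean_slope: float
    potentiated_mean_slope: float
    magnitude: float


def measure_ik(
    time: np.ndarray,
    trace: np.ndarray,
    stim_time: float,
    fit_span_s: float = 2.0,
    stimulus_count: int = 1,
) -> IKMeasurement:
    """I_K amplitude at 200 ms post-stimulus and mono-exponential decay constant.

    The trace must be baseline-subtracted.  The decay is fitted from the
    200-ms point over ``fit_span_s`` (or to the end of the trace) by
    nonlinear least squares initialized from a semilog line.  A non-decaying
    tail is flagged invalid.
    """
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    t0 = stim_time + IK_READOUT_DELAY_S
    i0 = int(np.searchsorted(time, t0))
    if i0 >= time.size:
        raise ValueError("readout point beyond the trace")
    amp = float(np.interp(t0, time, trace))
    i1 = int(np.searchsorted(time, t0 + fit_span_s))
    tt = time[i0:i1] - t0
    yy = trace[i0:i1]
    if tt.size < 10 or amp <= 0 or np.all(yy <= 0):
        return IKMeasurement(ik_amp=amp, tau_decay=np.nan, stimulus_count=stimulus_count, valid=False)

    pos = yy > 0
    slope, intercept = np.polyfit(tt[pos], np.log(yy[pos]), 1)
    if slope >= 0:
        return IKMeasurement(ik_amp=amp, tau_decay=np.nan, stimulus_count=stimulus_count, valid=False)
    try:
        popt, _ = optimize.curve_fit(
            lambda t, A, tau: A * np.exp(-t / tau),
            tt,
            yy,
            p0=(np.exp(intercept), -1.0 / slope),
            maxfev=10000,
        )
    except RuntimeError:
        return IKMeasurement(ik_amp=amp, tau_decay=np.nan, stimulus_count=stimulus_count, valid=False)
    if popt[1] <= 0:
        return IKMeasurement(ik_amp=amp, tau_decay=np.nan, stimulus_count=stimulus_count, valid=False)
    return IKMeasurement(
        ik_amp=amp, tau_decay=float(popt[1]), stimulus_count=stimulus_count
    )


def isolate_fifth(resp_5stim: np.ndarray, resp_4stim: np.ndarray) -> np.ndarray:
    """Isolate the fifth-stimulus current: pointwise 5-stimulus minus 4-stimulus response."""
    resp_5stim = np.asarray(resp_5stim, dtype=float)
    resp_4stim = np.asarray(resp_4stim, dtype=float)
    if resp_5stim.shape != resp_4stim.shape:
        raise ValueError("responses must share one time base")
    return resp_5stim - resp_4stim


def _peak_and_slope(time_ms, sweep, lo, hi):
    """Negative-peak amplitude and 20-80% rising slope within a window (ms)."""
    m = (time_ms >= lo) & (time_ms < hi)
    tw, yw = time_ms[m], sweep[m]
    if yw.size == 0 or yw.min() >= 0:
        return np.nan, np.nan
    ipk = int(np.argmin(yw))
    amp = -float(yw[ipk])
    y20, y80 = -0.2 * amp, -0.8 * amp
    seg_t, seg_y = tw[: ipk + 1], yw[: ipk + 1]

    def crossing(level):
        below = np.nonzero(seg_y <= level)[0]
        if below.size == 0:
            return np.nan
        j = below[0]
        if j == 0:
            return seg_t[0]
        return float(
            np.interp(level, [seg_y[j], seg_y[j - 1]], [seg_t[j], seg_t[j - 1]])
        )

    t20, t80 = crossing(y20), crossing(y80)
    if not np.isfinite(t20) or not np.isfinite(t80) or t80 <= t20:
        return amp, np.nan
    slope = 0.6 * amp / (t80 - t20)  # mV / ms, magnitude
    return amp, slope


def fepsp_metrics(
    time: np.ndarray,
    sweep: np.ndarray,
    stim_times,
    prv_window_ms: float = 2.0,
    response_window_ms: float = 40.0,
) -> FepspMetrics:
    """fEPSP amplitude, 20-80 % rising slope, fiber volley and paired-pulse ratio.

    Stimulus times are in seconds; with two stimuli the PPR is the second
    amplitude over the first.  The presynaptic volley is the first fast
    negative peak within ``prv_window_ms`` of the stimulus; the fEPSP peak is
    sought after it within ``response_window_ms``.
    """
    time_ms = np.asarray(time, dtype=float) * 1e3
    sweep = np.asarray(sweep, dtype=float)
    stim_ms = [s * 1e3 for s in np.atleast_1d(stim_times)]
    pre = time_ms < stim_ms[0]
    if pre.any():  # reference to the pre-stimulus baseline
        sweep = sweep - sweep[pre].mean()

    amps, slopes = [], []
    prv_amp = np.nan
    valid = True
    for si, s in enumerate(stim_ms):
        if si == 0:
            m = (time_ms >= s) & (time_ms < s + prv_window_ms)
            prv_amp = -float(sweep[m].min()) if m.any() else np.nan
        amp, slope = _peak_and_slope(time_ms, sweep, s + prv_window_ms, s + response_window_ms)
        if not np.isfinite(amp):
            valid = False
        amps.append(amp)
        slopes.append(slope)

    ppr = amps[1] / amps[0] if len(amps) > 1 and np.isfinite(amps[0]) else np.nan
    return FepspMetrics(
        amplitude=amps[0],
        slope_20_80=slopes[0],
        prv_amp=prv_amp,
        ppr=ppr,
        amplitude2=amps[1] if len(amps) > 1 else np.nan,
        valid=valid,
    )


def fit_gompertz(prv: np.ndarray, fepsp: np.ndarray) -> GompertzFit:
    """Fit the input-output relation with a Gompertz sigmoid.

    Initialization: a = max(y), x_c = x at half-maximum, k from the central
    finite-difference slope (max slope = a k / e).  Degenerate data (flat or
    non-positive response) is flagged instead of fitted.
    """
    x = np.asarray(prv, dtype=float)
    y = np.asarray(fepsp, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 input-output points")
    if np.all(y <= 0) or np.ptp(y) == 0:
        return GompertzFit(a=np.nan, k=np.nan, x_c=np.nan, max_slope=np.nan, valid=False)

    a0 = float(y.max())
    x_c0 = float(np.interp(a0 / 2.0, y, x)) if np.all(np.diff(y) >= 0) else float(
        x[np.argmin(np.abs(y - a0 / 2))]
    )
    dy = np.gradient(y, x)
    k0 = max(float(dy.max()) * np.e / a0, 1e-3)
    try:
        popt, _ = optimize.curve_fit(
            gompertz, x, y, p0=(a0, k0, x_c0), maxfev=20000
        )
    except RuntimeError:
        return GompertzFit(a=np.nan, k=np.nan, x_c=np.nan, max_slope=np.nan, valid=False)
    a, k, x_c = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((gompertz(x, *popt) - y) ** 2)))
    return GompertzFit(a=a, k=k, x_c=x_c, max_slope=a * k / np.e, residual=resid)


def ltp_magnitude(
    time_min: np.ndarray,
    slope_series: np.ndarray,
    hfs_time_min: float = 0.0,
    baseline_span_min: float = 20.0,
    potentiated_window_min: tuple[float, float] = (47.0, 60.0),
) -> LtpResult:
    """LTP magnitude: mean rising slope 47-60 min post-HFS over the baseline mean.

    Requires at least 20 min of pre-induction baseline and data through the
    end of the potentiated window.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(slope_series, dtype=float)
    base = (t >= hfs_time_min - baseline_span_min) & (t < hfs_time_min)
    lo, hi = potentiated_window_min
    pot = (t >= hfs_time_min + lo) & (t <= hfs_time_min + hi)
    if not base.any() or t[base].min() > hfs_time_min - baseline_span_min + 1.0:
        raise ValueError("insufficient pre-induction baseline")
    if not pot.any() or t.max() < hfs_time_min + hi - 1.0:
        raise ValueError("recording does not cover the potentiated window")
    b = float(y[base].mean())
    p = float(y[pot].mean())
    return LtpResult(baseline_mean_slope=b, potentiated_mean_slope=p, magnitude=p / b)
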