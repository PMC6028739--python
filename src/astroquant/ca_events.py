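"""x-y-time Ca2+ event detection and power-law statistics of event sizes.

Processing chain for one-frame-per-second time-lapse movies: dark-noise
subtraction (per-pixel median of dark frames), optional denoising hook,
rigid registration (single-step DFT phase correlation), per-pixel two-pass
baseline estimation (Savitzky-Golay smoothing with transient exclusion) to
obtain dF/F, statistical thresholding, grouping of active pixels into x-y
events per frame and linking across frames by footprint overlap into
x-y-time 3D events.  Each event carries its maximal projection area S_max
(union of per-frame footprints, um^2), its space-time integral (um^2 s) and
duration (s); events with integral < 4 um^2 s, S_max < 10 um^2 or duration
< 2 s are excluded as noise (values exactly at a threshold are kept — the
exclusion rule is "less than").  Distributions of S_max and duration follow
a power law P(x) ~ x**-alpha whose exponent is estimated by least squares on
log-binned densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_filter
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "DffMovie",
    "CaEvent",
    "PowerLawFit",
    "subtract_dark_noise",
    "register_movie",
    "compute_dff",
    "detect_events",
    "filter_events",
    "frequency_density",
    "fit_power_law",
]

# analysis floors for astrocytic events
MIN_INTEGRAL_UM2S = 4.0
MIN_SMAX_UM2 = 10.0
MIN_DURATION_S = 2.0


@dataclass
class DffMovie:
    dff: np.ndarray  # (t, y, x)
    F0: np.ndarray  # per-pixel baseline, (t, y, x)
    frame_interval: float  # s
    pixel_area: float  # um^2 / pixel


@dataclass
class CaEvent:
    voxels: np.ndarray  # (n, 3) array of (t, y, x)
    s_max: float  # um^2, area of the union of per-frame footprints
    integral: float  # um^2 s
    duration: float  # s
    t_start: float  # s


@dataclass
class PowerLawFit:
    alpha: float
    x_min: float
    n_samples: int
    bin_edges: np.ndarray
    fit_stderr: float
    intercept: float = field(default=np.nan)


def subtract_dark_noise(movie: np.ndarray, dark_frames: np.ndarray) -> np.ndarray:
    """Subtract the per-pixel median of the dark frames; clip negatives to zero."""
    movie = np.asarray(movie, dtype=float)
    dark_frames = np.asarray(dark_frames, dtype=float)
    if dark_frames.ndim == 2:
        dark_frames = dark_frames[None]
    if dark_frames.shape[1:] != movie.shape[1:]:
        raise ValueError("dark frames must match the movie field of view")
    out = movie - np.median(dark_frames, axis=0)
    n_neg = int((out < 0).sum())
    if n_neg:
        logger.info("dark subtraction clipped %d negative samples to zero", n_neg)
    return np.clip(out, 0.0, None)


def register_movie(
    movie: np.ndarray, upsample_factor: int = 10, reference: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid x-y registration of each frame to a reference by DFT phase correlation.

    Returns the registered movie and the applied (dy, dx) shift per frame.
    Frames carrying no spatial information get zero shift with a warning.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.shape[0] < 2:
        raise ValueError("need at least two frames to register")
    ref = movie[reference]
    out = np.empty_like(movie)
    shifts = np.zeros((movie.shape[0], 2))
    for i, frame in enumerate(movie):
        if i == reference:
            out[i] = frame
            continue
        if np.ptp(frame) == 0:
            logger.warning("frame %d is constant; zero shift assumed", i)
            out[i] = frame
            continue
        shift, _, _ = phase_cross_correlation(ref, frame, upsample_factor=upsample_factor)
        shifts[i] = shift
        out[i] = ndimage.shift(frame, shift, order=1, mode="nearest")
    return out, shifts


def _odd_window(seconds: float, dt: float, n_frames: int) -> int:
    w = int(round(seconds / dt))
    w = max(w, 5)
    if w % 2 == 0:
        w += 1
    if w >= n_frames:
        raise ValueError(
            f"{seconds}-s smoothing window needs more than {w} frames; movie has {n_frames}"
        )
    return w


def compute_dff(
    movie: np.ndarray,
    frame_interval: float = 1.0,
    pixel_size: float = 0.5,
    rough_window_s: float = 60.0,
    final_window_s: float = 100.0,
    polyorder: int = 3,
    exclusion_k: float = 2.5,
) -> DffMovie:
    """Per-pixel dF/F with a transient-excluded Savitzky-Golay baseline.

    Pass 1 smooths each pixel's trace with a 60-s 3rd-order Savitzky-Golay
    filter into a rough baseline F0_temp; samples whose provisional dF/F
    exceeds ``exclusion_k`` robust noise SDs are flagged as transients.
    Pass 2 removes those samples, linearly interpolates the gaps, and smooths
    with a 100-s filter to give the final uninterrupted baseline F0, from
    which dF/F = (F - F0) / F0.
    """
    movie = np.asarray(movie, dtype=float)
    T = movie.shape[0]
    w1 = _odd_window(rough_window_s, frame_interval, T)
    w2 = _odd_window(final_window_s, frame_interval, T)

    f0_temp = savgol_filter(movie, w1, polyorder, axis=0)
    f0_temp = np.clip(f0_temp, 1e-9, None)
    dff_temp = (movie - f0_temp) / f0_temp

    mad = np.median(np.abs(dff_temp - np.median(dff_temp, axis=0)), axis=0)
    noise = 1.4826 * mad
    transient = dff_temp > exclusion_k * np.maximum(noise, 1e-12)
    # the rough baseline tracks the middle of transients wider than ~w1/2,
    # unflagging their interior; closing along time merges onset/offset runs
    if transient.any():
        struct = np.ones((w1, 1, 1), dtype=bool)
        transient = ndimage.binary_closing(transient, structure=struct)

    cleaned = movie.copy()
    t_idx = np.arange(T, dtype=float)
    bad_pixels = np.argwhere(transient.any(axis=0))
    for y, x in bad_pixels:
        m = transient[:, y, x]
        if m.all():
            continue  # nothing to interpolate from; leave the trace as is
        cleaned[m, y, x] = np.interp(t_idx[m], t_idx[~m], movie[~m, y, x])

    f0 = savgol_filter(cleaned, w2, polyorder, axis=0)
    f0 = np.clip(f0, 1e-9, None)
    dff = (movie - f0) / f0
    return DffMovie(
        dff=dff, F0=f0, frame_interval=frame_interval, pixel_area=pixel_size**2
    )


# temporal linking: two x-y events in consecutive frames merge iff their
# footprints share at least one pixel (no diagonal links in time)
_LINK_STRUCTURE = np.zeros((3, 3, 3), dtype=bool)
_LINK_STRUCTURE[1] = True
_LINK_STRUCTURE[0, 1, 1] = True
_LINK_STRUCTURE[2, 1, 1] = True


def detect_events(
    dff_movie: DffMovie, threshold_k: float = 2.5, gap_frames: int = 0
) -> list[CaEvent]:
    """Detect x-y-time Ca2+ events above a statistical threshold.

    dF/F is binarized at ``threshold_k`` times the per-pixel robust noise SD
    (1.4826 * MAD of the trace); active pixels are grouped per frame with
    8-connectivity and linked across consecutive frames by footprint overlap.
    With ``gap_frames`` > 0, events separated by that many silent frames are
    additionally bridged.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be positive")
    dff = dff_movie.dff
    dt = dff_movie.frame_interval
    pa = dff_movie.pixel_area

    mad = np.median(np.abs(dff - np.median(dff, axis=0)), axis=0)
    noise = 1.4826 * mad
    active = dff > threshold_k * noise
    active &= dff > 0  # threshold_k * 0 on noiseless pixels

    if gap_frames > 0:
        closer = np.zeros((2 * gap_frames + 1, 1, 1), dtype=bool)
        closer[:, 0, 0] = True
        active = ndimage.binary_closing(active, structure=closer)

    labels, n_lab = ndimage.label(active, structure=_LINK_STRUCTURE)
    events: list[CaEvent] = []
    for lab_idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        sub = labels[sl] == lab_idx
        vox = np.argwhere(sub)
        vox[:, 0] += sl[0].start
        vox[:, 1] += sl[1].start
        vox[:, 2] += sl[2].start
        footprint_union = sub.any(axis=0)
        t_first, t_last = sl[0].start, sl[0].stop - 1
        events.append(
            CaEvent(
                voxels=vox,
                s_max=float(footprint_union.sum()) * pa,
                integral=float(sub.sum()) * pa * dt,
                duration=(t_last - t_first + 1) * dt,
                t_start=t_first * dt,
            )
        )
    return events


def filter_events(events: list[CaEvent]) -> list[CaEvent]:
    """Exclude noise events: integral < 4 um^2 s, S_max < 10 um^2 or duration < 2 s.

    Thresholds are exclusive ("less than"), so boundary values are kept.
    """
    return [
        e
        for e in events
        if e.integral >= MIN_INTEGRAL_UM2S
        and e.s_max >= MIN_SMAX_UM2
        and e.duration >= MIN_DURATION_S
    ]


def frequency_density(
    events: list, fov_area_mm2: float, movie_duration_s: float
) -> float:
    """Event frequency normalized to imaged area: count / (duration * area), s^-1 mm^-2."""
    if fov_area_mm2 <= 0 or movie_duration_s <= 0:
        raise ValueError("area and duration must be positive")
    return len(events) / (movie_duration_s * fov_area_mm2)


def fit_power_law(
    values,
    x_min: float,
    bins_per_decade: int = 12,
    tail_percentile: float = 99.0,
    min_bin_count: int = 5,
) -> PowerLawFit:
    """Estimate the exponent of P(x) ~ x**-alpha by log-binned least squares.

    Samples at or above ``x_min`` are histogrammed in log-spaced bins and the
    per-bin probability density (count / (bin width * n)) is fitted with a
    straight line in log-log space; alpha is the negated slope.  The extreme
    tail (above ``tail_percentile`` of the sample) and bins with fewer than
    ``min_bin_count`` counts are excluded: singleton tail bins survive while
    empty ones are dropped, which otherwise flattens the fitted slope.  The
    regression is weighted by the Poisson variance of each bin's log density,
    which also yields a calibrated standard error for the exponent.
    """
    values = np.asarray(values, dtype=float)
    sample = values[values >= x_min]
    if sample.size < 20:
        raise ValueError(f"need at least 20 samples >= x_min (got {sample.size})")
    if tail_percentile is not None:
        sample = sample[sample <= np.percentile(sample, tail_percentile)]
    top = sample.max() * (1 + 1e-9)
    decades = np.log10(top / x_min)
    n_bins = max(int(np.ceil(bins_per_decade * decades)), 4)
    edges = np.logspace(np.log10(x_min), np.log10(top), n_bins + 1)
    counts, _ = np.histogram(sample, bins=edges)
    widths = np.diff(edges)
    keep = counts >= max(min_bin_count, 1)
    if keep.sum() < 3:
        raise ValueError("too few occupied bins for a power-law fit")
    density = counts[keep] / (widths[keep] * sample.size)
    centers = np.sqrt(edges[:-1] * edges[1:])[keep]

    X = np.log10(centers)
    Y = np.log10(density)
    # var(log10 N) ~ 1 / (N ln(10)^2) for Poisson bin counts
    w = counts[keep] * np.log(10.0) ** 2
    sw, sx, sy = w.sum(), (w * X).sum(), (w * Y).sum()
    sxx, sxy = (w * X * X).sum(), (w * X * Y).sum()
    denom = sw * sxx - sx * sx
    slope = (sw * sxy - sx * sy) / denom
    intercept = (sxx * sy - sx * sxy) / denom
    stderr = float(np.sqrt(sw / denom))
    return PowerLawFit(
        alpha=float(-slope),
        x_min=float(x_min),
        n_samples=int(sample.size),
        bin_edges=edges,
        fit_stderr=stderr,
        intercept=float(intercept),
    )
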