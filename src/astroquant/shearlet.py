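"""Discrete shearlet decomposition of 2D images and local feature densities.

Shearlets are anisotropic multiscale waveforms indexed by scale ``j``, shear
(orientation) ``k`` and shift; their coefficients localize oriented image
features.  This module implements a finite discrete transform in the Fourier
domain with Meyer-type cone-adapted windows: the frequency plane is split into
a low-pass disc, horizontal and vertical cones, and within each cone at scale
``j`` the shear index runs over ``k in [-2**j, 2**j]``, the two seam windows
on the diagonals being glued across the cones.  The window stack is
renormalized so that ``sum_k W_k**2 == 1`` at every frequency bin, giving a
Parseval (tight) frame: the adjoint reconstructs the image to machine
precision for any image size and scale count.

Squared coefficient magnitudes, smoothed with a scale-dependent Gaussian and
normalized per pixel, yield a local probability density over feature bands —
the input to the entropy/complexity mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.fft import fft2, ifft2
from scipy.ndimage import gaussian_filter

__all__ = [
    "ShearletSystem",
    "CoefficientStack",
    "FeatureDensity",
    "build_system",
    "transform",
    "inverse_transform",
    "local_power_density",
    "feature_count",
]


def _meyer_aux(x: np.ndarray) -> np.ndarray:
    """Meyer auxiliary polynomial: 0 at 0, 1 at 1, C^3 flat at both ends."""
    x = np.clip(x, 0.0, 1.0)
    return x**4 * (35.0 - 84.0 * x + 70.0 * x**2 - 20.0 * x**3)


def _fall(r: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Smooth 1 -> 0 taper over [lo, hi] (cosine of Meyer auxiliary)."""
    t = (r - lo) / (hi - lo)
    return np.cos(0.5 * np.pi * _meyer_aux(t))


def _bump(x: np.ndarray) -> np.ndarray:
    """Meyer bump on [-1, 1]; integer shifts of its square tile the line."""
    out = np.zeros_like(x, dtype=float)
    inside = np.abs(x) < 1.0
    out[inside] = np.cos(0.5 * np.pi * _meyer_aux(np.abs(x[inside])))
    return out


@dataclass
class ShearletSystem:
    """Frequency-domain window stack for one image geometry.

    feature_index labels each window: ``("lowpass", 0, 0)`` or
    ``(scale, cone, shear)`` with cone one of ``"h"``, ``"v"``, ``"d"``
    (seam windows on the diagonals, glued across both cones).
    """

    image_shape: tuple[int, int]
    n_scales: int
    shears_per_scale: list[int]
    frequency_windows: np.ndarray  # (K, N, N), real
    feature_index: list[tuple]
    includes_lowpass: bool = True

    @property
    def n_features(self) -> int:
        return len(self.feature_index)


@dataclass
class CoefficientStack:
    """K coefficient images, each the size of the analyzed image."""

    coefficients: np.ndarray  # (K, N, N)
    feature_index: list[tuple]
    system: ShearletSystem = field(repr=False)


@dataclass
class FeatureDensity:
    """Per-pixel normalized shearlet power over feature bands.

    ``P[k, y, x]`` is a probability over k at each pixel; ``E`` holds the
    smoothed band powers before normalization.  Pixels whose total power
    fell below the floor carry the uniform distribution and are flagged in
    ``uniform_fallback``.
    """

    P: np.ndarray
    E: np.ndarray
    smoothing_sigmas: np.ndarray
    feature_index: list[tuple]
    uniform_fallback: np.ndarray


def feature_count(n_scales: int, include_lowpass: bool = True) -> int:
    """Number of windows: 2**(j+2) orientations per scale j, plus lowpass."""
    n = sum(2 ** (j + 2) for j in range(n_scales))
    return n + (1 if include_lowpass else 0)


def build_system(image_shape: tuple[int, int], n_scales: int = 3) -> ShearletSystem:
    """Build the cone-adapted Meyer-type window stack for a square even-sized image.

    Radial bands halve in width per scale down from the Nyquist band; the
    finest band saturates to the grid corners so the windows cover the whole
    plane.  The assembled stack is divided by ``sqrt(sum_k W_k**2)`` so the
    tight-frame property holds exactly on the discrete grid.
    """
    if isinstance(image_shape, (int, np.integer)):
        image_shape = (int(image_shape), int(image_shape))
    ny, nx = image_shape
    if ny != nx:
        raise ValueError("image must be square (mirror-pad upstream)")
    if ny % 2 != 0:
        raise ValueError("image side must be even")
    if ny < 32:
        raise ValueError("image too small for a multiscale decomposition")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")

    N = ny
    f = np.fft.fftfreq(N)  # cycles / pixel in [-0.5, 0.5)
    fy = f[:, None] * np.ones((1, N))
    fx = np.ones((N, 1)) * f[None, :]
    r = np.hypot(fx, fy)

    # radial partition: lowpass cutoff c0, band j spans [c_j, 2*c_{j+1}]
    cuts = [0.25 * 2.0 ** (-(n_scales - 1 - j)) for j in range(n_scales)]
    low_prev = _fall(r, cuts[0], 2 * cuts[0])  # overall lowpass edge
    lowpass = low_prev.copy()

    # cone membership and shear coordinates; fx == 0 column goes to the v-cone
    with np.errstate(divide="ignore", invalid="ignore"):
        s_h = np.where(fx != 0, fy / np.where(fx != 0, fx, 1.0), np.inf)
        s_v = np.where(fy != 0, fx / np.where(fy != 0, fy, 1.0), 0.0)
    in_h = np.abs(fy) <= np.abs(fx)
    in_h &= r > 0
    in_v = (~in_h) & (r > 0)

    windows = [lowpass]
    labels: list[tuple] = [("lowpass", 0, 0)]
    shears_per_scale = []

    for j in range(n_scales):
        if j < n_scales - 1:
            low_next = _fall(r, cuts[j + 1], 2 * cuts[j + 1])
        else:
            low_next = np.ones_like(r)
        band = np.sqrt(np.clip(low_next**2 - low_prev**2, 0.0, None))
        low_prev = low_next

        m = 2**j
        shears_per_scale.append(m)
        uh = np.where(in_h, m * np.clip(s_h, -2.0, 2.0), np.nan)
        uv = np.where(in_v, m * np.clip(s_v, -2.0, 2.0), np.nan)

        # interior horizontal shears
        for k in range(-m + 1, m):
            w = band * np.where(in_h, _bump(np.nan_to_num(uh - k, nan=9.0)), 0.0)
            windows.append(w)
            labels.append((j, "h", k))
        # interior vertical shears
        for k in range(-m + 1, m):
            w = band * np.where(in_v, _bump(np.nan_to_num(uv - k, nan=9.0)), 0.0)
            windows.append(w)
            labels.append((j, "v", k))
        # seam shears on the diagonals, glued across the cones
        for k in (-m, m):
            wh = np.where(in_h, _bump(np.nan_to_num(uh - k, nan=9.0)), 0.0)
            wv = np.where(in_v, _bump(np.nan_to_num(uv - k, nan=9.0)), 0.0)
            windows.append(band * (wh + wv))
            labels.append((j, "d", k))

    W = np.stack(windows)
    # Symmetrize under frequency negation: the Nyquist row/column holds both
    # +0.5 and -0.5 cycles/px in one bin, which flips the shear coordinate
    # there.  Averaging squared windows with their mirror restores the exact
    # symmetry (so real images give real coefficients) without disturbing the
    # partition of unity.
    W2 = W**2
    W2m = np.roll(W2[:, ::-1, ::-1], (1, 1), axis=(1, 2))
    W = np.sqrt(0.5 * (W2 + W2m))
    total = np.sqrt((W**2).sum(axis=0))
    if not np.all(total > 1e-6):
        raise RuntimeError("frequency plane not fully covered by windows")
    W /= total

    return ShearletSystem(
        image_shape=(N, N),
        n_scales=n_scales,
        shears_per_scale=shears_per_scale,
        frequency_windows=W,
        feature_index=labels,
        includes_lowpass=True,
    )


def transform(image: np.ndarray, system: ShearletSystem) -> CoefficientStack:
    """Decompose an image into shearlet coefficient images by spectral windowing.

    Linear in the input; windows are symmetric under frequency negation so
    coefficients of a real image are real.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != system.image_shape:
        raise ValueError(
            f"image shape {image.shape} does not match system {system.image_shape}"
        )
    F = fft2(image)
    coeffs = np.real(ifft2(F[None, :, :] * system.frequency_windows, axes=(1, 2)))
    return CoefficientStack(
        coefficients=coeffs, feature_index=list(system.feature_index), system=system
    )


def inverse_transform(stack: CoefficientStack, system: ShearletSystem) -> np.ndarray:
    """Reconstruct the image from its coefficients via the frame adjoint."""
    if stack.system.image_shape != system.image_shape or len(
        stack.feature_index
    ) != len(system.feature_index):
        raise ValueError("coefficient stack does not match this system")
    C = fft2(stack.coefficients, axes=(1, 2))
    F = (C * system.frequency_windows).sum(axis=0)
    return np.real(ifft2(F))


def default_sigmas(system: ShearletSystem, base: float = 24.0) -> np.ndarray:
    """Scale-dependent smoothing widths: ``base`` px at the coarsest scale, halved per scale.

    The default is 1.5x the coarsest band's spatial correlation length
    (~16 px for the default radial partition): narrower kernels average too
    few independent coefficient samples, leaving spurious structure in the
    density even for featureless white-noise input.
    """
    return base * 2.0 ** (-np.arange(system.n_scales))


def local_power_density(
    stack: CoefficientStack,
    smoothing_sigmas=None,
    include_lowpass: bool = False,
    power_floor_frac: float = 1e-12,
) -> FeatureDensity:
    """Per-pixel normalized shearlet power P_k(x, y) = E_k / sum_i E_i.

    E_k is the squared coefficient magnitude convolved with a Gaussian whose
    width follows the band's scale, calibrated by the band's spectral area so
    that a flat-spectrum (white-noise) input yields equal expected power in
    every band: without this, the density would reflect band bandwidths
    rather than the image's own scale/orientation content.  The low-pass band
    encodes local offset, not oriented structure, and is excluded by default.
    Pixels whose total power is below ``power_floor_frac`` of the image mean
    power receive the uniform distribution (the ratio is undefined at a zero
    denominator).
    """
    system = stack.system
    if smoothing_sigmas is None:
        smoothing_sigmas = default_sigmas(system)
    smoothing_sigmas = np.asarray(smoothing_sigmas, dtype=float)
    if smoothing_sigmas.size != system.n_scales:
        raise ValueError("need one smoothing sigma per scale")
    if np.any(smoothing_sigmas <= 0):
        raise ValueError("smoothing sigmas must be positive")

    keep = [
        i
        for i, lab in enumerate(stack.feature_index)
        if include_lowpass or lab[0] != "lowpass"
    ]
    labels = [stack.feature_index[i] for i in keep]
    # spectral area of each band: expected coefficient power under white noise
    band_area = (system.frequency_windows**2).mean(axis=(1, 2))
    E = np.empty((len(keep), *system.image_shape))
    for out_i, i in enumerate(keep):
        lab = stack.feature_index[i]
        sigma = smoothing_sigmas[0] if lab[0] == "lowpass" else smoothing_sigmas[lab[0]]
        E[out_i] = gaussian_filter(
            stack.coefficients[i] ** 2 / band_area[i], sigma, mode="wrap"
        )

    total = E.sum(axis=0)
    floor = power_floor_frac * max(total.mean(), np.finfo(float).tiny)
    fallback = total <= floor
    safe_total = np.where(fallback, 1.0, total)
    P = E / safe_total
    if fallback.any():
        P[:, fallback] = 1.0 / len(keep)
    return FeatureDensity(
        P=P,
        E=E,
        smoothing_sigmas=smoothing_sigmas,
        feature_index=labels,
        uniform_fallback=fallback,
    )
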