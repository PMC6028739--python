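"""Branch masks, Sholl intersection profiles and leaflet volume fraction.

Morphometry of dye-filled astrocytes proceeds in three steps: (1) each plane
of the z-stack is smoothed with edge-preserving anisotropic diffusion, the
maximal projection is adaptively thresholded into a binary branch mask;
(2) the Sholl profile counts crossings of the mask with concentric circles of
increasing radius about the soma; (3) the leaflet volume fraction along a
line from the soma is estimated from fluorescence relative to the soma
(VF = 1 by assumption of a dye-filled excitation volume) and background
(VF = 0): GV = (F - F0) / (Fmax - F0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.measure import profile_line

__all__ = [
    "BranchMask",
    "ShollProfile",
    "VFProfile",
    "anisotropic_diffusion",
    "make_branch_mask",
    "sholl_profile",
    "vf_profile",
]


@dataclass
class BranchMask:
    mask: np.ndarray  # 2D bool
    soma_center: tuple[int, int]  # (y, x) pixels
    pixel_size: float  # um / pixel
    provenance: dict = field(default_factory=dict)
    empty: bool = False


@dataclass
class ShollProfile:
    radii: np.ndarray  # um
    intersections: np.ndarray  # count per radius
    metrics: dict = field(default_factory=dict)


@dataclass
class VFProfile:
    positions: np.ndarray  # um along the line
    GV: np.ndarray  # estimated volume fraction per position
    F_max: float
    F_0: float
    mean_leaflet_vf: float  # percent
    n_clipped: int = 0


def anisotropic_diffusion(
    image: np.ndarray, n_iter: int = 10, kappa_percentile: float = 90.0, dt: float = 0.15
) -> np.ndarray:
    """Perona-Malik edge-preserving diffusion with exponential conduction.

    The conduction scale is set from the given percentile of the initial
    gradient magnitude, so smoothing acts inside regions but stalls at
    branch edges.
    """
    u = np.asarray(image, dtype=float).copy()
    gy, gx = np.gradient(u)
    gmag = np.hypot(gy, gx)
    kappa = np.percentile(gmag[gmag > 0], kappa_percentile) if np.any(gmag > 0) else 1.0
    if kappa <= 0:
        kappa = 1.0
    for _ in range(n_iter):
        dn = np.roll(u, 1, 0) - u
        ds = np.roll(u, -1, 0) - u
        de = np.roll(u, -1, 1) - u
        dw = np.roll(u, 1, 1) - u
        u = u + dt * sum(np.exp(-((d / kappa) ** 2)) * d for d in (dn, ds, de, dw))
    return u


def make_branch_mask(
    z_stack: np.ndarray,
    soma_center: tuple[int, int] | None = None,
    pixel_size: float = 0.5,
    diffusion_iters: int = 10,
    block_size: int = 31,
    offset_frac: float = 0.05,
    min_object_px: int = 16,
) -> BranchMask:
    """Binary branch mask from a z-stack: diffusion, max projection, local threshold.

    Each XY plane is diffusion-filtered, the stack is max-projected, and the
    projection is thresholded against its local mean (31-px window) minus a
    small negative offset so flat regions — background and sub-resolution
    leaflet haze — fall below threshold.  Small specks are removed and holes
    (e.g. inside the uniformly bright soma) filled.
    """
    z_stack = np.asarray(z_stack, dtype=float)
    if z_stack.ndim == 2:
        z_stack = z_stack[None]
    if z_stack.shape[0] < 1:
        raise ValueError("stack must have at least one plane")

    filtered = np.stack([anisotropic_diffusion(pl, diffusion_iters) for pl in z_stack])
    proj = filtered.max(axis=0)

    rng_int = float(proj.max() - proj.min())
    empty = False
    if rng_int <= 0:
        mask = np.zeros(proj.shape, dtype=bool)
        empty = True
    else:
        offset = -offset_frac * rng_int  # push threshold above flat regions
        thresh = threshold_local(proj, block_size=block_size, method="mean", offset=offset)
        mask = proj > thresh
        labels, n_lab = ndimage.label(mask)
        if n_lab:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_lab + 1))
            small = np.flatnonzero(sizes < min_object_px) + 1
            mask[np.isin(labels, small)] = False
        mask = ndimage.binary_fill_holes(mask)
        if not mask.any():
            empty = True

    if soma_center is None:
        soma_center = tuple(int(v) for v in np.unravel_index(np.argmax(proj), proj.shape))
    return BranchMask(
        mask=mask,
        soma_center=(int(soma_center[0]), int(soma_center[1])),
        pixel_size=pixel_size,
        provenance={
            "diffusion_iters": diffusion_iters,
            "threshold_method": "local-mean",
            "block_size": block_size,
            "offset_frac": offset_frac,
        },
        empty=empty,
    )


def _circle_crossings(mask: np.ndarray, cy: int, cx: int, r_px: float) -> int:
    """Count distinct foreground runs along a discretized circle of radius r_px.

    The circle is sampled densely in angle, consecutive duplicate pixels are
    merged (run-length merging, so thick branches count once), and the number
    of background-to-foreground transitions is counted with circular
    wrap-around.  A circle lying entirely in foreground counts one.
    """
    h, w = mask.shape
    m = max(int(np.ceil(4 * np.pi * r_px)), 16)
    ang = np.linspace(0.0, 2 * np.pi, m, endpoint=False)
    ys = np.round(cy + r_px * np.sin(ang)).astype(int)
    xs = np.round(cx + r_px * np.cos(ang)).astype(int)
    inside = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    vals = np.zeros(m, dtype=bool)
    vals[inside] = mask[ys[inside], xs[inside]]
    # merge consecutive duplicate pixels
    keep = np.ones(m, dtype=bool)
    keep[1:] = (ys[1:] != ys[:-1]) | (xs[1:] != xs[:-1])
    vals = vals[keep]
    if vals.size == 0:
        return 0
    if vals.all():
        return 1
    transitions = int((vals & ~np.roll(vals, 1)).sum())
    return transitions


def sholl_profile(branch_mask: BranchMask, step_um: float = 2.0) -> ShollProfile:
    """Sholl profile: circle/mask intersection counts at increasing radii.

    Derived metrics: ``n_primary`` — the count at the first radius past the
    soma boundary (the first circle not fully contained in the soma's
    foreground blob); ``peak_count``; ``enclosing_radius_um`` — the largest
    radius with a nonzero count; ``distal_counts`` — counts at radii beyond
    the profile peak.
    """
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    mask = branch_mask.mask
    cy, cx = branch_mask.soma_center
    px = branch_mask.pixel_size
    if not mask.any():
        radii = np.arange(step_um, max(mask.shape) * px / 2, step_um)
        return ShollProfile(
            radii=radii,
            intersections=np.zeros(radii.size, dtype=int),
            metrics={
                "n_primary": 0,
                "peak_count": 0,
                "enclosing_radius_um": 0.0,
                "distal_counts": [],
            },
        )
    if not (0 <= cy < mask.shape[0] and 0 <= cx < mask.shape[1]) or not mask[cy, cx]:
        raise ValueError("soma center does not lie on the foreground mask")

    # soma blob: connected component containing the soma center
    labels, _ = ndimage.label(mask)
    soma_label = labels[cy, cx]

    h, w = mask.shape
    r_max_px = min(
        np.hypot(*np.maximum([cy, cx], [h - 1 - cy, w - 1 - cx])), np.hypot(h, w)
    )
    radii_um = np.arange(step_um, r_max_px * px, step_um)
    counts = np.zeros(radii_um.size, dtype=int)
    soma_boundary_idx = None
    for i, r_um in enumerate(radii_um):
        r_px = r_um / px
        counts[i] = _circle_crossings(mask, cy, cx, r_px)
        if soma_boundary_idx is None:
            # circle fully inside the soma blob?
            m = max(int(np.ceil(4 * np.pi * r_px)), 16)
            ang = np.linspace(0.0, 2 * np.pi, m, endpoint=False)
            ys = np.round(cy + r_px * np.sin(ang)).astype(int)
            xs = np.round(cx + r_px * np.cos(ang)).astype(int)
            ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
            if not ok.all() or not np.all(labels[ys[ok], xs[ok]] == soma_label):
                soma_boundary_idx = i

    nonzero = np.nonzero(counts)[0]
    enclosing = float(radii_um[nonzero[-1]]) if nonzero.size else 0.0
    if soma_boundary_idx is None or nonzero.size == 0:
        n_primary = 0
        first_branch_idx = counts.size
    else:
        # the circle at the boundary radius itself rides the jagged soma
        # edge; branch metrics are read from one step further out
        first_branch_idx = min(soma_boundary_idx + 1, counts.size - 1)
        n_primary = int(counts[first_branch_idx])
    branch_counts = counts[first_branch_idx:]
    peak_rel = int(np.argmax(branch_counts)) if branch_counts.size else 0
    peak_idx = first_branch_idx + peak_rel
    metrics = {
        "n_primary": n_primary,
        "peak_count": int(branch_counts.max()) if branch_counts.size else 0,
        "enclosing_radius_um": enclosing,
        "distal_counts": counts[peak_idx + 1 :].tolist(),
    }
    return ShollProfile(radii=radii_um, intersections=counts, metrics=metrics)


def vf_profile(
    plane: np.ndarray,
    line_endpoints,
    soma_roi: np.ndarray,
    background_roi: np.ndarray,
    pixel_size: float = 0.5,
    expected_length_um: float | None = 45.0,
    branch_intervals_um: list[tuple[float, float]] | None = None,
    soma_gv_threshold: float = 0.5,
    detector_ceiling: float | None = None,
) -> VFProfile:
    """Leaflet volume fraction along a line from the soma on a single z-plane.

    ``GV = (F - F0) / (Fmax - F0)`` with ``Fmax`` the mean soma fluorescence
    (unsaturated, VF = 100 %) and ``F0`` the mean over a background region
    with no stained astrocytes (VF = 0).  The mean leaflet VF (in percent)
    averages GV over line positions outside the soma (initial contiguous run
    with GV above ``soma_gv_threshold``) and outside any user-marked branch
    intervals.
    """
    plane = np.asarray(plane, dtype=float)
    (y0, x0), (y1, x1) = line_endpoints
    length_um = float(np.hypot(y1 - y0, x1 - x0)) * pixel_size
    if expected_length_um is not None and abs(length_um - expected_length_um) > 1.0:
        raise ValueError(
            f"line length {length_um:.1f} um differs from the configured "
            f"{expected_length_um} um"
        )
    if detector_ceiling is not None and plane[np.asarray(soma_roi, bool)].max() >= detector_ceiling:
        raise ValueError("soma fluorescence saturated; VF calibration invalid")

    f_max = float(plane[np.asarray(soma_roi, dtype=bool)].mean())
    f_0 = float(plane[np.asarray(background_roi, dtype=bool)].mean())
    if f_max <= f_0:
        raise ValueError("degenerate calibration: soma not brighter than background")

    prof = profile_line(plane, (y0, x0), (y1, x1), linewidth=1, mode="constant")
    positions = np.arange(prof.size) * length_um / max(prof.size - 1, 1)
    gv = (prof - f_0) / (f_max - f_0)
    n_clipped = int(((gv < 0) | (gv > 1)).sum())
    gv = np.clip(gv, 0.0, 1.0)

    exclude = np.zeros(gv.size, dtype=bool)
    i = 0
    while i < gv.size and gv[i] >= soma_gv_threshold:  # initial soma run
        exclude[i] = True
        i += 1
    for lo, hi in branch_intervals_um or []:
        exclude |= (positions >= lo) & (positions <= hi)
    leaflet = gv[~exclude]
    mean_vf = float(leaflet.mean() * 100.0) if leaflet.size else float("nan")
    return VFProfile(
        positions=positions,
        GV=gv,
        F_max=f_max,
        F_0=f_0,
        mean_leaflet_vf=mean_vf,
        n_clipped=n_clipped,
    )
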