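"""Branch masks, Sholl profiles and volume-fraction estimation."""

import numpy as np
import pytest

from astroquant import morphometry, synthetic
from astroquant.morphometry import BranchMask, make_branch_mask, sholl_profile, vf_profile


def _mask_from_astro(astro):
    return make_branch_mask(
        astro.image_stack,
        soma_center=astro.soma_center[1:],
        pixel_size=astro.pixel_size,
    )


def test_mask_covers_planted_ray_skeleton():
    """The thresholded mask recovers >= 95 % of the true ray skeleton."""
    astro = synthetic.gen_astrocyte(seed=0)
    bm = _mask_from_astro(astro)
    _, cy, cx = astro.soma_center
    px = astro.pixel_size
    ray_len = astro.truth["ray_lengths"][0] / px
    covered = total = 0
    from scipy.ndimage import binary_dilation

    dil = binary_dilation(bm.mask)
    for ang in astro.truth["ray_angles"]:
        for t in np.linspace(0.05, 0.98, 60):
            y = int(round(cy + ray_len * t * np.sin(ang)))
            x = int(round(cx + ray_len * t * np.cos(ang)))
            total += 1
            covered += bool(dil[y, x])
    assert covered / total >= 0.95


def test_zero_stack_gives_flagged_empty_mask():
    bm = make_branch_mask(np.zeros((3, 64, 64)))
    assert bm.empty and not bm.mask.any()


def test_mask_is_deterministic():
    astro = synthetic.gen_astrocyte({"noise_sd": 0.02}, seed=1)
    m1 = _mask_from_astro(astro).mask
    m2 = _mask_from_astro(astro).mask
    assert np.array_equal(m1, m2)


@pytest.mark.parametrize("n_rays", [3, 6])
def test_star_counts_match_ray_circle_oracle(n_rays):
    """n straight rays cross every circle inside their length exactly n times."""
    astro = synthetic.gen_astrocyte({"n_rays": n_rays}, seed=0)
    prof = sholl_profile(_mask_from_astro(astro))
    inside = (prof.radii > astro.truth["soma_radius_um"] + 2) & (
        prof.radii < astro.truth["ray_lengths"][0] - 2
    )
    assert np.all(prof.intersections[inside] == n_rays)
    assert prof.metrics["n_primary"] == n_rays
    assert prof.metrics["enclosing_radius_um"] >= astro.truth["ray_lengths"][0] - 2


def test_empty_mask_profile_is_all_zero():
    bm = BranchMask(mask=np.zeros((64, 64), bool), soma_center=(32, 32), pixel_size=0.5)
    prof = sholl_profile(bm)
    assert not prof.intersections.any()
    assert prof.metrics["enclosing_radius_um"] == 0.0


def test_soma_off_mask_rejected():
    mask = np.zeros((64, 64), bool)
    mask[10:20, 10:20] = True
    bm = BranchMask(mask=mask, soma_center=(50, 50), pixel_size=0.5)
    with pytest.raises(ValueError):
        sholl_profile(bm)


def test_bifurcation_steps_from_one_to_two():
    """A single ray splitting at 20 um doubles the crossing count there."""
    n = 240
    cy = cx = 120
    mask = np.zeros((n, n), bool)
    mask[cy - 4 : cy + 5, cx - 4 : cx + 5] = True
    for i in range(40):  # trunk to 20 um (0.5 um/px)
        mask[cy : cy + 2, cx + i] = True
    for i in range(40, 90):  # branches at +-45 degrees
        d = i - 40
        mask[cy + d : cy + d + 2, cx + i] = True
        mask[cy - d : cy - d + 2, cx + i] = True
    prof = sholl_profile(BranchMask(mask=mask, soma_center=(cy, cx), pixel_size=0.5))
    before = (prof.radii > 4) & (prof.radii < 19)
    after = (prof.radii > 24) & (prof.radii < 40)
    assert np.all(prof.intersections[before] == 1)
    assert np.all(prof.intersections[after] == 2)


def test_counts_invariant_to_cell_rotation():
    """Rigidly rotating the planted cell about its soma leaves Sholl counts within +-1."""
    base = synthetic.gen_astrocyte({"n_rays": 5}, seed=3)
    rotated = synthetic.gen_astrocyte({"n_rays": 5, "angle_offset": 0.31}, seed=3)
    prof_a = sholl_profile(_mask_from_astro(base))
    prof_b = sholl_profile(_mask_from_astro(rotated))
    n = min(prof_a.intersections.size, prof_b.intersections.size)
    assert np.abs(prof_a.intersections[:n] - prof_b.intersections[:n]).max() <= 1


def test_micron_metrics_independent_of_pixel_size():
    p1 = sholl_profile(_mask_from_astro(synthetic.gen_astrocyte({"pixel_size": 0.5}, 0)))
    p2 = sholl_profile(_mask_from_astro(synthetic.gen_astrocyte({"pixel_size": 1.0}, 0)))
    assert abs(
        p1.metrics["enclosing_radius_um"] - p2.metrics["enclosing_radius_um"]
    ) <= 4.0
    assert p1.metrics["n_primary"] == p2.metrics["n_primary"]


# --- volume fraction -------------------------------------------------------


def _vf_fixture(leaflet_vf=0.034, seed=1):
    astro = synthetic.gen_astrocyte({"leaflet_vf": leaflet_vf}, seed=seed)
    plane = astro.image_stack[astro.soma_center[0]]
    _, cy, cx = astro.soma_center
    px = astro.pixel_size
    yy, xx = np.mgrid[0 : plane.shape[0], 0 : plane.shape[1]]
    r = np.hypot(yy - cy, xx - cx) * px
    soma_roi = r <= astro.truth["soma_radius_um"] * 0.8
    bg_roi = r >= astro.truth["domain_radius_um"] + 5.0
    angles = sorted(astro.truth["ray_angles"])
    mid = (angles[0] + angles[1]) / 2.0
    L = 45.0 / px
    end = (cy + L * np.sin(mid), cx + L * np.cos(mid))
    return astro, plane, ((cy, cx), end), soma_roi, bg_roi


def test_gv_endpoints_are_exact():
    """GV is 1 at soma fluorescence and 0 at background fluorescence."""
    _, plane, line, soma, bg = _vf_fixture()
    prof = vf_profile(plane, line, soma, bg, pixel_size=0.5)
    assert prof.GV[0] == pytest.approx(1.0, abs=1e-9)  # line starts in the soma
    # constructed plane: pixels at exactly F_max and F0 map to 1 and 0
    flat = np.full((60, 120), 7.0)
    flat[20:30, 10:30] = 50.0
    soma2 = np.zeros_like(flat, bool)
    soma2[20:30, 10:30] = True
    bg2 = np.zeros_like(flat, bool)
    bg2[40:50, 80:110] = True
    line2 = ((25, 12), (25, 102))  # 90 px * 0.5 um = 45 um
    p2 = vf_profile(flat, line2, soma2, bg2, pixel_size=0.5)
    assert p2.GV[0] == pytest.approx(1.0, abs=1e-12)  # F == F_max
    assert p2.GV[-1] == pytest.approx(0.0, abs=1e-12)  # F == F0


def test_vf_recovers_planted_fraction():
    astro, plane, line, soma, bg = _vf_fixture(leaflet_vf=0.034)
    prof = vf_profile(plane, line, soma, bg, pixel_size=0.5)
    assert prof.mean_leaflet_vf == pytest.approx(3.4, abs=0.3)


def test_vf_invariant_to_affine_intensity_rescaling():
    _, plane, line, soma, bg = _vf_fixture()
    p1 = vf_profile(plane, line, soma, bg, pixel_size=0.5)
    p2 = vf_profile(7.0 * plane + 40.0, line, soma, bg, pixel_size=0.5)
    assert np.allclose(p1.GV, p2.GV, atol=1e-9)
    assert p1.mean_leaflet_vf == pytest.approx(p2.mean_leaflet_vf, abs=1e-9)


def test_vf_degenerate_calibration_rejected():
    _, plane, line, soma, bg = _vf_fixture()
    with pytest.raises(ValueError):
        vf_profile(plane, line, bg, bg, pixel_size=0.5)  # soma ROI on background
    with pytest.raises(ValueError):
        vf_profile(plane, line, soma, bg, pixel_size=0.5, detector_ceiling=0.5)


def test_vf_line_length_checked():
    _, plane, (start, _), soma, bg = _vf_fixture()
    short = (start, (start[0] + 10, start[1]))
    with pytest.raises(ValueError):
        vf_profile(plane, short, soma, bg, pixel_size=0.5)
    # configurable off
    prof = vf_profile(plane, short, soma, bg, pixel_size=0.5, expected_length_um=None)
    assert np.isfinite(prof.F_max)
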