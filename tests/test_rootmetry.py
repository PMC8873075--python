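"""Deterministic aortic-root measurements."""

import numpy as np
import pytest

from aorticroot.geometry import Plane, rotation_from_tilt
from aorticroot.phantom import PhantomParams, generate_cylinder, generate_phantom
from aorticroot.rootmetry import (
    DiameterProfile,
    calcification_volume,
    combine_valve_region,
    mean_absolute_error,
    minimal_diameter,
    reference_diameter,
    slice_diameter_profile,
    suggest_device_size,
)
from aorticroot.volume_io import Mask

Z_PLANE = Plane(np.zeros(3), np.array([0.0, 0.0, 1.0]))


# -- profile -----------------------------------------------------------------

def test_cylinder_profile_within_one_voxel_of_analytic():
    _, mask = generate_cylinder(12.0, (0, 0, 1), 30.0, 0.6)
    prof = slice_diameter_profile(mask, Z_PLANE, step_mm=0.6)
    mid = np.abs(prof.offsets_mm) <= 12.0
    assert np.all(np.abs(prof.diameters_mm[mid] - 24.0) <= 1.2)


def test_profile_rotation_invariance():
    axis = rotation_from_tilt((20.0, 0.0)) @ np.array([0, 0, 1.0])
    _, m0 = generate_cylinder(12.0, (0, 0, 1), 30.0, 0.6)
    _, m1 = generate_cylinder(12.0, axis, 30.0, 0.6)
    p0 = slice_diameter_profile(m0, Z_PLANE, 0.6)
    p1 = slice_diameter_profile(m1, Plane(np.zeros(3), axis), 0.6)
    d0 = p0.diameters_mm[np.abs(p0.offsets_mm) <= 10].mean()
    d1 = p1.diameters_mm[np.abs(p1.offsets_mm) <= 10].mean()
    assert abs(d0 - d1) <= 0.6  # one voxel spacing


def test_single_voxel_slab_uses_degenerate_rule():
    m = np.zeros((9, 9, 9), dtype=np.uint8)
    m[4, 4, 4] = 1
    mask = Mask(m, (1.0,) * 3, (-4.0, -4.0, -4.0))
    prof = slice_diameter_profile(mask, Z_PLANE, step_mm=1.0)
    assert len(prof.offsets_mm) == 1
    assert prof.diameters_mm[0] == pytest.approx(2 * np.sqrt(1.0 / np.pi), rel=1e-6)


def test_hull_diameter_at_least_pixel_count_diameter():
    rng = np.random.default_rng(8)
    m = np.zeros((20, 20, 3), dtype=np.uint8)
    m[rng.integers(2, 18, 40), rng.integers(2, 18, 40), 1] = 1
    mask = Mask(m, (1.0,) * 3, (0.0, 0.0, -1.0))
    prof = slice_diameter_profile(mask, Z_PLANE, step_mm=1.0)
    count = int(m[:, :, 1].sum())
    d_pixels = 2 * np.sqrt(count * 1.0 / np.pi)
    sel = prof.offsets_mm == 0.0
    assert prof.diameters_mm[sel][0] >= d_pixels


def test_profile_validation():
    with pytest.raises(ValueError):
        DiameterProfile(np.array([0.0, 0.0]), np.array([20.0, 21.0]))  # not increasing
    with pytest.raises(ValueError):
        DiameterProfile(np.array([0.0]), np.array([-1.0]))


# -- minimal diameter and floor ---------------------------------------------

def test_minimal_diameter_floor_rule():
    prof = DiameterProfile(np.array([-1.0, 0.0, 1.0, 2.0]), np.array([20.0, 18.0, 16.0, 19.0]))
    assert minimal_diameter(prof) == 18.0
    const = DiameterProfile(np.array([0.0, 1.0, 2.0]), np.array([24.0, 24.0, 24.0]))
    assert minimal_diameter(const) == 24.0
    low = DiameterProfile(np.array([0.0, 1.0]), np.array([15.0, 15.0]))
    with pytest.raises(ValueError, match="no valid annulus diameter"):
        minimal_diameter(low)


# -- combined valve region ---------------------------------------------------

def test_combine_valve_region_set_algebra():
    _, cyl = generate_cylinder(10.0, (0, 0, 1), 40.0, 1.0)
    ann = np.zeros_like(cyl.values)
    ann[:, :, cyl.shape[2] // 2] = cyl.values[:, :, cyl.shape[2] // 2]
    annulus = Mask(ann, cyl.spacing, cyl.origin)
    out = combine_valve_region(cyl, annulus, Z_PLANE, height_mm=10.0)
    assert np.all(out.values[annulus.values > 0] == 1)  # union contains annulus
    # analytic slab volume: pi r^2 h
    assert out.volume_mm3() == pytest.approx(np.pi * 100.0 * 10.0, rel=0.05)
    far_plane = Plane(np.array([0.0, 0.0, 500.0]), np.array([0, 0, 1.0]))
    with pytest.raises(ValueError):
        combine_valve_region(cyl, annulus, far_plane)


# -- reference diameter ------------------------------------------------------

def test_reference_diameter_recovers_truth_and_respects_range(small_phantom):
    _, truth = small_phantom
    d = reference_diameter(truth.root_lvot_mask, truth.hinge_points)
    assert abs(d - truth.true_annulus_diameter_mm) <= 2 * max(truth.root_lvot_mask.spacing)
    # displacing the plane 20 mm along the axis leaves the waist outside the
    # +/-5 mm window, so the measured minimum must exceed the true diameter
    shifted = truth.hinge_points + 20.0 * truth.true_plane.normal
    d_shifted = reference_diameter(truth.root_lvot_mask, shifted)
    assert d_shifted > truth.true_annulus_diameter_mm
    empty = Mask(np.zeros((10, 10, 10), np.uint8), (1.0,) * 3, (0.0,) * 3)
    with pytest.raises(ValueError):
        reference_diameter(empty, truth.hinge_points)


# -- device sizing -----------------------------------------------------------

@pytest.mark.parametrize(
    "d,size",
    [
        (17.5, 20), (19.4, 20), (19.5, 23), (21.0, 23), (22.4, 23),
        (22.5, 26), (24.0, 26), (26.4, 26), (26.5, 29), (28.0, 29),
        (29.4, 29), (29.5, 34), (31.0, 34),
    ],
)
def test_sizing_bands_half_open(d, size):
    assert suggest_device_size(d) == size


def test_sizing_monotone_total_step_function():
    grid = np.arange(10.0, 40.0, 0.1)
    sizes = [suggest_device_size(d) for d in grid]
    assert all(b >= a for a, b in zip(sizes, sizes[1:]))
    assert set(sizes) == {20, 23, 26, 29, 34}
    with pytest.raises(ValueError):
        suggest_device_size(0.0)


# -- calcification -----------------------------------------------------------

def test_calcification_volume_bookkeeping():
    fast = dict(spacing_mm=(1.2,) * 3, extent_mm=(96.0, 96.0, 120.0))
    p = PhantomParams(noise_sd=0.0, calcification_blobs=2, seed=9, **fast)
    vol, truth = generate_phantom(p)
    whole = Mask(np.ones(vol.shape, np.uint8), vol.spacing, vol.origin)
    v = calcification_volume(vol, whole)
    assert v == pytest.approx(truth.calcium_voxel_count * vol.voxel_volume_mm3())
    assert calcification_volume(vol, whole, threshold_hu=2000.0) == 0.0
    p0 = PhantomParams(noise_sd=0.0, calcification_blobs=0, **fast)
    vol0, _ = generate_phantom(p0)
    whole0 = Mask(np.ones(vol0.shape, np.uint8), vol0.spacing, vol0.origin)
    assert calcification_volume(vol0, whole0) == 0.0


def test_calcification_rejects_normalized_input():
    vol, _ = generate_phantom(PhantomParams(spacing_mm=(2.0,) * 3, extent_mm=(96, 96, 120)))
    from aorticroot.volume_io import normalize_intensity

    norm = normalize_intensity(vol)
    whole = Mask(np.ones(norm.shape, np.uint8), norm.spacing, norm.origin)
    with pytest.raises(ValueError, match="normalized"):
        calcification_volume(norm, whole)


# -- mean absolute error -----------------------------------------------------

def test_mean_absolute_error():
    assert mean_absolute_error([24.0, 22.0], [22.0, 23.0]) == 1.5
    assert mean_absolute_error([21.0], [19.5]) == 1.5
    assert mean_absolute_error([3.0, 3.0], [3.0, 3.0]) == 0.0
    with pytest.raises(ValueError):
        mean_absolute_error([1.0], [1.0, 2.0])
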