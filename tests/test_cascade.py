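"""Cascade label generation, postprocessing and orchestration."""

import numpy as np
import pytest
from scipy import ndimage

from aorticroot import cascade as csc
from aorticroot.geometry import Plane, rotation_from_tilt
from aorticroot.phantom import PhantomParams, generate_cylinder, generate_phantom
from aorticroot.volume_io import BoundingBoxMM, Mask, Volume, crop_to_box


@pytest.fixture(scope="module")
def phantom_case():
    params = PhantomParams(
        noise_sd=0.0, spacing_mm=(1.2,) * 3, extent_mm=(96.0, 96.0, 120.0), seed=4
    )
    return generate_phantom(params)


# -- step 1 label and box ----------------------------------------------------

def test_roi_label_is_80mm_cube(phantom_case):
    vol, truth = phantom_case
    mask = csc.make_roi_label(truth.hinge_points, vol)
    idx = np.argwhere(mask.values > 0)
    span = (idx.max(axis=0) - idx.min(axis=0) + 1) * vol.spacing
    assert np.all(np.abs(span - 80.0) <= 2 * vol.spacing)
    count = mask.voxel_count() * vol.voxel_volume_mm3()
    assert count == pytest.approx(80.0**3, rel=0.1)


def test_roi_label_rejects_collinear_hinges(phantom_case):
    vol, _ = phantom_case
    bad = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
    with pytest.raises(ValueError):
        csc.make_roi_label(bad, vol)


def test_extract_roi_box_center_arithmetic():
    grid = Volume(np.zeros((61, 41, 41), dtype=np.float32), (1.0,) * 3, (0.0, 0.0, 0.0))
    v = grid.values.copy()
    v[0, 0, 0] = 1.0
    v[40, 0, 0] = 1.0  # blobs at (0,0,0) and (40,0,0) mm
    box = csc.extract_roi_box(grid.with_values(v))
    assert np.allclose(box.center_mm, (20.0, 0.0, 0.0))
    assert np.allclose(box.extents_mm, 80.0)  # always exactly 80 mm


def test_extract_roi_box_empty_raises_roi_not_found():
    grid = Volume(np.zeros((10, 10, 10), dtype=np.float32), (2.0,) * 3, (0.0,) * 3)
    with pytest.raises(csc.CascadeError, match="ROI not found"):
        csc.extract_roi_box(grid)


# -- step 2/3 labels ---------------------------------------------------------

def test_aorta_label_clips_to_roi(phantom_case):
    _, truth = phantom_case
    center = truth.hinge_points.mean(axis=0)
    roi = BoundingBoxMM(center, (40.0, 40.0, 40.0))
    lab = csc.make_aorta_label(truth.aorta_mask, roi, spacing_mm=1.2)
    assert set(np.unique(lab.values)) <= {0, 1}
    # overlap oracle: count lumen voxels whose centers fall inside the box
    idx = np.argwhere(truth.aorta_mask.values > 0)
    pts = truth.aorta_mask.index_to_mm(idx)
    inside = np.all(np.abs(pts - center) <= 20.0, axis=1).sum()
    assert lab.voxel_count() == pytest.approx(inside, rel=0.1)
    far = BoundingBoxMM(center + 300.0, (40.0,) * 3)
    with pytest.raises(ValueError):
        csc.make_aorta_label(truth.aorta_mask, far, spacing_mm=1.2)


def test_annulus_label_is_centered_slab():
    _, cyl = generate_cylinder(12.0, (0, 0, 1), 40.0, 1.0)
    hinges = np.array([[12.0, 0, 0], [-6.0, 10.39, 0], [-6.0, -10.39, 0]])
    lab = csc.make_annulus_label(cyl, hinges)
    z = np.argwhere(lab.values > 0)[:, 2]
    layers = z.max() - z.min() + 1
    assert abs(layers - 10) <= 1  # 10 mm slab at 1 mm spacing
    centroid_mm = lab.index_to_mm(np.argwhere(lab.values > 0)).mean(axis=0)
    assert abs(centroid_mm[2]) <= 1.0  # centered on the hinge plane
    far = hinges + np.array([0.0, 0.0, 500.0])
    with pytest.raises(ValueError):
        csc.make_annulus_label(cyl, far)


# -- contour masking ---------------------------------------------------------

def test_contour_masking_keeps_shell_adjacent_voxels():
    _, cyl = generate_cylinder(10.0, (0, 0, 1), 30.0, 1.0)
    annulus = Mask(cyl.values.copy(), cyl.spacing, cyl.origin)  # solid interior
    out = csc.mask_with_aorta_contour(annulus, cyl)
    a = cyl.values > 0
    shell = ndimage.binary_dilation(a & ~ndimage.binary_erosion(a))  # morphology oracle
    assert np.array_equal(out.values > 0, (annulus.values > 0) & shell)
    assert out.voxel_count() < annulus.voxel_count()


def test_contour_masking_keeps_largest_component():
    a = np.zeros((30, 30, 30), dtype=np.uint8)
    a[5:25, 5:25, 5:25] = 1
    aorta = Mask(a, (1.0,) * 3, (0.0,) * 3)
    ann = np.zeros_like(a)
    ann[5, 5:15, 5:15] = 1  # 100 voxels on the shell
    ann[24, 5:7, 5:10] = 1  # 10 voxels, disjoint
    out = csc.mask_with_aorta_contour(Mask(ann, (1.0,) * 3, (0.0,) * 3), aorta)
    assert out.voxel_count() == 100


def test_contour_masking_falls_back_when_empty(caplog):
    ann = np.zeros((10, 10, 10), dtype=np.uint8)
    ann[4:6, 4:6, 4:6] = 1
    annulus = Mask(ann, (1.0,) * 3, (0.0,) * 3)
    empty = Mask(np.zeros_like(ann), (1.0,) * 3, (0.0,) * 3)
    with caplog.at_level("WARNING"):
        out = csc.mask_with_aorta_contour(annulus, empty)
    assert np.array_equal(out.values, annulus.values)
    assert "falling back" in caplog.text


# -- PCA plane ---------------------------------------------------------------

def test_pca_plane_axis_aligned_disk():
    _, disk = generate_cylinder(15.0, (0, 0, 1), 4.0, 0.6)
    plane = csc.infer_annulus_plane(disk)
    assert np.allclose(plane.normal, (0, 0, 1), atol=1e-6)


def test_pca_plane_rotated_disk_within_one_degree():
    axis = rotation_from_tilt((30.0, 0.0)) @ np.array([0, 0, 1.0])
    _, disk = generate_cylinder(15.0, axis, 4.0, 0.6)
    plane = csc.infer_annulus_plane(disk)
    assert plane.angle_to(Plane(np.zeros(3), axis)) < 1.0


def test_pca_plane_sphere_is_ill_conditioned():
    g = np.stack(np.meshgrid(*[np.arange(20)] * 3, indexing="ij"), -1)
    sphere = (np.linalg.norm(g - 9.5, axis=-1) <= 8).astype(np.uint8)
    with pytest.warns(UserWarning, match="ill-conditioned"):
        csc.infer_annulus_plane(Mask(sphere, (1.0,) * 3, (0.0,) * 3))
    with pytest.raises(ValueError):
        csc.infer_annulus_plane(Mask(np.zeros((5, 5, 5), np.uint8), (1.0,) * 3, (0.0,) * 3))


# -- hinge plane -------------------------------------------------------------

def test_hinge_plane_basics():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float) * 10
    plane = csc.hinge_plane(pts)
    assert np.allclose(plane.normal, (0, 0, 1))  # HEAD-oriented
    assert np.allclose(plane.midpoint_mm, pts.mean(axis=0))
    shifted = csc.hinge_plane(pts + [5.0, -3.0, 2.0])
    assert np.allclose(shifted.midpoint_mm, plane.midpoint_mm + [5.0, -3.0, 2.0])
    with pytest.raises(ValueError):
        csc.hinge_plane(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float))


def test_hinge_plane_matches_phantom_axis(phantom_case):
    _, truth = phantom_case
    plane = csc.hinge_plane(truth.hinge_points)
    assert plane.angle_to(truth.true_plane) < 0.5


# -- orchestration with truth-backed oracle models ---------------------------

class _OracleModel:
    """Stands in for a trained network: predicts from stored phantom truth.

    step 1 -> the 80 mm ROI-cube label; step 2 -> the aortic lumen;
    step 3 -> the 10 mm annulus slab.  Deterministic by construction, so it
    exercises the full postprocessing and measurement chain in isolation
    from network quality.
    """

    def __init__(self, truth, step, spacing):
        self.truth, self.step, self.spacing = truth, step, spacing

    def predict(self, vol):
        t = self.truth
        if self.step == 1:
            out = csc.make_roi_label(t.hinge_points, vol)
        elif self.step == 2:
            out = crop_to_box(t.aorta_mask, _grid_box(vol), self.spacing, mode="label")
        else:
            root = crop_to_box(t.root_lvot_mask, _grid_box(vol), self.spacing, mode="label")
            out = csc.make_annulus_label(root, t.hinge_points)
        return vol.with_values(out.values.astype(np.float32))


def _grid_box(vol):
    return BoundingBoxMM(vol.center_mm, vol.extent_mm)


def test_run_cascade_with_oracle_models_recovers_truth(phantom_case):
    vol, truth = phantom_case
    sp = 1.2
    ensembles = {f"step{s}": _OracleModel(truth, s, sp) for s in (1, 2, 3)}
    opts = csc.CascadeOptions(detection_spacing_mm=2.4, roi_spacing_mm=sp)
    res = csc.run_cascade(vol, ensembles, opts)
    assert res.plane.angle_to(truth.true_plane) < 1.5
    assert abs(res.annulus_diameter_mm - truth.true_annulus_diameter_mm) <= 2 * sp
    # deterministic rerun
    res2 = csc.run_cascade(vol, ensembles, opts)
    assert res2.annulus_diameter_mm == res.annulus_diameter_mm
    assert np.array_equal(res2.aorta_mask.values, res.aorta_mask.values)


def test_run_cascade_stage1_failure_is_identified(phantom_case):
    vol, _ = phantom_case

    class _Silent:
        def predict(self, v):
            return v.with_values(np.zeros_like(v.values, dtype=np.float32))

    with pytest.raises(csc.CascadeError, match=r"\[step1\].*ROI not found"):
        csc.run_cascade(vol, {"step1": _Silent(), "step2": _Silent(), "step3": _Silent()})
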