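"""The three-step cascade: label generation, postprocessing and orchestration.

Step 1 detects an 80x80x80 mm^3 region of interest (ROI) around the aortic
root on a coarse 2 mm grid; step 2 segments aorta + valve inside the ROI at
0.6 mm; step 3 segments a 10 mm slab around the annulus plane, from which
the plane orientation is inferred by PCA of the voxel coordinates (the
normal is the eigenvector of the smallest covariance eigenvalue, valid
because the slab is flatter than it is wide).  Before the PCA the annulus
prediction is masked with the one-voxel contour of the step-2 aorta
segmentation and reduced to its largest 26-connected component, which
aligns the PCA input with the annulus at the cost of shifting its centroid
into the valve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import HEAD, Plane, validate_hinge_points
from .volume_io import (
    BoundingBoxMM,
    Mask,
    Volume,
    crop_detection_window,
    crop_to_box,
    in_volume_mask,
    normalize_intensity,
    resample_isotropic,
)

logger = logging.getLogger(__name__)

ROI_EXTENT_MM = 80.0
SLAB_HEIGHT_MM = 10.0
PROB_THRESHOLD = 0.5

__all__ = [
    "CascadeError",
    "CascadeOptions",
    "make_roi_label",
    "extract_roi_box",
    "make_aorta_label",
    "make_annulus_label",
    "mask_with_aorta_contour",
    "infer_annulus_plane",
    "hinge_plane",
    "run_cascade",
    "ROI_EXTENT_MM",
    "SLAB_HEIGHT_MM",
]


class CascadeError(RuntimeError):
    """A stage failure carrying the stage identity."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _voxel_centers_mm(vol: Volume) -> np.ndarray:
    """(nx, ny, nz, 3) patient-mm coordinates of all voxel centers."""
    idx = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in vol.shape], indexing="ij"),
        axis=-1,
    )
    flat = idx.reshape(-1, 3)
    return vol.index_to_mm(flat).reshape(vol.shape + (3,))


def make_roi_label(hinges, vol: Volume) -> Mask:
    """Binary mask of the axis-aligned 80 mm cube centered on the hinge midpoint."""
    pts = validate_hinge_points(hinges)
    center = pts.mean(axis=0)
    idx = vol.mm_to_index(center)
    if np.any(idx < -0.5) or np.any(idx > np.asarray(vol.shape) - 0.5):
        raise ValueError("hinge midpoint outside the volume")
    centers = _voxel_centers_mm(vol)
    half = ROI_EXTENT_MM / 2.0
    inside = np.all(np.abs(centers - center) <= half, axis=-1)
    return Mask(inside.astype(np.uint8), vol.spacing, vol.origin, vol.direction)


def extract_roi_box(prob: Volume, threshold: float = PROB_THRESHOLD) -> BoundingBoxMM:
    """Tight bounding box of voxels with p >= threshold, resized to 80 mm cube.

    The returned box keeps the tight box's center but has extents of exactly
    (80, 80, 80) mm.  Raises if no voxel reaches the threshold.
    """
    hits = np.argwhere(prob.values >= threshold)
    if hits.size == 0:
        raise CascadeError("step1", "ROI not found: no voxel above threshold")
    lo = hits.min(axis=0).astype(float)
    hi = hits.max(axis=0).astype(float)
    center = prob.index_to_mm((lo + hi) / 2.0)
    return BoundingBoxMM(center_mm=center, extents_mm=np.full(3, ROI_EXTENT_MM))


def make_aorta_label(truth_lumen_mask: Mask, roi: BoundingBoxMM, spacing_mm=0.6) -> Mask:
    """Aortic-lumen label cropped to the ROI at isotropic spacing."""
    out = crop_to_box(truth_lumen_mask, roi, spacing_mm, mode="label")
    if out.values.sum() == 0:
        raise ValueError("lumen mask does not intersect the ROI")
    return out


def make_annulus_label(
    root_lvot_mask: Mask, hinges, slab_height_mm: float = SLAB_HEIGHT_MM
) -> Mask:
    """Root+LVOT mask intersected with the 10 mm slab centered on the hinge plane."""
    plane = hinge_plane(hinges)
    centers = _voxel_centers_mm(root_lvot_mask)
    dist = (centers - plane.midpoint_mm) @ plane.normal
    slab = np.abs(dist) <= slab_height_mm / 2.0
    vals = (root_lvot_mask.values > 0) & slab
    if not vals.any():
        raise ValueError("hinge-plane slab does not intersect the mask")
    return Mask(
        vals.astype(np.uint8),
        root_lvot_mask.spacing,
        root_lvot_mask.origin,
        root_lvot_mask.direction,
    )


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def mask_with_aorta_contour(annulus_mask: Mask, aorta_mask: Mask) -> Mask:
    """Restrict the annulus prediction to the aorta contour shell.

    The contour is the aorta mask minus its one-voxel erosion, dilated by one
    voxel as tolerance; the intersection is reduced to its largest
    26-connected component.  An empty intersection falls back to the
    unmasked annulus mask with a warning.
    """
    if annulus_mask.values.shape != aorta_mask.values.shape:
        raise ValueError("masks must share a grid")
    a = aorta_mask.values > 0
    if not a.any():
        logger.warning("empty aorta mask; falling back to unmasked annulus region")
        return annulus_mask
    shell = a & ~ndimage.binary_erosion(a)
    shell = ndimage.binary_dilation(shell)
    hit = (annulus_mask.values > 0) & shell
    if not hit.any():
        logger.warning("annulus/contour intersection empty; falling back to unmasked mask")
        return annulus_mask
    labels, n = ndimage.label(hit, structure=_CONN26)
    if n > 1:
        sizes = ndimage.sum_labels(hit, labels, index=np.arange(1, n + 1))
        hit = labels == (1 + int(np.argmax(sizes)))
    return Mask(hit.astype(np.uint8), annulus_mask.spacing, annulus_mask.origin, annulus_mask.direction)


def infer_annulus_plane(region: Mask, min_voxels: int = 10) -> Plane:
    """PCA plane of a voxel region: centroid midpoint, smallest-variance normal.

    Valid when the region's in-plane diameters exceed its height; if the two
    smallest covariance eigenvalues are within 5% of each other the
    orientation is ambiguous (e.g. a sphere) and a warning is issued.
    """
    idx = np.argwhere(region.values > 0)
    if len(idx) < min_voxels:
        raise ValueError(f"region has fewer than {min_voxels} voxels")
    pts = region.index_to_mm(idx.astype(float))
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] > 0 and (evals[1] - evals[0]) / evals[1] < 0.05:
        warnings.warn(
            "ill-conditioned plane: two smallest PCA eigenvalues nearly equal",
            stacklevel=2,
        )
    return Plane(centroid, evecs[:, 0])


def hinge_plane(hinges) -> Plane:
    """Plane through the three hinge points; midpoint is their centroid."""
    pts = validate_hinge_points(hinges)
    normal = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    return Plane(pts.mean(axis=0), normal)


@dataclass
class CascadeOptions:
    """Grid resolutions and thresholds of the inference chain.

    Full-scale defaults: 2 mm detection grid, 0.6 mm ROI grid, probability
    threshold 0.5 for all steps.  Desk-scale runs may coarsen the grids.
    """

    detection_spacing_mm: float = 2.0
    roi_spacing_mm: float = 0.6
    threshold: float = PROB_THRESHOLD
    slab_height_mm: float = SLAB_HEIGHT_MM
    diameter_floor_mm: float = 17.0


def run_cascade(vol: Volume, ensembles, options: CascadeOptions | None = None):
    """Full inference: ROI detection -> aorta segmentation -> annulus region
    -> PCA plane -> diameter profile -> device size.

    ``ensembles`` is a mapping or 3-sequence of objects with
    ``predict(volume) -> probability volume`` for steps 1..3. Returns a
    :class:`aorticroot.rootmetry.CascadeResult`.
    """
    from . import rootmetry  # deferred: rootmetry holds the result type

    opts = options or CascadeOptions()
    if isinstance(ensembles, dict):
        step1, step2, step3 = ensembles["step1"], ensembles["step2"], ensembles["step3"]
    else:
        step1, step2, step3 = ensembles

    # -- step 1: ROI detection on the coarse grid --------------------------
    try:
        coarse = resample_isotropic(vol, opts.detection_spacing_mm, mode="image")
        window = crop_detection_window(coarse)
        prob1 = step1.predict(normalize_intensity(window))
        # padded out-of-scan voxels carry no information; keep in-scan only
        valid = in_volume_mask(window, coarse)
        prob1 = prob1.with_values(np.where(valid, prob1.values, 0.0))
        roi = extract_roi_box(prob1, opts.threshold)
    except CascadeError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage identity wrapper
        raise CascadeError("step1", str(exc)) from exc

    # -- step 2: aorta segmentation in the ROI ------------------------------
    try:
        roi_img = crop_to_box(vol, roi, opts.roi_spacing_mm, mode="image")
        roi_norm = normalize_intensity(roi_img)
        prob2 = step2.predict(roi_norm)
        aorta = Mask(
            (prob2.values >= opts.threshold).astype(np.uint8),
            prob2.spacing,
            prob2.origin,
            prob2.direction,
        )  # no postprocessing in this step
    except Exception as exc:  # noqa: BLE001
        raise CascadeError("step2", str(exc)) from exc

    # -- step 3: annulus region, plane, measurement -------------------------
    try:
        prob3 = step3.predict(roi_norm)
        annulus = Mask(
            (prob3.values >= opts.threshold).astype(np.uint8),
            prob3.spacing,
            prob3.origin,
            prob3.direction,
        )
        pca_input = mask_with_aorta_contour(annulus, aorta)
        plane = infer_annulus_plane(pca_input)
        region = rootmetry.combine_valve_region(aorta, annulus, plane, opts.slab_height_mm)
        profile = rootmetry.slice_diameter_profile(region, plane, step_mm=opts.roi_spacing_mm)
        # measure only slabs fully inside the height-limited region: the
        # outermost bins are partially cut by the +/- height/2 planes and
        # their truncated hulls would register spuriously small diameters
        full = np.abs(profile.offsets_mm) <= opts.slab_height_mm / 2.0 - opts.roi_spacing_mm / 2.0
        if full.any():
            profile = rootmetry.DiameterProfile(
                profile.offsets_mm[full], profile.diameters_mm[full]
            )
        diameter = rootmetry.minimal_diameter(profile, floor_mm=opts.diameter_floor_mm)
        device = rootmetry.suggest_device_size(diameter)
    except CascadeError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise CascadeError("step3", str(exc)) from exc

    return rootmetry.CascadeResult(
        aorta_mask=aorta,
        annulus_mask=annulus,
        plane=plane,
        profile=profile,
        annulus_diameter_mm=diameter,
        device_size_mm=device,
        roi_box=roi,
    )
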