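"""Deterministic aortic-root measurements.

The central quantity is the area-derived diameter d = 2*sqrt(A/pi) of a
cross-section, where A is the area of the convex hull of the segmented
voxel centers projected into a slice parallel to the annulus plane.  Voxel
centers underestimate the physical cross-section by about half a voxel all
around, so the hull area is corrected by the Minkowski terms
``A + P*s/2 + s**2`` (P the hull perimeter, s the effective in-plane pixel
pitch), which keeps a digital cylinder's diameter within about one voxel of
its analytic value.

The minimal diameter over the 10 mm valve region is the reported annulus
diameter; slices below the 17 mm floor are discarded first because a
cross-section that small cannot contain all three leaflets.  The reference
diameter uses the same machinery on the annotated root+LVOT mask within
+/-5 mm of the hinge-point plane.  Device sizes follow the sizing ladder
20/23/26/29/34 mm with band edges at 19.5, 22.5, 26.5 and 29.5 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .geometry import Plane
from .volume_io import Mask, Volume

__all__ = [
    "DiameterProfile",
    "CascadeResult",
    "DEVICE_SIZES_MM",
    "combine_valve_region",
    "slice_diameter_profile",
    "minimal_diameter",
    "reference_diameter",
    "suggest_device_size",
    "calcification_volume",
    "mean_absolute_error",
]

DEVICE_SIZES_MM = (20, 23, 26, 29, 34)
SIZING_EDGES_MM = (19.5, 22.5, 26.5, 29.5)  # half-open bands [lo, hi)
DIAMETER_FLOOR_MM = 17.0
CALCIUM_THRESHOLD_HU = 850.0


@dataclass
class DiameterProfile:
    """Area-derived diameter per signed offset along the plane normal."""

    offsets_mm: np.ndarray
    diameters_mm: np.ndarray

    def __post_init__(self):
        self.offsets_mm = np.asarray(self.offsets_mm, dtype=float)
        self.diameters_mm = np.asarray(self.diameters_mm, dtype=float)
        if self.offsets_mm.shape != self.diameters_mm.shape:
            raise ValueError("offsets and diameters must align")
        if len(self.offsets_mm) > 1 and not np.all(np.diff(self.offsets_mm) > 0):
            raise ValueError("offsets must be strictly increasing")
        if np.any(self.diameters_mm < 0):
            raise ValueError("diameters must be non-negative")


@dataclass
class CascadeResult:
    """Everything the cascade produces for one CT volume."""

    aorta_mask: Mask
    annulus_mask: Mask
    plane: Plane
    profile: DiameterProfile
    annulus_diameter_mm: float
    device_size_mm: int
    roi_box: object = None

    def report(self) -> dict:
        return {
            "plane_midpoint_mm": self.plane.midpoint_mm.tolist(),
            "plane_normal": self.plane.normal.tolist(),
            "annulus_diameter_mm": self.annulus_diameter_mm,
            "device_size_mm": self.device_size_mm,
            "profile_offsets_mm": self.profile.offsets_mm.tolist(),
            "profile_diameters_mm": self.profile.diameters_mm.tolist(),
        }


def combine_valve_region(
    aorta_mask: Mask, annulus_mask: Mask, plane: Plane, height_mm: float = 10.0
) -> Mask:
    """Union of aorta and annulus masks, cut to the 10 mm slab around the plane."""
    if aorta_mask.values.shape != annulus_mask.values.shape:
        raise ValueError("masks must share a grid")
    union = (aorta_mask.values > 0) | (annulus_mask.values > 0)
    idx = np.argwhere(union)
    if idx.size == 0:
        raise ValueError("empty union of masks")
    pts = aorta_mask.index_to_mm(idx.astype(float))
    keep = np.abs(plane.signed_distance(pts)) <= height_mm / 2.0
    if not keep.any():
        raise ValueError("slab does not intersect the combined mask")
    out = np.zeros(aorta_mask.values.shape, dtype=np.uint8)
    kept = idx[keep]
    out[kept[:, 0], kept[:, 1], kept[:, 2]] = 1
    return Mask(out, aorta_mask.spacing, aorta_mask.origin, aorta_mask.direction)


def _plane_basis(normal: np.ndarray):
    helper = np.array([1.0, 0.0, 0.0])
    if abs(normal @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def _slice_area(p2d: np.ndarray, pitch: float) -> float:
    """Convex-hull area of projected voxel centers with digitization correction."""
    if len(p2d) < 3:
        return len(p2d) * pitch**2
    try:
        hull = ConvexHull(p2d)
    except QhullError:  # collinear points
        return len(p2d) * pitch**2
    # Minkowski sum of the hull with a pitch-sized pixel square
    return float(hull.volume + hull.area * pitch / 2.0 + pitch**2)


def slice_diameter_profile(region: Mask, plane: Plane, step_mm: float = 0.6) -> DiameterProfile:
    """Per-slab area-derived diameters along the plane normal.

    Voxel centers are binned into slabs of thickness ``step_mm`` perpendicular
    to the normal; each slab's member centers are projected onto the plane
    and measured via the corrected convex-hull area.  Slabs with fewer than
    three non-collinear points use the degenerate pixel-count rule.
    """
    if step_mm <= 0:
        raise ValueError("step must be positive")
    idx = np.argwhere(region.values > 0)
    if idx.size == 0:
        raise ValueError("empty region")
    pts = region.index_to_mm(idx.astype(float))
    dist = plane.signed_distance(pts)
    # effective in-plane pixel pitch: voxel volume spread over the slab height
    pitch = float(np.sqrt(region.voxel_volume_mm3() / step_mm))
    u, v = _plane_basis(plane.normal)
    rel = pts - plane.midpoint_mm
    p2d = np.stack([rel @ u, rel @ v], axis=1)
    bins = np.round(dist / step_mm).astype(int)
    offsets, diameters = [], []
    for b in np.unique(bins):
        sel = bins == b
        area = _slice_area(p2d[sel], pitch)
        offsets.append(b * step_mm)
        diameters.append(2.0 * np.sqrt(area / np.pi))
    return DiameterProfile(np.asarray(offsets), np.asarray(diameters))


def minimal_diameter(profile: DiameterProfile, floor_mm: float = DIAMETER_FLOOR_MM) -> float:
    """Minimum profile diameter after discarding entries below the floor."""
    if len(profile.diameters_mm) == 0:
        raise ValueError("empty profile")
    valid = profile.diameters_mm[profile.diameters_mm >= floor_mm]
    if valid.size == 0:
        raise ValueError(f"no valid annulus diameter: all slices below {floor_mm} mm")
    return float(valid.min())


def reference_diameter(
    root_lvot_mask: Mask,
    hinges,
    range_mm: float = 5.0,
    step_mm: float | None = None,
    floor_mm: float = DIAMETER_FLOOR_MM,
) -> float:
    """Ground-truth diameter: minimal area-derived diameter of the annotated
    root+LVOT cross sections within +/-range_mm of the hinge-point plane."""
    from .cascade import hinge_plane  # local import to avoid a module cycle

    plane = hinge_plane(hinges)
    if step_mm is None:
        step_mm = float(np.min(root_lvot_mask.spacing))
    profile = slice_diameter_profile(root_lvot_mask, plane, step_mm=step_mm)
    sel = np.abs(profile.offsets_mm) <= range_mm + 1e-9
    if not sel.any():
        raise ValueError("mask has no cross sections within the hinge-plane range")
    sub = DiameterProfile(profile.offsets_mm[sel], profile.diameters_mm[sel])
    return minimal_diameter(sub, floor_mm=floor_mm)


def suggest_device_size(diameter_mm: float) -> int:
    """Device size from the sizing bands (half-open [lo, hi) at shared edges):
    < 19.5 -> 20, [19.5, 22.5) -> 23, [22.5, 26.5) -> 26, [26.5, 29.5) -> 29,
    >= 29.5 -> 34."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    i = int(np.searchsorted(SIZING_EDGES_MM, diameter_mm, side="right"))
    return DEVICE_SIZES_MM[i]


def calcification_volume(
    vol: Volume, valve_mask: Mask, threshold_hu: float = CALCIUM_THRESHOLD_HU
) -> float:
    """Calcification volume (mm^3): voxels in the valve mask at/above 850 HU."""
    if vol.values.shape != valve_mask.values.shape:
        raise ValueError("volume and mask must share a grid")
    vmax = float(np.abs(vol.values).max())
    if vmax <= 10.0:
        raise ValueError("volume appears intensity-normalized; calcium scoring needs HU")
    count = int(np.count_nonzero((valve_mask.values > 0) & (vol.values >= threshold_hu)))
    return count * vol.voxel_volume_mm3()


def mean_absolute_error(pred, ref) -> float:
    """Mean of |pred_i - ref_i| over paired diameter lists (mm)."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("pred and ref must be equal-length non-empty 1D sequences")
    return float(np.mean(np.abs(pred - ref)))
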