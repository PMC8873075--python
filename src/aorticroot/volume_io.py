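"""CT volume container, NIfTI/DICOM IO, resampling and the fixed geometric crops.

The in-memory convention is DICOM-native LPS patient coordinates: a voxel
index ``(i, j, k)`` maps to ``origin + direction @ (spacing * index)`` mm.
Arrays are indexed ``(x, y, z)`` (fastest-varying axis first in physical x),
and the HEAD (superior) direction is the patient +z axis.  NIfTI files use
RAS; the sign flips are handled on read/write via SimpleITK.

Preprocessing follows the fixed chain used for aortic-root detection: the
thorax scan is resampled to a coarse isotropic grid, cropped to a
256x256x384 mm^3 window centered 128 mm toward HEAD from the image center
(padded with air, -1024 HU, where the window leaves the scan), and the
detected region of interest is later cropped at 0.6 mm isotropic spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

logger = logging.getLogger(__name__)

AIR_HU = -1024.0

__all__ = [
    "Volume",
    "Mask",
    "BoundingBoxMM",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "normalize_intensity",
    "crop_detection_window",
    "crop_to_box",
    "in_volume_mask",
    "AIR_HU",
]


@dataclass
class Volume:
    """A 3D scalar grid with LPS patient-coordinate geometry.

    values : float array indexed (x, y, z)
    spacing : per-axis voxel spacing in mm (> 0)
    origin : patient-mm position of voxel (0, 0, 0)
    direction : 3x3 orthonormal matrix; column j is the patient-space unit
        vector along voxel axis j
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if abs(abs(np.linalg.det(self.direction)) - 1.0) > 1e-6:
            raise ValueError("direction must be orthonormal (|det| = 1)")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self):
        return self.values.shape

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical edge lengths of the voxel grid."""
        return self.spacing * np.asarray(self.shape)

    def index_to_mm(self, index) -> np.ndarray:
        index = np.asarray(index, dtype=float)
        return (index * self.spacing) @ self.direction.T + self.origin

    def mm_to_index(self, point_mm) -> np.ndarray:
        point_mm = np.asarray(point_mm, dtype=float)
        return ((point_mm - self.origin) @ self.direction) / self.spacing

    @property
    def center_mm(self) -> np.ndarray:
        """Patient-mm position of the geometric center of the voxel grid."""
        return self.index_to_mm((np.asarray(self.shape) - 1) / 2.0)

    @property
    def head_direction(self) -> np.ndarray:
        """Patient superior axis (+z in LPS)."""
        return np.array([0.0, 0.0, 1.0])

    def with_values(self, values: np.ndarray) -> "Volume":
        """Same grid, new voxel data (shape must match)."""
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch")
        return replace(self, values=values)

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    # -- SimpleITK bridge --------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.values.T))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        img.SetDirection(tuple(self.direction.flatten()))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "Volume":
        values = sitk.GetArrayFromImage(img).T
        return cls(
            values=values,
            spacing=np.asarray(img.GetSpacing()),
            origin=np.asarray(img.GetOrigin()),
            direction=np.asarray(img.GetDirection()).reshape(3, 3),
        )


class Mask(Volume):
    """A Volume whose values are binary {0, 1} (stored as uint8)."""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("mask values must be binary")
        self.values = self.values.astype(np.uint8)
        super().__post_init__()

    def voxel_count(self) -> int:
        return int(self.values.sum())

    def volume_mm3(self) -> float:
        return self.voxel_count() * self.voxel_volume_mm3()


@dataclass
class BoundingBoxMM:
    """Axis-aligned (in patient coordinates) box: center and per-axis extents, mm."""

    center_mm: np.ndarray
    extents_mm: np.ndarray

    def __post_init__(self):
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        self.extents_mm = np.asarray(self.extents_mm, dtype=float)
        if np.any(self.extents_mm <= 0):
            raise ValueError("extents must be positive")

    @property
    def low_mm(self) -> np.ndarray:
        return self.center_mm - self.extents_mm / 2.0

    @property
    def high_mm(self) -> np.ndarray:
        return self.center_mm + self.extents_mm / 2.0

    def volume_mm3(self) -> float:
        return float(np.prod(self.extents_mm))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_volume(path) -> Volume:
    """Read a NIfTI file or a DICOM series directory as an HU volume in LPS."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.is_dir():
        reader = sitk.ImageSeriesReader()
        ids = reader.GetGDCMSeriesIDs(str(path))
        if not ids:
            raise ValueError(f"no DICOM series found in {path}")
        if len(ids) > 1:
            raise ValueError(f"mixed DICOM series in {path}: {ids}")
        reader.SetFileNames(reader.GetGDCMSeriesFileNames(str(path), ids[0]))
        img = reader.Execute()
    else:
        img = sitk.ReadImage(str(path))
    return Volume.from_sitk(img)


def write_volume(vol: Volume, path) -> None:
    """Write a volume (or mask) as NIfTI with a correct affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(vol.to_sitk(), str(path))


# ---------------------------------------------------------------------------
# Resampling and normalization
# ---------------------------------------------------------------------------

def _resample_to_grid(vol, origin, size, spacing, direction, mode, pad_value):
    interp = sitk.sitkLinear if mode == "image" else sitk.sitkNearestNeighbor
    img = vol.to_sitk()
    ref = sitk.Image([int(s) for s in size], img.GetPixelID())
    ref.SetOrigin(tuple(np.asarray(origin, dtype=float)))
    ref.SetSpacing(tuple(np.asarray(spacing, dtype=float)))
    ref.SetDirection(tuple(np.asarray(direction, dtype=float).flatten()))
    out = sitk.Resample(img, ref, sitk.Transform(), interp, float(pad_value))
    res = Volume.from_sitk(out)
    if isinstance(vol, Mask):
        return Mask(res.values, res.spacing, res.origin, res.direction)
    return res


def resample_isotropic(vol: Volume, target_spacing_mm: float, mode: str = "image") -> Volume:
    """Resample to isotropic spacing, preserving physical extent.

    Images are interpolated linearly, label masks with nearest neighbor
    (``mode='label'``), which keeps them binary.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    if mode not in ("image", "label"):
        raise ValueError("mode must be 'image' or 'label'")
    if mode == "label" and not isinstance(vol, Mask):
        uniq = np.unique(vol.values)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("mode='label' requires binary input")
    t = float(target_spacing_mm)
    if np.allclose(vol.spacing, t, atol=1e-9):
        return vol
    size = np.maximum(np.round(vol.extent_mm / t), 1).astype(int)
    # keep the voxel-center lattice anchored at the old first voxel center
    origin = vol.origin
    pad = AIR_HU if mode == "image" else 0.0
    return _resample_to_grid(vol, origin, size, (t, t, t), vol.direction, mode, pad)


def normalize_intensity(vol: Volume) -> Volume:
    """Standardize intensities to zero mean, unit standard deviation.

    Statistics are computed over the whole subimage being processed.  A
    constant volume (zero variance) is returned as all zeros with a logged
    warning.
    """
    v = vol.values.astype(np.float32)
    mu = float(v.mean())
    sd = float(v.std())
    if sd < 1e-12:
        logger.warning("normalize_intensity: zero-variance volume, returning zeros")
        return vol.with_values(np.zeros_like(v))
    return vol.with_values((v - mu) / sd)


# ---------------------------------------------------------------------------
# Fixed geometric crops
# ---------------------------------------------------------------------------

DETECTION_WINDOW_MM = np.array([256.0, 256.0, 384.0])
DETECTION_OFFSET_MM = 128.0


def in_volume_mask(grid: Volume, source: Volume) -> np.ndarray:
    """Boolean array over ``grid`` voxels whose centers lie inside ``source``.

    Used to distinguish real scan content from the air padding introduced by
    the fixed-window crop: predictions on padded voxels carry no information
    about the scan.
    """
    idx = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in grid.shape], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    src_idx = source.mm_to_index(grid.index_to_mm(idx))
    ok = np.all((src_idx >= -0.5) & (src_idx <= np.asarray(source.shape) - 0.5), axis=1)
    return ok.reshape(grid.shape)


def crop_detection_window(vol: Volume, mode: str = "image") -> Volume:
    """Crop to the fixed 256x256x384 mm^3 detection window.

    The window is centered 128 mm toward the patient HEAD from the geometric
    image center; regions outside the input are padded with air (-1024 HU).
    Spacing is preserved; the output grid is axis-aligned in patient
    coordinates.
    """
    center = vol.center_mm + DETECTION_OFFSET_MM * vol.head_direction
    box = BoundingBoxMM(center_mm=center, extents_mm=DETECTION_WINDOW_MM.copy())
    return crop_to_box(vol, box, spacing_mm=vol.spacing, mode=mode, require_overlap=False)


def crop_to_box(
    vol: Volume,
    box: BoundingBoxMM,
    spacing_mm=0.6,
    mode: str = "image",
    require_overlap: bool = True,
) -> Volume:
    """Resample-crop to an axis-aligned patient-mm box at the given spacing.

    Out-of-field voxels are padded with -1024 HU (images) or 0 (labels).
    """
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,)).astype(float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    if require_overlap:
        lo = np.minimum(vol.index_to_mm((0, 0, 0)), vol.index_to_mm(np.asarray(vol.shape) - 1))
        hi = np.maximum(vol.index_to_mm((0, 0, 0)), vol.index_to_mm(np.asarray(vol.shape) - 1))
        if np.any(box.high_mm < lo) or np.any(box.low_mm > hi):
            raise ValueError("box does not overlap the volume")
    size = np.maximum(np.round(box.extents_mm / spacing), 1).astype(int)
    # voxel centers span the box symmetrically
    origin = box.center_mm - spacing * (size - 1) / 2.0
    pad = AIR_HU if mode == "image" else 0.0
    return _resample_to_grid(vol, origin, size, spacing, np.eye(3), mode, pad)
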