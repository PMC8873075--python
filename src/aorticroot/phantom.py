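"""Parametric synthetic aortic-root phantoms with exact ground truth.

The phantom is a rotationally symmetric contrast-filled tube swept along a
tilted straight axis, with a piecewise-linear radius profile
LVOT -> annulus waist -> sinus bulge -> ascending aorta.  The waist is the
global minimum of the profile, so the minimal area-derived cross-sectional
diameter of the root+LVOT mask equals twice the annulus radius by
construction.  Around the lumen sits a soft-tissue body cylinder in air;
optional calcific blobs (> 850 HU) are placed at the lumen wall near the
valve, and Gaussian noise is added to the rendered image only - masks,
hinge points, plane and diameter truths stay exact.

A voxel belongs to a structure when its center lies inside the analytic
surface.  All randomness is driven by the ``seed`` field so phantoms are
bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .geometry import HEAD, Plane, rotation_from_tilt
from .volume_io import Mask, Volume, write_volume

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "GeometryError",
    "generate_phantom",
    "generate_cylinder",
    "generate_dataset",
    "DEFAULT_PARAM_RANGES",
]


class GeometryError(ValueError):
    """The requested tube does not fit the volume extent."""


@dataclass
class PhantomParams:
    """Anatomical and imaging parameters of one phantom.

    Radii are lumen radii in mm; ``annulus_radius_mm`` is the waist minimum
    and must stay below the LVOT, sinus and aorta radii and at least 8.5 mm
    (area-derived diameter >= 17 mm).  ``tilt_deg`` rotates the tube axis
    about the patient x and y axes.  HU levels default to contrast-enhanced
    blood 300, soft tissue 40, air -1000 and calcium 1000 (above the 850 HU
    calcification threshold).
    """

    aorta_radius_mm: float = 14.0
    sinus_radius_mm: float = 16.0
    annulus_radius_mm: float = 11.5
    lvot_radius_mm: float = 12.5
    tilt_deg: tuple = (8.0, -5.0)
    segment_lengths_mm: tuple = (20.0, 10.0, 22.0, 28.0)  # LVOT, annulus, sinus, aorta
    hu_blood: float = 300.0
    hu_tissue: float = 40.0
    hu_air: float = -1000.0
    hu_calcium: float = 1000.0
    noise_sd: float = 20.0
    calcification_blobs: int = 0
    spacing_mm: tuple = (0.6, 0.6, 0.6)
    extent_mm: tuple = (96.0, 96.0, 120.0)
    seed: int = 0

    def validate(self) -> None:
        r = self.annulus_radius_mm
        if not (r < self.lvot_radius_mm and r < self.sinus_radius_mm and r < self.aorta_radius_mm):
            raise ValueError("annulus radius must be the global minimum of the radius profile")
        if r < 8.5:
            raise ValueError("annulus radius must be >= 8.5 mm (diameter floor 17 mm)")
        if not (self.hu_calcium > 850.0 > self.hu_blood):
            raise ValueError("need hu_calcium > 850 > hu_blood")
        if self.calcification_blobs < 0:
            raise ValueError("calcification_blobs must be >= 0")
        if any(s <= 0 for s in self.spacing_mm) or any(e <= 0 for e in self.extent_mm):
            raise ValueError("spacing and extent must be positive")
        if any(l <= 0 for l in self.segment_lengths_mm):
            raise ValueError("segment lengths must be positive")

    @property
    def total_length_mm(self) -> float:
        return float(sum(self.segment_lengths_mm))

    def to_json(self) -> dict:
        d = asdict(self)
        for k in ("tilt_deg", "segment_lengths_mm", "spacing_mm", "extent_mm"):
            d[k] = list(d[k])
        return d


@dataclass
class PhantomTruth:
    """Exact ground truth rendered with the phantom.

    ``aorta_mask`` is the lumen from the annulus segment upward (valve and
    ascending aorta, no LVOT); ``root_lvot_mask`` is the lumen of LVOT,
    annulus and sinus (the aortic-root/LVOT cross-section region).  Hinge
    points sit on the waist circle 120 degrees apart; the true plane passes
    through the waist perpendicular to the tube axis.
    """

    aorta_mask: Mask
    root_lvot_mask: Mask
    hinge_points: np.ndarray
    true_plane: Plane
    true_annulus_diameter_mm: float
    calcium_voxel_count: int = 0
    params: PhantomParams | None = None


def _radius_profile(params: PhantomParams):
    """Piecewise-linear radius knots (arclength t, radius)."""
    l1, l2, l3, l4 = params.segment_lengths_mm
    knots_t = np.array([0.0, l1, l1 + l2 / 2.0, l1 + l2 + l3 / 2.0, l1 + l2 + l3, l1 + l2 + l3 + l4])
    knots_r = np.array(
        [
            params.lvot_radius_mm,
            params.lvot_radius_mm,
            params.annulus_radius_mm,
            params.sinus_radius_mm,
            params.aorta_radius_mm,
            params.aorta_radius_mm,
        ]
    )
    return knots_t, knots_r


def _grid(spacing, extent):
    spacing = np.asarray(spacing, dtype=float)
    extent = np.asarray(extent, dtype=float)
    size = np.maximum(np.round(extent / spacing), 1).astype(int)
    origin = -spacing * (size - 1) / 2.0  # grid centered at the patient origin
    return size, origin, spacing


def _voxel_centers(size, origin, spacing):
    ax = [origin[i] + spacing[i] * np.arange(size[i]) for i in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    return np.stack([xx, yy, zz], axis=-1)


def generate_phantom(params: PhantomParams) -> tuple[Volume, PhantomTruth]:
    """Render one phantom volume (HU) and its exact ground truth."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    size, origin, spacing = _grid(params.spacing_mm, params.extent_mm)
    rot = rotation_from_tilt(params.tilt_deg)
    axis = rot @ HEAD
    if axis @ HEAD < 0:
        axis = -axis
    L = params.total_length_mm
    base = -axis * (L / 2.0)  # tube centered on the patient origin

    knots_t, knots_r = _radius_profile(params)
    # the tube must fit inside the extent; position and radius are linear in
    # arclength between knots, so checking the knots bounds every segment
    half_extent = np.asarray(params.extent_mm) / 2.0
    for t_k, r_k in zip(knots_t, knots_r):
        p = base + axis * t_k
        if np.any(np.abs(p) + r_k > half_extent + 1e-9):
            raise GeometryError("extent too small to contain the tilted tube")

    pts = _voxel_centers(size, origin, spacing)
    rel = pts - base
    t = rel @ axis
    radial = rel - t[..., None] * axis
    rho = np.linalg.norm(radial, axis=-1)
    r_of_t = np.interp(t, knots_t, knots_r)
    in_tube = (t >= 0) & (t <= L) & (rho <= r_of_t)

    # soft-tissue body: a straight cylinder along z around the patient origin
    body_r = min(params.extent_mm[0], params.extent_mm[1]) / 2.0 - 2.0
    in_body = np.hypot(pts[..., 0], pts[..., 1]) <= body_r

    hu = np.full(tuple(size), params.hu_air, dtype=np.float32)
    hu[in_body] = params.hu_tissue
    hu[in_tube] = params.hu_blood

    # calcification blobs at the lumen wall near the valve
    l1, l2, l3, _ = params.segment_lengths_mm
    calcium_count = 0
    for _b in range(params.calcification_blobs):
        tb = rng.uniform(l1, l1 + l2 + l3)
        ang = rng.uniform(0, 2 * np.pi)
        rb = rng.uniform(1.5, 3.0)
        rwall = float(np.interp(tb, knots_t, knots_r))
        u, v = _plane_basis(axis)
        cpos = base + axis * tb + rwall * (np.cos(ang) * u + np.sin(ang) * v)
        blob = np.linalg.norm(pts - cpos, axis=-1) <= rb
        calcium_count += int(np.count_nonzero(blob & ~(hu == params.hu_calcium)))
        hu[blob] = params.hu_calcium

    if params.noise_sd > 0:
        hu = hu + rng.normal(0.0, params.noise_sd, size=hu.shape).astype(np.float32)

    vol = Volume(hu, spacing, origin)

    t_waist = l1 + l2 / 2.0
    aorta_mask = Mask((in_tube & (t >= l1)).astype(np.uint8), spacing, origin)
    root_lvot_mask = Mask((in_tube & (t <= l1 + l2 + l3)).astype(np.uint8), spacing, origin)

    u, v = _plane_basis(axis)
    waist_center = base + axis * t_waist
    angles = np.radians([0.0, 120.0, 240.0])
    hinges = np.stack(
        [
            waist_center + params.annulus_radius_mm * (np.cos(a) * u + np.sin(a) * v)
            for a in angles
        ]
    )
    truth = PhantomTruth(
        aorta_mask=aorta_mask,
        root_lvot_mask=root_lvot_mask,
        hinge_points=hinges,
        true_plane=Plane(waist_center, axis),
        true_annulus_diameter_mm=2.0 * params.annulus_radius_mm,
        calcium_voxel_count=calcium_count,
        params=params,
    )
    return vol, truth


def _plane_basis(normal):
    """Two orthonormal vectors spanning the plane perpendicular to ``normal``."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def generate_cylinder(
    radius_mm: float,
    axis_direction,
    length_mm: float,
    spacing_mm,
    hu_blood: float = 300.0,
    hu_air: float = -1000.0,
    extent_mm=None,
) -> tuple[Volume, Mask]:
    """A solid digital cylinder: HU volume (blood inside, air outside) + mask.

    Used as an analytically known oracle fixture for diameter and plane
    measurements.  The axis direction is normalized; a zero vector is an
    error; ``length_mm == 0`` yields an empty mask.
    """
    axis = np.asarray(axis_direction, dtype=float)
    nn = np.linalg.norm(axis)
    if nn < 1e-12:
        raise ValueError("axis direction must be non-zero")
    axis = axis / nn
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,)).astype(float)
    if radius_mm < 2 * spacing.max() and length_mm > 0:
        raise ValueError("radius must be at least two voxel spacings")
    if extent_mm is None:
        margin = 4 * spacing.max()
        half = abs(length_mm) / 2.0 * np.abs(axis) + radius_mm + margin
        extent_mm = 2 * half
    size, origin, spacing = _grid(spacing, extent_mm)
    pts = _voxel_centers(size, origin, spacing)
    t = pts @ axis
    rho = np.linalg.norm(pts - t[..., None] * axis, axis=-1)
    inside = (np.abs(t) <= length_mm / 2.0) & (rho <= radius_mm) & (length_mm > 0)
    hu = np.where(inside, hu_blood, hu_air).astype(np.float32)
    return Volume(hu, spacing, origin), Mask(inside.astype(np.uint8), spacing, origin)


DEFAULT_PARAM_RANGES: dict = {
    # the annulus waist is sampled absolutely; the other radii are sampled as
    # positive offsets from it so every draw is an anatomically plausible root
    # (sinus widest, LVOT and ascending aorta slightly above the waist)
    "annulus_radius_mm": (8.75, 16.0),
    "lvot_offset_mm": (0.5, 2.5),
    "sinus_offset_mm": (3.0, 6.0),
    "aorta_offset_mm": (1.0, 4.0),
    "tilt_deg_x": (-15.0, 15.0),
    "tilt_deg_y": (-15.0, 15.0),
    "noise_sd": (10.0, 25.0),
    "calcification_blobs": (0, 4),
}


def generate_dataset(
    n: int,
    params_ranges: dict | None = None,
    seed: int = 0,
    base_params: PhantomParams | None = None,
) -> list[tuple[Volume, PhantomTruth]]:
    """Draw ``n`` phantoms with parameters uniform over the stated ranges.

    The annulus radius is drawn absolutely; LVOT, sinus and aorta radii are
    drawn as positive offsets from it (``*_offset_mm`` keys), which keeps the
    waist the global minimum and the sinus the widest segment for every
    draw.  Each case records its own parameters in the returned truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(DEFAULT_PARAM_RANGES)
    if params_ranges:
        ranges.update(params_ranges)
    for k, (lo, hi) in ranges.items():
        if hi < lo:
            raise ValueError(f"empty range for {k}")
    for k in ("lvot_offset_mm", "sinus_offset_mm", "aorta_offset_mm"):
        if ranges[k][0] <= 0:
            raise ValueError(f"{k} must be strictly positive to keep the waist minimal")
    base = base_params or PhantomParams()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        draw = {k: rng.uniform(lo, hi) for k, (lo, hi) in ranges.items()}
        ann = draw["annulus_radius_mm"]
        lvot = ann + draw["lvot_offset_mm"]
        sin = ann + draw["sinus_offset_mm"]
        aor = ann + draw["aorta_offset_mm"]
        params = PhantomParams(
            aorta_radius_mm=aor,
            sinus_radius_mm=sin,
            annulus_radius_mm=ann,
            lvot_radius_mm=lvot,
            tilt_deg=(draw.get("tilt_deg_x", base.tilt_deg[0]), draw.get("tilt_deg_y", base.tilt_deg[1])),
            segment_lengths_mm=base.segment_lengths_mm,
            hu_blood=base.hu_blood,
            hu_tissue=base.hu_tissue,
            hu_air=base.hu_air,
            hu_calcium=base.hu_calcium,
            noise_sd=draw.get("noise_sd", base.noise_sd),
            calcification_blobs=int(round(draw.get("calcification_blobs", base.calcification_blobs))),
            spacing_mm=base.spacing_mm,
            extent_mm=base.extent_mm,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(generate_phantom(params))
    return out


def save_case(vol: Volume, truth: PhantomTruth, out_dir, stem: str) -> None:
    """Write a phantom case: NIfTI volume + masks and a JSON truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_volume(vol, out_dir / f"{stem}_ct.nii.gz")
    write_volume(truth.aorta_mask, out_dir / f"{stem}_aorta_mask.nii.gz")
    write_volume(truth.root_lvot_mask, out_dir / f"{stem}_root_lvot_mask.nii.gz")
    sidecar = {
        "hinge_points_mm": truth.hinge_points.tolist(),
        "plane_midpoint_mm": truth.true_plane.midpoint_mm.tolist(),
        "plane_normal": truth.true_plane.normal.tolist(),
        "true_annulus_diameter_mm": truth.true_annulus_diameter_mm,
        "calcium_voxel_count": truth.calcium_voxel_count,
        "params": truth.params.to_json() if truth.params else None,
    }
    (out_dir / f"{stem}_truth.json").write_text(json.dumps(sidecar, indent=2))
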