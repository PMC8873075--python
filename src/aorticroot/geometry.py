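"""Shared geometric primitives: the annulus plane and hinge-point triples."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HEAD = np.array([0.0, 0.0, 1.0])  # patient superior axis in LPS


@dataclass
class Plane:
    """A plane given by a midpoint (mm) and a unit normal oriented toward HEAD."""

    midpoint_mm: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.midpoint_mm = np.asarray(self.midpoint_mm, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn < 1e-12:
            raise ValueError("plane normal must be non-zero")
        n = n / nn
        if n @ HEAD < 0:
            n = -n
        self.normal = n

    def signed_distance(self, points_mm) -> np.ndarray:
        """Signed distance of points to the plane, positive toward HEAD."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - self.midpoint_mm) @ self.normal

    def angle_to(self, other: "Plane") -> float:
        """Angle between the two normals in degrees (sign convention removed)."""
        c = abs(float(np.clip(self.normal @ other.normal, -1.0, 1.0)))
        return float(np.degrees(np.arccos(c)))


def validate_hinge_points(points) -> np.ndarray:
    """Check that three hinge points are distinct and non-collinear.

    Returns the points as a (3, 3) float array; raises ValueError otherwise.
    The non-collinearity threshold is a triangle area of 1 mm^2.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (3, 3):
        raise ValueError("hinge points must be three 3D points")
    if (
        np.linalg.norm(pts[0] - pts[1]) < 1e-9
        or np.linalg.norm(pts[0] - pts[2]) < 1e-9
        or np.linalg.norm(pts[1] - pts[2]) < 1e-9
    ):
        raise ValueError("hinge points must be pairwise distinct")
    area = 0.5 * np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
    if area <= 1.0:
        raise ValueError("hinge points are (near-)collinear: triangle area <= 1 mm^2")
    return pts


def rotation_from_tilt(tilt_deg) -> np.ndarray:
    """Rotation matrix from two tilt angles (deg) about the patient x and y axes."""
    ax, ay = np.radians(np.asarray(tilt_deg, dtype=float))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    return ry @ rx
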