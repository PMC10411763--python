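"""Six-degree-of-freedom rigid transforms.

Convention: a transform maps *reference* world coordinates (mm) to *target*
world coordinates,

    p' = R (p - c) + c + t,

where ``t`` is the translation (mm), ``c`` the rotation center (mm) and ``R``
the rotation built from Euler angles in degrees about fixed (extrinsic) axes,
applied z, then y, then x:  R = Rx(rx) @ Ry(ry) @ Rz(rz).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RigidTransform", "rotation_angle_deg"]


def _euler_zyx_to_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    a, b, c = np.deg2rad([rx, ry, rz])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    # R = Rx @ Ry @ Rz, written out
    return np.array(
        [
            [cb * cc, -cb * sc, sb],
            [ca * sc + sa * sb * cc, ca * cc - sa * sb * sc, -sa * cb],
            [sa * sc - ca * sb * cc, sa * cc + ca * sb * sc, ca * cb],
        ]
    )


def _matrix_to_euler_zyx(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`_euler_zyx_to_matrix`; returns (rx, ry, rz) degrees."""
    sb = np.clip(R[0, 2], -1.0, 1.0)
    ry = np.arcsin(sb)
    if abs(sb) < 1.0 - 1e-12:
        rx = np.arctan2(-R[1, 2], R[2, 2])
        rz = np.arctan2(-R[0, 1], R[0, 0])
    else:  # gimbal lock: ry = ±90°, only rx ± rz is determined
        rx = np.arctan2(R[2, 1], R[1, 1])
        rz = 0.0
    return tuple(np.rad2deg([rx, ry, rz]))


def rotation_angle_deg(R: np.ndarray) -> float:
    """Geodesic rotation angle (degrees) of a 3x3 rotation matrix."""
    return float(np.rad2deg(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0))))


@dataclass(frozen=True)
class RigidTransform:
    """Rigid 6-DOF transform: translations in mm, Euler rotations in degrees."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(center=tuple(float(v) for v in center))

    @classmethod
    def from_params(cls, params, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from a 6-vector (tx, ty, tz, rx, ry, rz)."""
        p = np.asarray(params, dtype=float)
        if p.shape != (6,):
            raise ValueError("params must be a 6-vector (tx, ty, tz, rx, ry, rz)")
        return cls(tuple(p[:3]), tuple(p[3:]), tuple(float(v) for v in center))

    def params(self) -> np.ndarray:
        return np.array([*self.translation, *self.rotation_deg], dtype=float)

    def rotation_matrix(self) -> np.ndarray:
        return _euler_zyx_to_matrix(*self.rotation_deg)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix of p' = R (p - c) + c + t."""
        R = self.rotation_matrix()
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + t - R @ c
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Recover parameters from a homogeneous rigid matrix.

        The rotation center is not identifiable from the matrix; the caller
        chooses it and the translation is adjusted so the mapping is identical.
        """
        M = np.asarray(M, dtype=float)
        R = M[:3, :3]
        if abs(np.linalg.det(R) - 1.0) > 1e-6 or not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("matrix is not a proper rigid rotation")
        c = np.asarray(center, dtype=float)
        # b = c + t - R c  =>  t = b - c + R c
        t = M[:3, 3] - c + R @ c
        return cls(tuple(t), _matrix_to_euler_zyx(R), tuple(float(v) for v in c))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of world points (mm)."""
        p = np.asarray(points, dtype=float)
        R = self.rotation_matrix()
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        return (p - c) @ R.T + c + t

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix()), center=self.center)

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return the transform p -> self(inner(p)), centered at self.center."""
        return RigidTransform.from_matrix(self.matrix() @ inner.matrix(), center=self.center)

    # --- error measures against another transform -------------------------
    def rotation_error_deg(self, other: "RigidTransform") -> float:
        return rotation_angle_deg(self.rotation_matrix().T @ other.rotation_matrix())

    def translation_error_mm(self, other: "RigidTransform", at_point=None) -> float:
        """Displacement difference (mm) at a world point (default: self.center)."""
        p = np.asarray(self.center if at_point is None else at_point, dtype=float)
        return float(np.linalg.norm(self.apply(p) - other.apply(p)))

    def as_dict(self) -> dict:
        return {
            "translations_mm": list(map(float, self.translation)),
            "rotations_deg": list(map(float, self.rotation_deg)),
            "center_mm": list(map(float, self.center)),
            "convention": "zyx-fixed",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            tuple(d["translations_mm"]),
            tuple(d["rotations_deg"]),
            tuple(d.get("center_mm", (0.0, 0.0, 0.0))),
        )
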