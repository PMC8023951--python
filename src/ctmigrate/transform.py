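"""Proper rigid motions of 3-D world space.

A :class:`RigidTransform` maps a world point ``x`` (mm, DICOM LPS axes) to
``R @ x + t`` with ``R`` a proper rotation (orthonormal, det +1) and ``t`` a
translation in millimetres.  It is the unit of all registration output:
transforms estimated between two examinations map exam-1 world coordinates
into exam-2 world coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation, world millimetres."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.array(self.rotation, dtype=float).reshape(3, 3)
        t = np.array(self.translation, dtype=float).reshape(3)
        err = float(np.abs(R.T @ R - np.eye(3)).max())
        if err > _ORTHO_TOL:
            raise ValueError(
                f"rotation matrix not orthonormal: max|R'R - I| = {err:.3e}"
            )
        if np.linalg.det(R) < 0.0:
            raise ValueError("rotation matrix is a reflection (det < 0)")
        R.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # ------------------------------------------------------------------ #
    # constructors
    # ------------------------------------------------------------------ #
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix, project: bool = False) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix or a (R, t) pair.

        With ``project=True`` the rotation block is projected onto SO(3)
        via SVD — used when ingesting optimizer output that may carry
        round-off beyond the orthonormality tolerance.
        """
        m = np.asarray(matrix, dtype=float)
        if m.shape == (4, 4):
            R, t = m[:3, :3], m[:3, 3]
        else:
            raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
        if project:
            u, _, vt = np.linalg.svd(R)
            d = np.sign(np.linalg.det(u @ vt))
            R = u @ np.diag([1.0, 1.0, d]) @ vt
        return cls(R, t)

    @classmethod
    def from_axis_angle(
        cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0), center=None
    ) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis``, optionally about a
        ``center`` point (mm) rather than the world origin, plus a
        translation."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        t = np.asarray(translation, dtype=float).copy()
        if center is not None:
            c = np.asarray(center, dtype=float)
            t = t + c - R @ c
        return cls(R, t)

    @classmethod
    def from_euler_xyz(
        cls, rx_deg: float, ry_deg: float, rz_deg: float,
        translation=(0.0, 0.0, 0.0), center=None,
    ) -> "RigidTransform":
        """Intrinsic x->y->z Euler rotation (degrees): R = Rx @ Ry @ Rz."""
        R = Rotation.from_euler("XYZ", [rx_deg, ry_deg, rz_deg], degrees=True).as_matrix()
        t = np.asarray(translation, dtype=float).copy()
        if center is not None:
            c = np.asarray(center, dtype=float)
            t = t + c - R @ c
        return cls(R, t)

    # ------------------------------------------------------------------ #
    # algebra
    # ------------------------------------------------------------------ #
    def apply(self, points) -> np.ndarray:
        """Map a point (3,) or point set (..., 3) through the motion."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @property
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees (axis-angle norm)."""
        return float(
            np.rad2deg(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )

    def deviation_from(self, other: "RigidTransform", radius_mm: float = 100.0):
        """(max point displacement over a sphere of ``radius_mm``, angle °)
        between two motions — a chart-free distance used in tests."""
        d = self.compose(other.inverse())
        ang = d.rotation_angle_deg
        # worst-case displacement of a point at distance radius_mm from origin
        disp = float(np.linalg.norm(d.translation)) + 2.0 * radius_mm * np.sin(
            np.deg2rad(ang) / 2.0
        )
        return disp, ang

    # ------------------------------------------------------------------ #
    # serialization
    # ------------------------------------------------------------------ #
    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]))
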