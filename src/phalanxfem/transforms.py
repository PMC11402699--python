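"""Rigid (proper orthogonal) spatial transforms.

A :class:`RigidTransform` maps world points ``x`` (mm) to ``R @ x + t``.
Rotations are stored as 3x3 proper orthogonal matrices; every constructor
validates orthogonality and ``det(R) = +1`` so downstream code can rely on
the invariant instead of re-checking it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` with lengths in mm."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation is not orthogonal (max |R'R - I| = {err:.3g})")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has det < 0 (improper / reflection)")

    # -- constructors ------------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    @staticmethod
    def from_axis_angle(axis, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("rotation axis must be non-zero")
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / n)
        return RigidTransform(rot.as_matrix(), np.asarray(translation, dtype=float))

    # -- algebra -----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N,3) array or a single 3-vector."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply *other* first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def about_point(self, point) -> "RigidTransform":
        """Re-express so the rotation pivots about ``point``: x -> R(x-p)+p+t."""
        p = np.asarray(point, dtype=float)
        return RigidTransform(self.rotation, p + self.translation - self.rotation @ p)

    # -- inspection --------------------------------------------------------
    def rotvec(self) -> np.ndarray:
        """Axis-angle vector (radians) of the rotation part."""
        return Rotation.from_matrix(self.rotation).as_rotvec()

    def angle_deg(self) -> float:
        return float(np.rad2deg(np.linalg.norm(self.rotvec())))

    def is_identity(self, tol: float = _ORTHO_TOL) -> bool:
        return (
            np.abs(self.rotation - np.eye(3)).max() <= tol
            and np.abs(self.translation).max() <= tol
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": [[float(v) for v in row] for row in self.rotation],
            "translation_mm": [float(v) for v in self.translation],
        }

    @staticmethod
    def from_dict(d: dict) -> "RigidTransform":
        return RigidTransform(np.asarray(d["rotation"]), np.asarray(d["translation_mm"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @staticmethod
    def from_json(path) -> "RigidTransform":
        with open(path) as fh:
            return RigidTransform.from_dict(json.load(fh))


def geodesic_interpolate(T: RigidTransform, fraction: float, pivot=None) -> RigidTransform:
    """Constant-axis interpolation: rotation angle and translation scale linearly.

    ``fraction=0`` gives the identity, ``fraction=1`` gives ``T`` exactly.
    Without a pivot the world-frame translation scales linearly; with one,
    the rotation pivots about that point and the pivot's own displacement
    scales linearly instead (the two differ for intermediate fractions).
    """
    rv = T.rotvec()
    R = Rotation.from_rotvec(fraction * rv).as_matrix()
    if pivot is None:
        return RigidTransform(R, fraction * T.translation)
    p = np.asarray(pivot, dtype=float)
    tau = T.apply(p) - p
    return RigidTransform(R, p + fraction * tau - R @ p)
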