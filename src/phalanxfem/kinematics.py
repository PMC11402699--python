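"""Fragment kinematics from optical marker clouds.

The measured quantity is the pose of each bone fragment over the flexion
exercise; the quantity driving the FE model is the *relative* motion of the
distal fragment in the (fixed) proximal fragment's frame, expressed at the
plate's reference divots and discretized into evenly spaced load steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .transforms import RigidTransform, geodesic_interpolate


@dataclass(frozen=True)
class DivotFrame:
    """Plate reference landmarks: the two divots and the plate's long axis."""

    proximal_divot: np.ndarray
    distal_divot: np.ndarray
    section_axis: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proximal_divot, dtype=float).reshape(3)
        d = np.asarray(self.distal_divot, dtype=float).reshape(3)
        a = np.asarray(self.section_axis, dtype=float).reshape(3)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("section axis must be non-zero")
        if np.allclose(p, d):
            raise ValueError("divots must be distinct points")
        object.__setattr__(self, "proximal_divot", p)
        object.__setattr__(self, "distal_divot", d)
        object.__setattr__(self, "section_axis", a / n)


def _as_matched_arrays(reference, current):
    if isinstance(reference, dict):
        labels = sorted(reference)
        if sorted(current) != labels:
            raise ValueError("marker labels do not match between frames")
        P = np.array([reference[k] for k in labels], dtype=float)
        Q = np.array([current[k] for k in labels], dtype=float)
    else:
        P = np.asarray(reference, dtype=float)
        Q = np.asarray(current, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("need matching (N, 3) point arrays")
    return P, Q


def fit_rigid_transform(reference_points, current_points):
    """Least-squares rigid fit (Kabsch): minimizes sum ||R p_i + t - q_i||^2.

    Accepts matched (N,3) arrays or ``{label: point}`` dicts. Returns
    ``(RigidTransform, rms_residual_mm)``. The SVD solution carries a
    reflection guard, so the result is always a proper rotation even for
    mirrored or very noisy clouds.
    """
    P, Q = _as_matched_arrays(reference_points, current_points)
    if P.shape[0] < 3:
        raise ValueError("need at least 3 markers per fragment")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    s = np.linalg.svd(P0, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("markers are collinear; rotation about the line is unobservable")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    S = np.diag([1.0, 1.0, d])
    R = Vt.T @ S @ U.T
    t = qc - R @ pc
    T = RigidTransform(R, t)
    rms = float(np.sqrt(np.mean(np.sum((T.apply(P) - Q) ** 2, axis=1))))
    return T, rms


def relative_transform_at_divot(
    T_proximal: RigidTransform, T_distal: RigidTransform, frame: DivotFrame
) -> RigidTransform:
    """Distal motion seen from the (held fixed) proximal fragment.

    ``T_rel = T_proximal^-1 o T_distal`` as a world map; common-mode motion of
    the whole hand cancels exactly. The divot frame fixes the reporting
    convention — use :func:`divot_decomposition` to read rotation about, and
    translation of, the distal divot.
    """
    return T_proximal.inverse().compose(T_distal)


def divot_decomposition(T_rel: RigidTransform, frame: DivotFrame):
    """(rotation vector [rad], translation of the distal divot [mm])."""
    return T_rel.rotvec(), T_rel.apply(frame.distal_divot) - frame.distal_divot


def make_displacement_steps(
    T_rel: RigidTransform, n: int = 10, pivot=None
) -> list[RigidTransform]:
    """Discretize ``T_rel`` into ``n`` evenly spaced steps (geodesic).

    Step k rotates by (k/n) of the total angle about the fixed rotation axis.
    With ``pivot`` given (normally the distal divot), the rotation pivots
    about that point and the pivot's own displacement scales linearly; the
    final step equals ``T_rel`` exactly either way.
    """
    if n < 1:
        raise ValueError("need at least one step")
    if T_rel.angle_deg() >= 180.0 - 1e-9:
        raise ValueError("rotation of 180 deg or more: interpolation axis is ambiguous")
    return [geodesic_interpolate(T_rel, k / n, pivot=pivot) for k in range(1, n + 1)]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_steps_json(steps, path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in steps], fh, indent=1)


def read_steps_json(path) -> list[RigidTransform]:
    with open(path) as fh:
        return [RigidTransform.from_dict(d) for d in json.load(fh)]
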