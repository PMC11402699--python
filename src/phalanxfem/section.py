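"""Internal section resultants at the plate mid-length and capacity checks.

The quantity of interest is the bending moment transmitted through the plate
at its mid-section, evaluated in a cut plane that follows the deformed plate
centerline (tangent-aligned frame). The scalar "bending moment" is the norm
of the two transverse moment components; torsion about the tangent is
reported separately and excluded from the scalar.

Sign convention: resultants summed over the distal side of the cut are the
force and moment exerted *by the distal segment on the proximal one*;
evaluating from the proximal side flips the sign (action-reaction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SectionFrame:
    point: np.ndarray  # deformed centerline point at the station (mm)
    tangent: np.ndarray  # unit vector along the deformed centerline
    t1: np.ndarray  # transverse axis near the plate width direction
    t2: np.ndarray  # tangent x t1


@dataclass
class MomentCurve:
    """Per-step section resultants; moments in N mm, forces in N."""

    steps: list = field(default_factory=list)  # step indices
    moment: list = field(default_factory=list)  # (3,) [torsion, M_t1, M_t2]
    force: list = field(default_factory=list)  # (3,) [axial N, V1, V2]

    def add(self, step: int, moment_section: np.ndarray, force_section: np.ndarray) -> None:
        self.steps.append(int(step))
        self.moment.append(np.asarray(moment_section, dtype=float))
        self.force.append(np.asarray(force_section, dtype=float))

    def bending_magnitudes(self) -> np.ndarray:
        m = np.asarray(self.moment)
        if m.size == 0:
            return np.zeros(0)
        return np.hypot(m[:, 1], m[:, 2])

    def to_frame(self) -> pd.DataFrame:
        m = np.asarray(self.moment).reshape(-1, 3)
        f = np.asarray(self.force).reshape(-1, 3)
        return pd.DataFrame(
            {
                "step": self.steps,
                "M_t1": m[:, 1],
                "M_t2": m[:, 2],
                "M_axial_torsion": m[:, 0],
                "N": f[:, 0],
                "V1": f[:, 1],
                "V2": f[:, 2],
                "M_bend": self.bending_magnitudes(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


def max_bending_moment(curve: MomentCurve) -> float:
    """Maximum transverse-moment magnitude over the load steps (N mm)."""
    mags = curve.bending_magnitudes()
    if mags.size == 0:
        raise ValueError("moment curve has no steps")
    return float(mags.max())


# ---------------------------------------------------------------------------
# deformed centerline frame
# ---------------------------------------------------------------------------

def deformed_centerline_frame(
    node_coords: np.ndarray,
    displacements: np.ndarray,
    station: float = 0.5,
    long_axis=(1.0, 0.0, 0.0),
    width_axis=(0.0, 1.0, 0.0),
    n_slabs: int = 25,
) -> SectionFrame:
    """Section frame on the deformed plate centerline.

    The centerline is sampled as centroids of ``n_slabs`` thin transverse
    slabs (binned along ``long_axis`` in *reference* coordinates) displaced
    by the FE field; the tangent at the station is a normalized central
    difference, and the transverse axes follow by Gram-Schmidt of the width
    direction against the tangent. Empty slabs are widened into their
    neighbours; more than 25% empty raises.
    """
    x = np.asarray(node_coords, dtype=float)
    u = np.asarray(displacements, dtype=float)
    a = np.asarray(long_axis, dtype=float)
    a = a / np.linalg.norm(a)
    s = x @ a
    lo, hi = float(s.min()), float(s.max())
    if hi - lo <= 0:
        raise ValueError("plate has no extent along the long axis")
    edges = np.linspace(lo, hi, n_slabs + 1)
    which = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_slabs - 1)
    deformed = x + u

    centroids = np.full((n_slabs, 3), np.nan)
    for k in range(n_slabs):
        sel = which == k
        if sel.any():
            centroids[k] = deformed[sel].mean(axis=0)
    empty = np.isnan(centroids[:, 0])
    if empty.mean() > 0.25:
        raise ValueError("more than 25% of centerline slabs are empty")
    if empty.any():  # widen: fill from nearest non-empty neighbours
        good = np.nonzero(~empty)[0]
        for k in np.nonzero(empty)[0]:
            near = good[np.argmin(np.abs(good - k))]
            centroids[k] = centroids[near]

    k0 = min(int(round(station * (n_slabs - 1))), n_slabs - 1)
    km, kp = max(k0 - 1, 0), min(k0 + 1, n_slabs - 1)
    tangent = centroids[kp] - centroids[km]
    nt = np.linalg.norm(tangent)
    if nt == 0:
        raise ValueError("degenerate centerline tangent")
    tangent = tangent / nt

    w = np.asarray(width_axis, dtype=float)
    t1 = w - (w @ tangent) * tangent
    n1 = np.linalg.norm(t1)
    if n1 < 1e-12:
        raise ValueError("width axis is parallel to the tangent")
    t1 = t1 / n1
    t2 = np.cross(tangent, t1)
    return SectionFrame(centroids[k0], tangent, t1, t2)


# ---------------------------------------------------------------------------
# cut-plane resultants
# ---------------------------------------------------------------------------

def cut_plane_resultants(
    system,
    fe_result,
    plane_point,
    frame: SectionFrame,
    element_set: str | None = None,
    side: str = "distal",
    use_deformed: bool = True,
):
    """Force and moment transmitted across the cut plane, in the section frame.

    Sums the element-internal nodal forces of the plate elements over all
    their nodes on the requested side of the plane (classified by deformed
    position); moments are taken about ``plane_point``. With
    ``use_deformed=False`` positions are taken in the reference configuration
    (the consistent first-order choice for a linear small-strain solve: the
    deformed-position correction is second order in the displacements).
    Returns ``(moment_section, force_section)`` with components ordered
    ``[along tangent, t1, t2]``.
    """
    u = fe_result.nodal_displacements
    f = system.internal_forces(u, element_set)
    if element_set is not None:
        nodes = np.unique(system.mesh.elements[system.mesh.element_sets[element_set]])
    else:
        nodes = np.arange(system.mesh.n_nodes)
    p = np.asarray(plane_point, dtype=float)
    t = frame.tangent
    xd = system.mesh.nodes[nodes]
    if use_deformed:
        xd = xd + u[nodes]
    proj = (xd - p) @ t

    if system.ties is not None and len(system.ties):
        s_proj = (system.mesh.nodes[system.ties[:, 0]] + u[system.ties[:, 0]] - p) @ t
        m_proj = (system.mesh.nodes[system.ties[:, 1]] + u[system.ties[:, 1]] - p) @ t
        if np.any(np.sign(s_proj) != np.sign(m_proj)):
            raise ValueError("cut plane passes through a tie constraint; move the station")

    sel = proj > 0 if side == "distal" else proj < 0
    F = f[nodes][sel].sum(axis=0)
    M = np.cross(xd[sel] - p, f[nodes][sel]).sum(axis=0)
    axes = np.stack([t, frame.t1, frame.t2])
    return axes @ M, axes @ F


def compute_moment_curve(
    system,
    results,
    station: float = 0.5,
    element_set: str = "plate_elements",
    node_set: str = "plate_nodes",
    long_axis=(1.0, 0.0, 0.0),
    width_axis=(0.0, 1.0, 0.0),
    n_slabs: int = 25,
    linearize: bool = False,
) -> MomentCurve:
    """Moment curve over a sequence of FE step results (plate mid-section).

    With ``linearize=True`` (appropriate for the linear solver mode) the cut
    plane and lever arms use the reference configuration, making the
    resultants exactly linear in the imposed motion; otherwise the plane
    follows the deformed centerline.
    """
    plate_nodes = system.mesh.node_sets[node_set]
    curve = MomentCurve()
    for res in results:
        disp = res.nodal_displacements[plate_nodes]
        fr = deformed_centerline_frame(
            system.mesh.nodes[plate_nodes],
            np.zeros_like(disp) if linearize else disp,
            station=station,
            long_axis=long_axis,
            width_axis=width_axis,
            n_slabs=n_slabs,
        )
        M, F = cut_plane_resultants(
            system, res, fr.point, fr, element_set, use_deformed=not linearize
        )
        curve.add(res.step_index, M, F)
    return curve


# ---------------------------------------------------------------------------
# capacity comparison
# ---------------------------------------------------------------------------

@dataclass
class CapacityReport:
    """Demand vs flexural capacity of a rectangular fixation cross-section."""

    demand_moment: float  # N mm
    allowable_moment: float  # N mm
    safety_factor: float
    utilization: float
    infinite: bool = False


def capacity_check(
    demand: float, width: float, thickness: float, flexural_strength: float
) -> CapacityReport:
    """Allowable moment ``sigma_f * b h^2 / 6`` against the demand moment.

    Units: mm and MPa in, N mm out. A zero demand is reported with an
    infinite safety factor flag.
    """
    if min(width, thickness, flexural_strength) <= 0 or demand < 0:
        raise ValueError("inputs must be positive (demand non-negative)")
    allowable = flexural_strength * width * thickness**2 / 6.0
    if demand == 0:
        return CapacityReport(0.0, allowable, math.inf, 0.0, infinite=True)
    sf = allowable / demand
    return CapacityReport(demand, allowable, sf, 1.0 / sf)
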