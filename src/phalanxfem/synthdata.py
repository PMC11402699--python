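"""Synthetic study inputs with known ground truth.

Every input the pipeline consumes can be generated here: an HR-pQCT-like
phantom of an osteotomized phalanx (idealized as a hollow cortical cylinder —
the downstream method is geometry-agnostic and an analyzable shape gives
exact oracles), a de-featured four-hole fixation plate, optical-marker
trajectories of rigid fragment motion, and uniaxial dog-bone tension curves
for the plate polymer. All generators are bit-reproducible under a fixed
seed; noiseless outputs satisfy their geometric invariants exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fem.mesh import Tet10Mesh, blocks_to_tet10
from .images import Mask, VoxelImage
from .transforms import RigidTransform, geodesic_interpolate

# PEEK constants measured on the physical plate material (used as generator
# ground truth and as the default plate stiffness)
PEEK_E = 1740.5  # MPa
PEEK_NU = 0.3779
PEEK_YIELD = 100.3  # MPa

# nominal dog-bone specimen dimensions (mm); reporting only, the curve math
# works in stress/strain
DOGBONE_LENGTH = 63.5
DOGBONE_WIDTH = 9.53
DOGBONE_THICKNESS = 4.0
DOGBONE_GAUGE_LENGTH = 9.53
DOGBONE_GAUGE_WIDTH = 3.18


# ---------------------------------------------------------------------------
# phantom volume
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Hollow-cylinder phalanx phantom: geometry, contrast and noise."""

    outer_radius: float = 4.0  # mm
    cortical_thickness: float = 1.5  # mm
    bone_length: float = 24.0  # mm
    gap_size: float = 3.0  # mm, transverse osteotomy at mid-length
    cortical_hu: float = 1600.0
    marrow_hu: float = 100.0
    background_hu: float = 0.0
    voxel_size: float = 0.082  # mm, isotropic (HR-pQCT class)
    noise_sd: float = 0.0  # HU
    seed: int = 0
    margin: float = 1.0  # mm of background padding around the bone

    def __post_init__(self) -> None:
        if self.gap_size < 0:
            raise ValueError("gap size must be non-negative")
        if not 0 < self.cortical_thickness < self.outer_radius:
            raise ValueError("need 0 < cortical thickness < outer radius")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if self.voxel_size > self.cortical_thickness:
            raise ValueError("voxel size exceeds cortical thickness: cortex unresolvable")
        if not self.marrow_hu < 400 <= self.cortical_hu <= 4000:
            raise ValueError("need marrow < 400 <= cortical <= 4000 HU for segmentation")
        if self.gap_size >= self.bone_length:
            raise ValueError("gap swallows the whole bone")


@dataclass
class PhantomModel:
    """Phantom image plus exact ground-truth cortex masks per fragment."""

    image: VoxelImage
    proximal_mask: Mask
    distal_mask: Mask
    spec: PhantomSpec
    gap_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gap_normal: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def cortex_mask(self) -> Mask:
        return Mask.like(self.image, self.proximal_mask.values | self.distal_mask.values)


def make_phalanx_phantom(spec: PhantomSpec) -> PhantomModel:
    """Voxelize the phantom; the bone axis is x, the osteotomy plane is x = 0.

    Voxels are classified by their centre (no partial-volume blur), so voxel
    counts track analytic volumes to discretization accuracy and the gap is
    an exact slab of background. The grid is snapped so x = 0 (and y = z = 0)
    fall on voxel boundaries, which makes the gap contain a whole number of
    transverse voxel planes.
    """
    h = spec.voxel_size
    nhx = int(np.ceil((spec.bone_length / 2 + spec.margin) / h))
    nhy = int(np.ceil((spec.outer_radius + spec.margin) / h))
    origin = np.array([-nhx * h, -nhy * h, -nhy * h])
    shape = (2 * nhx, 2 * nhy, 2 * nhy)

    img = VoxelImage(np.zeros(shape, dtype=np.float32), h, origin)
    x, y, z = img.center_grid()
    r2 = (y**2)[:, None] + (z**2)[None, :]
    in_bone_x = np.abs(x) <= spec.bone_length / 2
    in_gap_x = np.abs(x) < spec.gap_size / 2
    keep_x = in_bone_x & ~in_gap_x

    cortex_rz = (r2 <= spec.outer_radius**2) & (
        r2 > (spec.outer_radius - spec.cortical_thickness) ** 2
    )
    marrow_rz = r2 <= (spec.outer_radius - spec.cortical_thickness) ** 2

    cross_section = np.where(
        cortex_rz, spec.cortical_hu, np.where(marrow_rz, spec.marrow_hu, spec.background_hu)
    ).astype(np.float32)
    vals = np.full(shape, spec.background_hu, dtype=np.float32)
    vals[keep_x] = cross_section[None, :, :]

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vals = vals + rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)
    img.values = vals

    cortex = keep_x[:, None, None] & cortex_rz[None, :, :]
    prox = cortex & (x < 0)[:, None, None]
    dist = cortex & (x > 0)[:, None, None]
    return PhantomModel(img, Mask.like(img, prox), Mask.like(img, dist), spec)


def annulus_volume(spec: PhantomSpec) -> float:
    """Analytic cortex volume pi (R^2 - r^2) (L - g), mm^3."""
    R = spec.outer_radius
    r = R - spec.cortical_thickness
    return float(np.pi * (R**2 - r**2) * (spec.bone_length - spec.gap_size))


# ---------------------------------------------------------------------------
# fixation plate
# ---------------------------------------------------------------------------

@dataclass
class PlateSpec:
    """De-featured rectangular plate with four through-holes and two divots.

    The physical plate is a clinical hand-plate profile simplified to a
    prism for predictable bending; hole placement matches the surgical
    guide: two holes per fragment, 5 mm apart and 5 mm from the fracture
    line. Overall dimensions are configuration (stand-in defaults).
    """

    length: float = 24.0  # mm, along x
    width: float = 4.0  # mm, along y
    thickness: float = 1.5  # mm, along z
    hole_diameter: float = 1.5  # mm
    hole_spacing: float = 5.0  # mm between holes on the same fragment
    hole_offset_from_fracture: float = 5.0  # mm, innermost holes
    divot_positions: tuple | None = None  # two points on the top surface

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.thickness, self.hole_diameter) <= 0:
            raise ValueError("plate dimensions must be positive")
        outermost = self.hole_offset_from_fracture + self.hole_spacing
        if 2 * outermost + self.hole_diameter >= self.length:
            raise ValueError("holes do not fit within the plate length")
        if self.hole_diameter >= self.width:
            raise ValueError("holes wider than the plate")
        if self.hole_spacing <= self.hole_diameter or 2 * self.hole_offset_from_fracture <= self.hole_diameter:
            raise ValueError("holes overlap")
        if self.divot_positions is None:
            xd = self.hole_offset_from_fracture + self.hole_spacing / 2.0
            self.divot_positions = (
                np.array([-xd, 0.0, self.thickness]),
                np.array([xd, 0.0, self.thickness]),
            )
        else:
            self.divot_positions = tuple(
                np.asarray(p, dtype=float).reshape(3) for p in self.divot_positions
            )
            for p in self.divot_positions:
                if not (
                    abs(p[0]) <= self.length / 2 + 1e-9
                    and abs(p[1]) <= self.width / 2 + 1e-9
                    and abs(p[2] - self.thickness) <= 1e-9
                ):
                    raise ValueError("divots must lie on the plate top surface")

    def hole_centers_x(self) -> np.ndarray:
        o, s = self.hole_offset_from_fracture, self.hole_spacing
        return np.array([-(o + s), -o, o, o + s])


@dataclass
class PlateModel:
    """Solid tet10 plate mesh with labelled hole node sets and divot points."""

    mesh: Tet10Mesh
    spec: PlateSpec
    divot_proximal: np.ndarray
    divot_distal: np.ndarray

    @property
    def hole_set_names(self) -> list:
        return [f"hole_{i + 1}" for i in range(4)]


def make_plate(
    spec: PlateSpec,
    edge: float = 0.5,
    modulus: float = PEEK_E,
    poisson: float = PEEK_NU,
) -> PlateModel:
    """Mesh the plate from structured bricks of ~``edge`` mm.

    The plate is centred on the fracture plane (x = 0) with its underside at
    z = 0. Holes are carved by removing bricks whose centre falls inside a
    hole cylinder; ``hole_k`` node sets collect the staircase boundary nodes
    of hole k (ordered by increasing x).
    """
    nx = max(2, round(spec.length / edge))
    ny = max(2, round(spec.width / edge))
    nz = max(2, round(spec.thickness / edge))
    hx, hy, hz = spec.length / nx, spec.width / ny, spec.thickness / nz
    origin = np.array([-spec.length / 2, -spec.width / 2, 0.0])

    cx = origin[0] + (np.arange(nx) + 0.5) * hx
    cy = origin[1] + (np.arange(ny) + 0.5) * hy
    holes_x = spec.hole_centers_x()
    rad = spec.hole_diameter / 2.0
    in_hole = np.zeros((nx, ny), dtype=bool)
    for hxc in holes_x:
        in_hole |= ((cx - hxc) ** 2)[:, None] + (cy**2)[None, :] < rad**2
    occupied = np.broadcast_to(~in_hole[:, :, None], (nx, ny, nz))
    bidx = np.argwhere(occupied)
    if bidx.size == 0:
        raise ValueError("degenerate plate: nothing left after hole removal")

    mesh = blocks_to_tet10(bidx, (hx, hy, hz), origin, modulus, poisson)
    mesh.check()

    capture = rad + 0.55 * max(hx, hy)
    for i, hxc in enumerate(holes_x):
        d = np.hypot(mesh.nodes[:, 0] - hxc, mesh.nodes[:, 1])
        mesh.node_sets[f"hole_{i + 1}"] = np.nonzero(d <= capture)[0].astype(np.int64)
    dp, dd = spec.divot_positions
    return PlateModel(mesh, spec, dp, dd)


def plate_solid_volume(spec: PlateSpec) -> float:
    """Analytic prism-minus-holes volume, mm^3."""
    holes = 4 * np.pi * (spec.hole_diameter / 2.0) ** 2 * spec.thickness
    return float(spec.length * spec.width * spec.thickness - holes)


# ---------------------------------------------------------------------------
# marker trajectories
# ---------------------------------------------------------------------------

@dataclass
class MarkerFrame:
    """One camera frame: labelled marker points (mm) per fragment."""

    time_index: int
    proximal: dict
    distal: dict

    def __post_init__(self) -> None:
        for group in (self.proximal, self.distal):
            if len(group) < 3:
                raise ValueError("need at least 3 markers per fragment")


DEFAULT_PROXIMAL_MARKERS = {
    "P1": np.array([-10.0, 1.0, 7.0]),
    "P2": np.array([-7.0, -2.0, 8.5]),
    "P3": np.array([-5.0, 2.0, 9.5]),
    "P4": np.array([-8.5, 0.5, 11.0]),
}
DEFAULT_DISTAL_MARKERS = {
    "D1": np.array([10.0, -1.0, 7.0]),
    "D2": np.array([7.0, 2.0, 8.5]),
    "D3": np.array([5.0, -2.0, 9.5]),
    "D4": np.array([8.5, -0.5, 11.0]),
}


def make_marker_trajectory(
    final_transform: RigidTransform,
    n_frames: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
    proximal_markers: dict | None = None,
    distal_markers: dict | None = None,
    pivot=None,
) -> list[MarkerFrame]:
    """Marker frames of a rigid distal-fragment motion, proximal side static.

    Frame k (of ``n_frames``) carries the geodesic fraction ``k/(n_frames-1)``
    of ``final_transform`` (constant rotation axis, linearly scaled angle and
    pivot translation). Optional isotropic Gaussian noise perturbs every
    marker coordinate independently per frame.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    prox = proximal_markers or DEFAULT_PROXIMAL_MARKERS
    dist = distal_markers or DEFAULT_DISTAL_MARKERS
    if len(prox) < 3 or len(dist) < 3:
        raise ValueError("need at least 3 markers per fragment")
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n_frames):
        f = k / (n_frames - 1)
        Tk = geodesic_interpolate(final_transform, f, pivot=pivot)
        p = {lbl: np.asarray(pt, dtype=float).copy() for lbl, pt in prox.items()}
        d = {lbl: Tk.apply(pt) for lbl, pt in dist.items()}
        if noise_sd > 0:
            for grp in (p, d):
                for lbl in grp:
                    grp[lbl] = grp[lbl] + rng.normal(0.0, noise_sd, 3)
        frames.append(MarkerFrame(k, p, d))
    return frames


def write_markers_csv(frames: list[MarkerFrame], path) -> None:
    rows = []
    for fr in frames:
        for frag, group in (("proximal", fr.proximal), ("distal", fr.distal)):
            for lbl in sorted(group):
                x, y, z = group[lbl]
                rows.append((fr.time_index, frag, lbl, x, y, z))
    pd.DataFrame(
        rows, columns=["time_index", "fragment", "marker_label", "x_mm", "y_mm", "z_mm"]
    ).to_csv(path, index=False)


def read_markers_csv(path) -> list[MarkerFrame]:
    df = pd.read_csv(path)
    frames = []
    for t, g in df.groupby("time_index", sort=True):
        groups = {"proximal": {}, "distal": {}}
        for _, row in g.iterrows():
            groups[row["fragment"]][row["marker_label"]] = np.array(
                [row["x_mm"], row["y_mm"], row["z_mm"]]
            )
        frames.append(MarkerFrame(int(t), groups["proximal"], groups["distal"]))
    return frames


# ---------------------------------------------------------------------------
# dog-bone stress-strain curves
# ---------------------------------------------------------------------------

@dataclass
class StressStrainCurve:
    """Engineering uniaxial tension curve; lateral strain optional."""

    axial_strain: np.ndarray
    axial_stress: np.ndarray
    lateral_strain: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.axial_strain = np.asarray(self.axial_strain, dtype=float)
        self.axial_stress = np.asarray(self.axial_stress, dtype=float)
        if self.lateral_strain is not None:
            self.lateral_strain = np.asarray(self.lateral_strain, dtype=float)
            if self.lateral_strain.shape != self.axial_strain.shape:
                raise ValueError("lateral strain length mismatch")
        if self.axial_strain.shape != self.axial_stress.shape:
            raise ValueError("strain and stress arrays must have equal length")
        if self.axial_strain[0] != 0.0:
            raise ValueError("strain must start at 0")
        if np.any(np.diff(self.axial_strain) <= 0):
            raise ValueError("strain must be strictly increasing")
        if abs(self.axial_stress[0]) > 1e-12:
            raise ValueError("stress at zero strain must be 0")

    def to_csv(self, path) -> None:
        d = {"strain": self.axial_strain, "stress_MPa": self.axial_stress}
        if self.lateral_strain is not None:
            d["lateral_strain"] = self.lateral_strain
        pd.DataFrame(d).to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "StressStrainCurve":
        df = pd.read_csv(path)
        lat = df["lateral_strain"].to_numpy() if "lateral_strain" in df else None
        return StressStrainCurve(df["strain"].to_numpy(), df["stress_MPa"].to_numpy(), lat)


def make_dogbone_curve(
    E: float = PEEK_E,
    nu: float = PEEK_NU,
    offset_yield: float = PEEK_YIELD,
    hardening_modulus: float = 50.0,
    max_strain: float = 0.12,
    n_points: int = 240,
    noise_sd: float = 0.0,
    seed: int | None = None,
    offset: float = 0.002,
) -> StressStrainCurve:
    """Bilinear elastic-plastic tension curve with an exact offset yield.

    The elastic branch (slope E) meets a hardening branch (slope H) at a kink
    placed analytically so the ``offset``-line intersection stress equals
    ``offset_yield`` exactly:

        eps* = offset + offset_yield / E            (intersection strain)
        eps_k = (offset_yield - H eps*) / (E - H)   (kink strain)

    Lateral strain is ``-nu * eps`` elastically and incompressible
    (``nu = 0.5``) for the plastic part. The kink and intersection strains
    are inserted as exact samples so piecewise-linear readers see them.
    """
    if E <= 0:
        raise ValueError("E must be positive")
    if not 0 < nu < 0.5:
        raise ValueError("Poisson's ratio must lie in (0, 0.5)")
    if not 0 <= hardening_modulus < E:
        raise ValueError("hardening modulus must satisfy 0 <= H < E")
    if offset_yield / E >= max_strain:
        raise ValueError("curve never yields within max_strain")
    eps_star = offset + offset_yield / E
    if eps_star >= max_strain:
        raise ValueError("offset intersection lies beyond max_strain")
    H = hardening_modulus
    eps_k = (offset_yield - H * eps_star) / (E - H)
    if eps_k <= 0:
        raise ValueError("hardening too strong for the requested offset yield")

    eps = np.union1d(np.linspace(0.0, max_strain, n_points), [eps_k, eps_star])
    sig_k = E * eps_k
    sig = np.where(eps <= eps_k, E * eps, sig_k + H * (eps - eps_k))
    eps_el = sig / E
    eps_pl = eps - eps_el
    lateral = -(nu * eps_el + 0.5 * eps_pl)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, eps.size)
        noise[0] = 0.0  # keep the invariant stress(0) = 0
        sig = sig + noise
    return StressStrainCurve(eps, sig, lateral)
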