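"""Tet10 mesh container and voxel/block meshing.

Meshes are built from axis-aligned blocks: each block (a cube or brick) is
split into 6 tetrahedra along its main diagonal (Kuhn/Freudenthal split, the
same orientation in every block so shared faces conform), then promoted to
10-node quadratic tetrahedra by inserting globally de-duplicated edge
midpoints. Straight-sided axis-aligned splits guarantee positive Jacobians.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import tet10
from ..images import Mask, VoxelImage

#: map a local corner pair to the local mid-edge node index
_EDGE_LOCAL = {tuple(sorted(e)): 4 + i for i, e in enumerate(tet10.EDGES)}

#: corner-node faces of the reference tet
_FACES = np.array([(0, 1, 2), (0, 1, 3), (1, 2, 3), (0, 2, 3)])


@dataclass
class Tet10Mesh:
    """Quadratic tetrahedral mesh with per-element material data.

    ``elements[:, :4]`` are corners, ``elements[:, 4:]`` mid-edge nodes on
    edges (0,1), (1,2), (2,0), (0,3), (1,3), (2,3) — VTK TETRA10 ordering.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_modulus: np.ndarray
    element_poisson: np.ndarray
    node_sets: dict = field(default_factory=dict)
    element_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.elements = np.asarray(self.elements, dtype=np.int32).reshape(-1, 10)
        self.element_modulus = np.broadcast_to(
            np.asarray(self.element_modulus, dtype=float), (self.n_elements,)
        ).copy()
        self.element_poisson = np.broadcast_to(
            np.asarray(self.element_poisson, dtype=float), (self.n_elements,)
        ).copy()

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_coords(self, which=slice(None)) -> np.ndarray:
        return self.nodes[self.elements[which]]

    def volume(self) -> float:
        return float(tet10.element_volumes(self.element_coords()).sum())

    def check(self) -> None:
        """Validate invariants: positive Jacobians, exact mid-edge midpoints, no orphans."""
        vols = tet10.element_volumes(self.element_coords())
        if np.any(vols <= 0):
            raise ValueError("mesh contains inverted elements")
        c = self.element_coords()
        for m, (a, b) in enumerate(tet10.EDGES):
            err = np.abs(c[:, 4 + m] - 0.5 * (c[:, a] + c[:, b])).max()
            if err > 1e-9:
                raise ValueError("mid-edge nodes are not at edge midpoints")
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.elements.ravel()] = True
        if not used.all():
            raise ValueError("mesh has orphan nodes")


# ---------------------------------------------------------------------------
# block -> tet10 meshing
# ---------------------------------------------------------------------------

def _kuhn_tets() -> np.ndarray:
    """(6, 4) corner indices (in 0..7, bit-coded dz|dy|dx) of the 6-tet cube split."""
    def code(v):
        return v[0] + 2 * v[1] + 4 * v[2]

    tets = []
    for perm in itertools.permutations(range(3)):
        v = np.zeros((4, 3), dtype=int)
        for step, ax in enumerate(perm):
            v[step + 1] = v[step]
            v[step + 1, ax] += 1
        t = [code(vv) for vv in v]
        # positive orientation: parity of the permutation decides
        par = (
            sum(1 for i in range(3) for j in range(i + 1, 3) if perm[i] > perm[j]) % 2
        )
        if par:
            t[2], t[3] = t[3], t[2]
        tets.append(t)
    return np.array(tets)


_KUHN = _kuhn_tets()
# ordered so that row index == bit-code dx + 2*dy + 4*dz
_CORNER_OFFSETS = np.array([[c & 1, (c >> 1) & 1, (c >> 2) & 1] for c in range(8)])


def blocks_to_tet10(
    block_index: np.ndarray,
    block_size,
    origin,
    modulus_per_block,
    poisson_per_block,
) -> Tet10Mesh:
    """Mesh a set of axis-aligned bricks into tet10 elements.

    block_index: (K, 3) integer brick indices on a regular lattice;
    brick ``(i,j,k)`` spans ``origin + [i,j,k]*block_size`` to the next corner.
    Material values are per brick and copied to the brick's 6 tets.
    """
    bidx = np.asarray(block_index, dtype=np.int64).reshape(-1, 3)
    if bidx.shape[0] == 0:
        raise ValueError("no blocks to mesh")
    size = np.broadcast_to(np.asarray(block_size, dtype=float), (3,))
    origin = np.asarray(origin, dtype=float).reshape(3)

    # global corner lattice keyed on (i, j, k) of corner
    corners = bidx[:, None, :] + _CORNER_OFFSETS[None, :, :]  # (K, 8, 3)
    span = corners.reshape(-1, 3).max(axis=0) + 1
    keys = np.ravel_multi_index(corners.reshape(-1, 3).T, span)
    uniq, inv = np.unique(keys, return_inverse=True)
    corner_ids = inv.reshape(-1, 8)  # (K, 8)
    lattice = np.stack(np.unravel_index(uniq, span), axis=1).astype(float)
    corner_coords = origin + lattice * size

    tet4 = corner_ids[:, _KUHN].reshape(-1, 4)  # (6K, 4)

    # promote to tet10: unique edge midpoints
    edges = tet4[:, tet10.EDGES]  # (6K, 6, 2)
    edges = np.sort(edges, axis=2).reshape(-1, 2)
    ek, einv = np.unique(edges[:, 0] * np.int64(len(uniq)) + edges[:, 1], return_inverse=True)
    e_a = (ek // len(uniq)).astype(np.int64)
    e_b = (ek % len(uniq)).astype(np.int64)
    mid_coords = 0.5 * (corner_coords[e_a] + corner_coords[e_b])
    mid_ids = einv.reshape(-1, 6) + corner_coords.shape[0]

    nodes = np.vstack([corner_coords, mid_coords])
    elements = np.hstack([tet4, mid_ids])

    E = np.repeat(np.broadcast_to(np.asarray(modulus_per_block, dtype=float), (bidx.shape[0],)), 6)
    nu = np.repeat(np.broadcast_to(np.asarray(poisson_per_block, dtype=float), (bidx.shape[0],)), 6)
    return Tet10Mesh(nodes, elements, E, nu)


def voxels_to_tet10(
    mask: Mask,
    density,
    target_edge: float,
    cal,
    poisson: float = 0.3,
    fill_threshold: float = 0.5,
) -> Tet10Mesh:
    """Coarsen a voxel mask into ~``target_edge`` bricks and mesh them.

    Bricks group ``n = round(target_edge / spacing)`` voxels per axis; a brick
    is kept when its mask fill fraction reaches ``fill_threshold``. Each
    brick's modulus comes from the density->modulus law applied to the mean
    density over the whole brick (voxels outside the mask count as zero),
    which softens partially filled boundary bricks.
    """
    from ..imaging import density_to_modulus  # local import avoids a cycle

    if mask.count() == 0:
        raise ValueError("mask is empty")
    rho = density.values if isinstance(density, VoxelImage) else np.asarray(density)
    if rho.shape != mask.shape:
        raise ValueError("density grid must match the mask grid")
    rho = np.where(mask.values, rho, 0.0)

    n = np.maximum(1, np.rint(target_edge / mask.spacing).astype(int))
    shape = np.asarray(mask.shape)
    nblocks = -(-shape // n)  # ceil division
    pad = [(0, int(nblocks[a] * n[a] - shape[a])) for a in range(3)]
    mpad = np.pad(mask.values.astype(float), pad)
    rpad = np.pad(rho, pad)

    def block_mean(a):
        return a.reshape(
            nblocks[0], n[0], nblocks[1], n[1], nblocks[2], n[2]
        ).mean(axis=(1, 3, 5))

    fill = block_mean(mpad)
    rho_block = block_mean(rpad)
    keep = fill >= max(fill_threshold, 1e-12)
    if not keep.any():
        raise ValueError("coarsening removed all material; lower fill_threshold")

    bidx = np.argwhere(keep)
    E = density_to_modulus(rho_block[keep], cal)
    mesh = blocks_to_tet10(bidx, n * mask.spacing, mask.origin, E, poisson)
    mesh.check()
    return mesh


# ---------------------------------------------------------------------------
# surfaces and combination
# ---------------------------------------------------------------------------

def boundary_faces(mesh: Tet10Mesh, elements=None) -> np.ndarray:
    """(F, 6) node ids of boundary faces: 3 corners then their 3 mid-edge nodes."""
    conn = mesh.elements if elements is None else mesh.elements[elements]
    faces6 = []
    for fa, fb, fc in _FACES:
        mids = [
            _EDGE_LOCAL[tuple(sorted((fa, fb)))],
            _EDGE_LOCAL[tuple(sorted((fb, fc)))],
            _EDGE_LOCAL[tuple(sorted((fa, fc)))],
        ]
        faces6.append(conn[:, [fa, fb, fc] + mids])
    faces6 = np.vstack(faces6)
    key = np.sort(faces6[:, :3], axis=1)
    _, inv, cnt = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces6[cnt[inv] == 1]


def surface_nodes(mesh: Tet10Mesh, elements=None) -> np.ndarray:
    """Sorted node ids (corners and mid-edges) lying on the boundary surface."""
    return np.unique(boundary_faces(mesh, elements))


def combine_meshes(a: Tet10Mesh, b: Tet10Mesh, prefix_a: str, prefix_b: str) -> Tet10Mesh:
    """Concatenate two bodies into one mesh (no node merging; use ties to join).

    Node/element sets are carried over with ``<prefix>_`` prepended, and
    ``<prefix>_nodes`` / ``<prefix>_elements`` sets are added per body.
    """
    off_n, off_e = a.n_nodes, a.n_elements
    mesh = Tet10Mesh(
        np.vstack([a.nodes, b.nodes]),
        np.vstack([a.elements, b.elements + off_n]),
        np.concatenate([a.element_modulus, b.element_modulus]),
        np.concatenate([a.element_poisson, b.element_poisson]),
    )
    for name, ids in a.node_sets.items():
        mesh.node_sets[f"{prefix_a}_{name}"] = np.asarray(ids, dtype=np.int64)
    for name, ids in b.node_sets.items():
        mesh.node_sets[f"{prefix_b}_{name}"] = np.asarray(ids, dtype=np.int64) + off_n
    for name, ids in a.element_sets.items():
        mesh.element_sets[f"{prefix_a}_{name}"] = np.asarray(ids, dtype=np.int64)
    for name, ids in b.element_sets.items():
        mesh.element_sets[f"{prefix_b}_{name}"] = np.asarray(ids, dtype=np.int64) + off_e
    mesh.node_sets[f"{prefix_a}_nodes"] = np.arange(off_n, dtype=np.int64)
    mesh.node_sets[f"{prefix_b}_nodes"] = np.arange(off_n, mesh.n_nodes, dtype=np.int64)
    mesh.element_sets[f"{prefix_a}_elements"] = np.arange(off_e, dtype=np.int64)
    mesh.element_sets[f"{prefix_b}_elements"] = np.arange(off_e, mesh.n_elements, dtype=np.int64)
    return mesh
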