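"""10-node quadratic tetrahedral element: shape functions, stiffness, stress.

Local node ordering (VTK ``TETRA10`` convention):

* nodes 0-3: corners, reference coordinates (0,0,0), (1,0,0), (0,1,0), (0,0,1)
* nodes 4-9: mid-edge nodes on edges (0,1), (1,2), (2,0), (0,3), (1,3), (2,3)

Shape functions in barycentric coordinates ``L0..L3`` (``L0 = 1-x-e-z``):
``N_i = L_i (2 L_i - 1)`` at corners and ``N = 4 L_a L_b`` on edge (a, b).
For straight-sided elements the Jacobian is constant and the 4-point Gauss
rule (degree 2) integrates the stiffness exactly.
"""

from __future__ import annotations

import numpy as np

#: edge (a, b) corner pairs for mid-edge nodes 4..9
EDGES = np.array([(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)])

# 4-point Gauss rule on the reference tet: barycentric (a,b,b,b) permutations
_GA = 0.5854101966249685
_GB = 0.1381966011250105
GAUSS_BARY = np.array(
    [
        [_GA, _GB, _GB, _GB],
        [_GB, _GA, _GB, _GB],
        [_GB, _GB, _GA, _GB],
        [_GB, _GB, _GB, _GA],
    ]
)
GAUSS_W = np.full(4, 1.0 / 24.0)  # reference-volume weights (tet volume 1/6)

_CENTROID_BARY = np.full((1, 4), 0.25)


def shape_gradients_ref(bary: np.ndarray) -> np.ndarray:
    """d(N_i)/d(xi) at barycentric points; returns (n_pts, 10, 3).

    Reference coordinates are (xi, eta, zeta) = (L1, L2, L3).
    """
    bary = np.atleast_2d(bary)
    n = bary.shape[0]
    # dL/dxi rows for L0..L3
    dL = np.array(
        [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    out = np.zeros((n, 10, 3))
    for c in range(4):
        out[:, c, :] = (4.0 * bary[:, c] - 1.0)[:, None] * dL[c]
    for m, (a, b) in enumerate(EDGES):
        out[:, 4 + m, :] = 4.0 * (bary[:, a, None] * dL[b] + bary[:, b, None] * dL[a])
    return out


def shape_values(bary: np.ndarray) -> np.ndarray:
    """N_i at barycentric points; returns (n_pts, 10)."""
    bary = np.atleast_2d(bary)
    n = bary.shape[0]
    out = np.zeros((n, 10))
    out[:, :4] = bary * (2.0 * bary - 1.0)
    for m, (a, b) in enumerate(EDGES):
        out[:, 4 + m] = 4.0 * bary[:, a] * bary[:, b]
    return out


_DN_GAUSS = shape_gradients_ref(GAUSS_BARY)  # (4, 10, 3)
_DN_CENTROID = shape_gradients_ref(_CENTROID_BARY)  # (1, 10, 3)


def elasticity_matrix(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Isotropic Hooke matrix in Voigt order (xx, yy, zz, xy, yz, xz).

    Accepts scalars or per-element arrays; returns (..., 6, 6).
    """
    E = np.asarray(E, dtype=float)
    nu = np.asarray(nu, dtype=float)
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    D = np.zeros(np.broadcast(E, nu).shape + (6, 6))
    for i in range(3):
        for j in range(3):
            D[..., i, j] = lam
        D[..., i, i] = lam + 2.0 * mu
        D[..., 3 + i, 3 + i] = mu
    return D


def _b_matrices(coords: np.ndarray, dn_ref: np.ndarray):
    """Strain-displacement matrices for a batch of elements.

    coords: (M, 10, 3); dn_ref: (G, 10, 3).
    Returns B (M, G, 6, 30) and detJ (M, G).
    """
    # J[m,g,r,c] = d x_c / d xi_r
    J = np.einsum("gir,mic->mgrc", dn_ref, coords)
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    # dN/dx[m,g,i,c] = dn_ref[g,i,r] * (J^-1)^T[r,c]
    dndx = np.einsum("gir,mgcr->mgic", dn_ref, Jinv)
    M, G = dndx.shape[:2]
    B = np.zeros((M, G, 6, 30))
    dx, dy, dz = dndx[..., 0], dndx[..., 1], dndx[..., 2]
    idx = np.arange(10)
    B[..., 0, idx * 3 + 0] = dx
    B[..., 1, idx * 3 + 1] = dy
    B[..., 2, idx * 3 + 2] = dz
    B[..., 3, idx * 3 + 0] = dy
    B[..., 3, idx * 3 + 1] = dx
    B[..., 4, idx * 3 + 1] = dz
    B[..., 4, idx * 3 + 2] = dy
    B[..., 5, idx * 3 + 0] = dz
    B[..., 5, idx * 3 + 2] = dx
    return B, detJ


def element_stiffness(coords: np.ndarray, E, nu) -> np.ndarray:
    """Stiffness matrices (M, 30, 30) for a batch of straight tet10 elements.

    Raises if any Jacobian is non-positive at a Gauss point (inverted element).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    B, detJ = _b_matrices(coords, _DN_GAUSS)
    if np.any(~np.isfinite(detJ)) or np.any(detJ <= 0):
        bad = int(np.argwhere((detJ <= 0).any(axis=1))[0, 0])
        raise ValueError(f"non-positive Jacobian in element {bad}")
    D = elasticity_matrix(E, nu)
    if D.ndim == 2:
        D = np.broadcast_to(D, (coords.shape[0], 6, 6))
    DB = np.einsum("mij,mgjk->mgik", D, B)
    # each Gauss point carries reference weight 1/24 times detJ
    Ke = np.einsum("mgij,mgik,mg->mjk", B, DB, detJ) / 24.0
    return Ke


def element_volumes(coords: np.ndarray) -> np.ndarray:
    """Volumes from the corner nodes (exact for straight-sided elements)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    a = coords[:, 1, :] - coords[:, 0, :]
    b = coords[:, 2, :] - coords[:, 0, :]
    c = coords[:, 3, :] - coords[:, 0, :]
    return np.einsum("mi,mi->m", np.cross(a, b), c) / 6.0


def centroid_stress(coords: np.ndarray, u: np.ndarray, E, nu) -> np.ndarray:
    """Voigt stress (M, 6) at element centroids from nodal displacements u (M, 10, 3)."""
    coords = np.asarray(coords, dtype=float)
    u = np.asarray(u, dtype=float)
    if coords.ndim == 2:
        coords, u = coords[None], u[None]
    B, _ = _b_matrices(coords, _DN_CENTROID)
    ue = u.reshape(u.shape[0], 30)
    strain = np.einsum("mij,mj->mi", B[:, 0], ue)
    D = elasticity_matrix(E, nu)
    if D.ndim == 2:
        D = np.broadcast_to(D, (coords.shape[0], 6, 6))
    return np.einsum("mij,mj->mi", D, strain)


def von_mises(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress from Voigt (…, 6) [xx, yy, zz, xy, yz, xz]."""
    s = np.asarray(stress, dtype=float)
    sx, sy, sz, sxy, syz, sxz = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + sxz**2)
    )
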