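"""Assembly, multipoint constraints and the displacement-driven solve.

The model is driven purely by prescribed displacements: the proximal bone
end is clamped, the distal end follows a rigid step transform, and the plate
hangs on tie constraints at its screw holes. Ties are master-slave DOF
eliminations (slave plate node := nearest bone surface node), applied via a
sparse elimination operator T with ``K_red = T' K T``. Each load step then
partitions the reduced DOFs into prescribed and free and solves the SPD
system ``K_ff u_f = -K_fp u_p`` with a cached sparse LU factorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla
from scipy.spatial import cKDTree

from . import tet10
from .mesh import Tet10Mesh, combine_meshes, surface_nodes
from ..transforms import RigidTransform

_CHUNK = 2000  # elements per assembly batch (bounds peak memory)


@dataclass
class Constraint:
    """Kinematic constraint on a node set.

    kind: "fixed" (clamp to zero), "rigid_drive" (nodes follow the step
    transform rigidly) or "tie" (slave DOFs eliminated to a master node).
    """

    kind: str
    slave_nodes: np.ndarray
    master: int | None = None
    drive_transform: RigidTransform | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "rigid_drive", "tie"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        self.slave_nodes = np.asarray(self.slave_nodes, dtype=np.int64).ravel()


@dataclass
class ContactPlane:
    """Node-to-plane non-penetration condition ``(x + u - point) . normal >= 0``.

    Enforced by penalty springs (stiffness 100x the max stiffness diagonal)
    on the violating nodes, with an active-set iteration. Intended for
    gap-closure studies; inactive under rehabilitation-scale motion.
    """

    nodes: np.ndarray
    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=np.int64).ravel()
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        self.normal = n / np.linalg.norm(n)


@dataclass
class FEResult:
    """Solution of one load step."""

    step_index: int
    nodal_displacements: np.ndarray  # (N, 3) mm
    element_stress: np.ndarray  # (M, 6) Voigt MPa at centroids
    nodal_internal_forces: np.ndarray  # (N, 3) N; K u, i.e. reactions at BCs

    def reaction(self, nodes) -> np.ndarray:
        return self.nodal_internal_forces[np.asarray(nodes, dtype=np.int64)].sum(axis=0)


def assemble(mesh: Tet10Mesh, elements=None) -> sparse.csr_matrix:
    """Global stiffness (3N x 3N, CSR, symmetric) over all or a subset of elements."""
    conn = mesh.elements if elements is None else mesh.elements[np.asarray(elements)]
    E = mesh.element_modulus if elements is None else mesh.element_modulus[np.asarray(elements)]
    nu = mesh.element_poisson if elements is None else mesh.element_poisson[np.asarray(elements)]
    ndof = 3 * mesh.n_nodes
    K = sparse.csr_matrix((ndof, ndof))
    for start in range(0, conn.shape[0], _CHUNK):
        sl = slice(start, min(start + _CHUNK, conn.shape[0]))
        coords = mesh.nodes[conn[sl]]
        try:
            Ke = tet10.element_stiffness(coords, E[sl], nu[sl])
        except ValueError as exc:
            raise ValueError(f"assembly failed in chunk at element {start}: {exc}") from exc
        if not np.all(np.isfinite(Ke)):
            bad = start + int(np.argwhere(~np.isfinite(Ke).all(axis=(1, 2)))[0, 0])
            raise ValueError(f"non-finite stiffness entries in element {bad}")
        dof = (3 * conn[sl][:, :, None] + np.arange(3)).reshape(-1, 30)
        rows = np.repeat(dof, 30, axis=1).ravel()
        cols = np.tile(dof, (1, 30)).ravel()
        K = K + sparse.coo_matrix((Ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K


class FESystem:
    """Assembled plate-bone model with ties, boundary conditions and a solver."""

    def __init__(self, mesh: Tet10Mesh, ties: np.ndarray | None = None,
                 yield_stress: float | None = None,
                 yield_elements: np.ndarray | None = None):
        mesh.check()
        self.mesh = mesh
        self.ties = (
            np.zeros((0, 2), dtype=np.int64)
            if ties is None
            else np.asarray(ties, dtype=np.int64).reshape(-1, 2)
        )
        if self.ties.size:
            slaves = self.ties[:, 0]
            if np.unique(slaves).size != slaves.size:
                raise ValueError("a node appears as slave in more than one tie")
            if np.intersect1d(slaves, self.ties[:, 1]).size:
                raise ValueError("tie master is itself a slave")
        self.yield_stress = yield_stress
        self.yield_elements = yield_elements
        self.K = assemble(mesh)
        self._sub_K: dict = {}
        self._T = self._build_elimination()
        self.K_red = (self._T.T @ self.K @ self._T).tocsr()
        self.fixed_nodes = np.zeros(0, dtype=np.int64)
        self.driven_nodes = np.zeros(0, dtype=np.int64)
        self.driven_components = np.ones(3, dtype=bool)
        self._factor = None
        self._partition = None

    # -- constraint plumbing ----------------------------------------------
    def _build_elimination(self) -> sparse.csr_matrix:
        N = self.mesh.n_nodes
        rep = np.arange(N, dtype=np.int64)
        if self.ties.size:
            rep[self.ties[:, 0]] = self.ties[:, 1]
        self.node_rep = rep
        keep = np.setdiff1d(np.arange(N, dtype=np.int64), self.ties[:, 0] if self.ties.size else [])
        red_index = -np.ones(N, dtype=np.int64)
        red_index[keep] = np.arange(keep.size)
        self.reduced_nodes = keep
        self.reduced_index = red_index
        rows = (3 * np.arange(N)[:, None] + np.arange(3)).ravel()
        cols = (3 * red_index[rep][:, None] + np.arange(3)).ravel()
        return sparse.csr_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(3 * N, 3 * keep.size)
        )

    def set_constraints(self, fixed_nodes, driven_nodes, driven_components=None) -> None:
        """Clamp ``fixed_nodes`` and drive ``driven_nodes`` with the step transform.

        ``driven_components`` optionally restricts the driven DOFs to a subset
        of (x, y, z) — e.g. ``(False, False, True)`` imposes only transverse
        displacement and leaves the other components free.
        """
        fixed = np.unique(np.asarray(fixed_nodes, dtype=np.int64))
        driven = np.unique(np.asarray(driven_nodes, dtype=np.int64))
        self.driven_components = (
            np.ones(3, dtype=bool)
            if driven_components is None
            else np.asarray(driven_components, dtype=bool).reshape(3)
        )
        if np.intersect1d(fixed, driven).size:
            raise ValueError("a node cannot be both fixed and driven")
        if self.ties.size and (
            np.intersect1d(self.ties[:, 0], fixed).size
            or np.intersect1d(self.ties[:, 0], driven).size
        ):
            raise ValueError("tied slave nodes cannot carry boundary conditions")
        if fixed.size + driven.size < 3:
            raise ValueError("constraints cover too few DOFs; structure would float")
        self.fixed_nodes, self.driven_nodes = fixed, driven
        self._factor = None
        self._partition = None

    def _prescribed_dofs(self):
        comps = np.nonzero(self.driven_components)[0]
        rf = self.reduced_index[self.node_rep[self.fixed_nodes]]
        rd = self.reduced_index[self.node_rep[self.driven_nodes]]
        fixed_dofs = (3 * rf[:, None] + np.arange(3)).ravel()
        driven_dofs = (3 * rd[:, None] + comps).ravel()
        dofs = np.concatenate([fixed_dofs, driven_dofs])
        if np.unique(dofs).size != dofs.size:
            raise ValueError("overlapping prescribed DOFs")
        free = np.setdiff1d(np.arange(self.K_red.shape[0]), dofs)
        return dofs, free

    def _factorize(self):
        if self._factor is not None:
            return
        pres, free = self._prescribed_dofs()
        self._partition = (pres, free)
        Kff = self.K_red[np.ix_(free, free)].tocsc()
        self._Kfp = self.K_red[np.ix_(free, pres)].tocsr()
        try:
            self._factor = spla.splu(Kff, permc_spec="MMD_AT_PLUS_A")
        except Exception:
            # fall back to an iterative solve wrapper
            ilu = spla.spilu(Kff, drop_tol=1e-5, fill_factor=15)
            M = spla.LinearOperator(Kff.shape, ilu.solve)

            class _CGFactor:
                def solve(self_inner, b):
                    x, info = spla.cg(Kff, b, M=M, rtol=1e-10, maxiter=5000)
                    if info != 0:
                        raise RuntimeError("iterative solve did not converge")
                    return x

            self._factor = _CGFactor()

    # -- solving -----------------------------------------------------------
    def prescribed_displacement(self, step_transform: RigidTransform) -> np.ndarray:
        """(n_driven, 3) displacements of the driven nodes under the step map."""
        x = self.mesh.nodes[self.driven_nodes]
        return step_transform.apply(x) - x

    def solve_step(self, step_transform: RigidTransform, step_index: int = 0,
                   contact: list | None = None) -> FEResult:
        """Solve one load step: clamp fixed nodes, drive the distal set rigidly.

        ``contact`` is an optional list of :class:`ContactPlane`; violated
        planes are enforced by penalty springs with an active-set loop.
        """
        if self.fixed_nodes.size + self.driven_nodes.size == 0:
            raise ValueError("no constraints set; call set_constraints first")
        self._factorize()
        pres, free = self._partition
        up = self._prescribed_values(self.prescribed_displacement(step_transform))
        rhs = -self._Kfp @ up
        try:
            uf = self._factor.solve(rhs)
        except RuntimeError as exc:
            raise RuntimeError(
                f"singular or ill-conditioned system: {exc}; check that constraints "
                "restrain all rigid-body modes"
            ) from exc
        u_red = np.zeros(self.K_red.shape[0])
        u_red[pres] = up
        u_red[free] = uf
        if contact:
            u_red = self._contact_iterate(contact, up)
        u_full = (self._T @ u_red).reshape(-1, 3)
        f_int = (self.K @ u_full.ravel()).reshape(-1, 3)
        stress = self.element_stresses(u_full)
        self._warn_yield(stress)
        return FEResult(step_index, u_full, stress, f_int)

    def solve_steps(self, steps, mode: str = "linear", contact: list | None = None) -> list:
        """Solve a sequence of step transforms.

        "linear": proportional displacement loading — the final pose's
        prescribed displacement is ramped linearly over the steps (one
        solve; intermediate results scale exactly, matching how a linear
        static analysis treats a ramp amplitude). This coincides with the
        geodesic intermediate poses to second order in the rotation angle.
        "incremental": each step's pose is imposed exactly, the node
        coordinates are updated and the stiffness reassembled after every
        step — a first-order account of geometric nonlinearity; stresses
        accumulate over increments.
        """
        if mode == "linear":
            n = len(steps)
            if contact:
                # contact breaks superposition: every step is solved in full
                return [
                    self.solve_step(T, k, contact=contact)
                    for k, T in enumerate(steps, start=1)
                ]
            final = self.solve_step(steps[-1], n)
            out = []
            for k in range(1, n):
                f = k / n
                out.append(
                    FEResult(
                        k,
                        f * final.nodal_displacements,
                        f * final.element_stress,
                        f * final.nodal_internal_forces,
                    )
                )
            return out + [final]
        if mode != "incremental":
            raise ValueError("mode must be 'linear' or 'incremental'")
        base = self.mesh.nodes.copy()
        u_total = np.zeros_like(base)
        stress_total = np.zeros((self.mesh.n_elements, 6))
        results = []
        try:
            for k, T in enumerate(steps, start=1):
                # target displacement is defined on the reference coordinates
                x_drv = base[self.driven_nodes]
                target = T.apply(x_drv) - x_drv
                inc = target - u_total[self.driven_nodes]
                res = self._solve_increment(inc)
                u_total = u_total + res.nodal_displacements
                stress_total = stress_total + res.element_stress
                self.mesh.nodes = base + u_total
                self.K = assemble(self.mesh)
                self._sub_K.clear()
                self.K_red = (self._T.T @ self.K @ self._T).tocsr()
                self._factor = None
                f_int = (self.K @ u_total.ravel()).reshape(-1, 3)
                self._warn_yield(stress_total)
                results.append(FEResult(k, u_total.copy(), stress_total.copy(), f_int))
        finally:
            self.mesh.nodes = base
            self.K = assemble(self.mesh)
            self._sub_K.clear()
            self.K_red = (self._T.T @ self.K @ self._T).tocsr()
            self._factor = None
        return results

    def _contact_iterate(self, contact, up, max_iter: int = 12) -> np.ndarray:
        """Active-set penalty enforcement of node-to-plane contact.

        Solves the reduced system repeatedly, activating penalty springs on
        nodes that penetrate their plane, until the active set is stable.
        """
        pres, free = self._partition
        ndof = self.K_red.shape[0]
        kp = 100.0 * float(self.K_red.diagonal().max())
        active_prev = None
        u_red = np.zeros(ndof)
        u_red[pres] = up
        u_red[free] = self._factor.solve(-self._Kfp @ up)
        for _ in range(max_iter):
            rows, vals, rhs_pen = [], [], np.zeros(ndof)
            active = []
            for cp in contact:
                red = self.reduced_index[self.node_rep[cp.nodes]]
                dofs = 3 * red[:, None] + np.arange(3)
                un = (u_red[dofs] * cp.normal).sum(axis=1)
                d = (cp.point - self.mesh.nodes[cp.nodes]) @ cp.normal
                pen = un - d < 0  # penetration
                active.append(pen)
                for r, di in zip(dofs[pen], d[pen]):
                    rows.append(r)
                    vals.append(cp.normal)
                    rhs_pen[r] += kp * di * cp.normal
            key = tuple(a.tobytes() for a in active)
            if active_prev == key:
                break
            active_prev = key
            if not rows:
                break
            P = sparse.csr_matrix((ndof, ndof))
            if rows:
                r = np.concatenate([np.repeat(d, 3) for d in rows])
                c = np.concatenate([np.tile(d, 3) for d in rows])
                v = np.concatenate([kp * np.outer(n, n).ravel() for n in vals])
                P = sparse.coo_matrix((v, (r, c)), shape=(ndof, ndof)).tocsr()
            A = (self.K_red + P)[np.ix_(free, free)].tocsc()
            b = -(self.K_red + P)[np.ix_(free, pres)] @ up + rhs_pen[free]
            u_red[free] = spla.spsolve(A, b)
        return u_red

    def _prescribed_values(self, driven_disp: np.ndarray) -> np.ndarray:
        comps = np.nonzero(self.driven_components)[0]
        return np.concatenate(
            [np.zeros(3 * self.fixed_nodes.size), driven_disp[:, comps].ravel()]
        )

    def _solve_increment(self, driven_disp: np.ndarray) -> FEResult:
        self._factorize()
        pres, free = self._partition
        up = self._prescribed_values(driven_disp)
        uf = self._factor.solve(-self._Kfp @ up)
        u_red = np.zeros(self.K_red.shape[0])
        u_red[pres] = up
        u_red[free] = uf
        u_full = (self._T @ u_red).reshape(-1, 3)
        f_int = (self.K @ u_full.ravel()).reshape(-1, 3)
        return FEResult(0, u_full, self.element_stresses(u_full), f_int)

    # -- post-processing ---------------------------------------------------
    def element_stresses(self, u: np.ndarray) -> np.ndarray:
        out = np.zeros((self.mesh.n_elements, 6))
        conn = self.mesh.elements
        for start in range(0, conn.shape[0], _CHUNK):
            sl = slice(start, min(start + _CHUNK, conn.shape[0]))
            out[sl] = tet10.centroid_stress(
                self.mesh.nodes[conn[sl]],
                u[conn[sl]],
                self.mesh.element_modulus[sl],
                self.mesh.element_poisson[sl],
            )
        return out

    def internal_forces(self, u: np.ndarray, element_set: str | None = None) -> np.ndarray:
        """(N, 3) nodal internal forces of all elements or a named element set."""
        if element_set is None:
            return (self.K @ u.ravel()).reshape(-1, 3)
        if element_set not in self._sub_K:
            ids = self.mesh.element_sets[element_set]
            self._sub_K[element_set] = assemble(self.mesh, ids)
        return (self._sub_K[element_set] @ u.ravel()).reshape(-1, 3)

    def _warn_yield(self, stress: np.ndarray) -> None:
        if self.yield_stress is None:
            return
        sub = stress if self.yield_elements is None else stress[self.yield_elements]
        vm = tet10.von_mises(sub).max() if sub.size else 0.0
        if vm > self.yield_stress:
            warnings.warn(
                f"max von Mises stress {vm:.1f} MPa exceeds yield "
                f"({self.yield_stress:.1f} MPa); elastic solution is extrapolating"
            )


def solve_step(system: FESystem, constraints, step_transform: RigidTransform,
               step_index: int = 0) -> FEResult:
    """Functional wrapper: apply a list of :class:`Constraint` and solve one step."""
    fixed, driven = [], []
    for c in constraints:
        if c.kind == "fixed":
            fixed.append(c.slave_nodes)
        elif c.kind == "rigid_drive":
            driven.append(c.slave_nodes)
    system.set_constraints(
        np.concatenate(fixed) if fixed else [],
        np.concatenate(driven) if driven else [],
    )
    return system.solve_step(step_transform, step_index)


# ---------------------------------------------------------------------------
# plate-bone ties
# ---------------------------------------------------------------------------

@dataclass
class TieReport:
    n_ties: int
    per_hole: dict
    max_distance: float
    distances: np.ndarray = field(repr=False, default=None)


def apply_ties(
    plate_mesh: Tet10Mesh,
    bone_mesh: Tet10Mesh,
    hole_sets: list | None = None,
    search_radius: float = 1.0,
    yield_stress: float | None = None,
) -> tuple[FESystem, TieReport]:
    """Combine plate and bone and tie the screw-hole nodes to the bone surface.

    Every plate hole-boundary node with a bone *surface* node within
    ``search_radius`` has its 3 DOFs eliminated to that nearest node. A hole
    with no reachable bone raises. Returns the assembled system plus a
    report of slave->master distances.
    """
    hole_sets = hole_sets or sorted(k for k in plate_mesh.node_sets if k.startswith("hole"))
    combined = combine_meshes(plate_mesh, bone_mesh, "plate", "bone")
    bone_surf = surface_nodes(bone_mesh) + plate_mesh.n_nodes
    tree = cKDTree(combined.nodes[bone_surf])

    pairs, dists, per_hole = [], [], {}
    for name in hole_sets:
        slaves = combined.node_sets[f"plate_{name}"]
        d, j = tree.query(combined.nodes[slaves], k=1)
        ok = d <= search_radius
        if not ok.any():
            raise ValueError(
                f"no bone surface node within {search_radius} mm of plate {name}"
            )
        pairs.append(np.column_stack([slaves[ok], bone_surf[j[ok]]]))
        dists.append(d[ok])
        per_hole[name] = int(ok.sum())
    ties = np.vstack(pairs)
    # a slave can sit near two holes' capture zones; keep the first occurrence
    _, first = np.unique(ties[:, 0], return_index=True)
    ties = ties[np.sort(first)]
    dist = np.concatenate(dists)[np.sort(first)]
    yield_elems = combined.element_sets["plate_elements"] if yield_stress else None
    system = FESystem(combined, ties, yield_stress=yield_stress, yield_elements=yield_elems)
    report = TieReport(ties.shape[0], per_hole, float(dist.max()), dist)
    return system, report
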