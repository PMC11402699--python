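"""Quadratic-tet solver: meshing oracles, stiffness properties, ties."""

import itertools

import numpy as np
import pytest

from phalanxfem.fem import (
    FESystem,
    assemble,
    blocks_to_tet10,
    boundary_faces,
    combine_meshes,
    voxels_to_tet10,
)
from phalanxfem.fem import tet10
from phalanxfem.fem.mesh import _KUHN
from phalanxfem.images import Mask, VoxelImage
from phalanxfem.imaging import DensityCalibration
from phalanxfem.transforms import RigidTransform
from conftest import box_mesh


class TestBlockMeshing:
    def test_unit_cube_node_count_against_edge_enumeration(self):
        """Independent oracle: count unique nodes of the 6-tet split by brute
        force over the split's corner pairs."""
        corners = [np.array([c & 1, (c >> 1) & 1, (c >> 2) & 1]) for c in range(8)]
        edges = set()
        for tet in _KUHN:
            for a, b in itertools.combinations(tet, 2):
                edges.add(tuple(sorted((a, b))))
        expected_nodes = 8 + len(edges)
        mesh = blocks_to_tet10(np.array([[0, 0, 0]]), 1.0, (0, 0, 0), 1.0, 0.3)
        assert mesh.n_elements == 6
        assert mesh.n_nodes == expected_nodes == 27
        # mid-edge nodes sit at midpoints of actual split edges
        mids = {tuple(np.round((corners[a] + corners[b]) / 2, 9)) for a, b in edges}
        mesh_mids = {tuple(np.round(p, 9)) for p in mesh.nodes[8:]}
        assert mids == mesh_mids

    def test_cube_split_volume_is_exact(self):
        rng = np.random.default_rng(0)
        occ = rng.random((4, 5, 3)) > 0.4
        mesh = blocks_to_tet10(np.argwhere(occ), (0.7, 0.3, 0.5), (1, -2, 0), 5.0, 0.3)
        expected = occ.sum() * 0.7 * 0.3 * 0.5
        assert mesh.volume() == pytest.approx(expected, rel=1e-12)

    def test_mesh_invariants_hold(self):
        mesh = box_mesh(4, 2, 2, 0.5, 100.0, 0.3)
        mesh.check()  # jacobians, midpoints, orphans

    def test_voxel_mesh_volume_matches_mask_at_native_edge(self):
        rng = np.random.default_rng(1)
        vals = rng.random((8, 8, 8)) > 0.5
        mask = Mask(vals, 0.5, (0, 0, 0))
        cal = DensityCalibration()
        mesh = voxels_to_tet10(mask, np.full(vals.shape, 1000.0), 0.5, cal)
        assert mesh.volume() == pytest.approx(mask.volume_mm3(), abs=1e-9)

    def test_uniform_density_gives_uniform_modulus(self):
        vals = np.ones((6, 6, 6), dtype=bool)
        mask = Mask(vals, 0.5, (0, 0, 0))
        mesh = voxels_to_tet10(mask, np.full(vals.shape, 800.0), 1.0, DensityCalibration())
        assert np.ptp(mesh.element_modulus) == 0

    def test_empty_mask_rejected(self):
        mask = Mask(np.zeros((4, 4, 4), dtype=bool), 1.0, (0, 0, 0))
        with pytest.raises(ValueError, match="empty"):
            voxels_to_tet10(mask, np.zeros((4, 4, 4)), 1.0, DensityCalibration())

    def test_boundary_faces_of_cube(self):
        mesh = blocks_to_tet10(np.array([[0, 0, 0]]), 1.0, (0, 0, 0), 1.0, 0.3)
        faces = boundary_faces(mesh)
        assert faces.shape[0] == 12  # 2 triangles per cube face
        tri = mesh.nodes[faces[:, :3]]
        area = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        ).sum()
        assert area == pytest.approx(6.0, rel=1e-12)


class TestStiffness:
    def test_rigid_modes_are_zero_energy(self):
        mesh = box_mesh(2, 1, 1, 0.5, 2000.0, 0.3)
        K = assemble(mesh)
        X = mesh.nodes
        scale = abs(K.data).max()
        for u in (
            np.tile([1.0, -2.0, 0.5], (mesh.n_nodes, 1)),
            np.cross(np.array([0.3, 0.2, 0.9]), X - X.mean(0)),
        ):
            assert np.abs(K @ u.ravel()).max() / scale < 1e-8

    def test_patch_test_constant_strain_exact(self):
        mesh = box_mesh(1, 1, 1, 0.5, 2000.0, 0.3)
        A = np.array([[1e-3, 2e-4, -1e-4], [3e-4, -5e-4, 2e-4], [1e-4, 1e-4, 8e-4]])
        u = mesh.nodes @ A.T
        s = tet10.centroid_stress(
            mesh.nodes[mesh.elements], u[mesh.elements],
            mesh.element_modulus, mesh.element_poisson,
        )
        eps = 0.5 * (A + A.T)
        voigt = np.array([eps[0, 0], eps[1, 1], eps[2, 2],
                          2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[0, 2]])
        exact = tet10.elasticity_matrix(2000.0, 0.3) @ voigt
        assert np.abs(s - exact).max() < 1e-10 * np.abs(exact).max()

    def test_stiffness_scales_linearly_with_modulus(self):
        m1 = box_mesh(2, 1, 1, 0.5, 1000.0, 0.3)
        m2 = box_mesh(2, 1, 1, 0.5, 3000.0, 0.3)
        K1, K2 = assemble(m1), assemble(m2)
        assert abs(K2 - 3.0 * K1).max() < 1e-9 * abs(K1).max()

    def test_energy_nonnegative(self):
        mesh = box_mesh(2, 1, 1, 0.5, 500.0, 0.4)
        K = assemble(mesh)
        rng = np.random.default_rng(3)
        for _ in range(5):
            u = rng.normal(size=3 * mesh.n_nodes)
            assert u @ (K @ u) >= -1e-9


class TestSolve:
    def test_identity_step_is_stress_free(self, cantilever):
        res = cantilever["system"].solve_step(RigidTransform.identity())
        assert np.abs(res.nodal_displacements).max() < 1e-12
        assert np.abs(res.element_stress).max() < 1e-12

    def test_cantilever_reaction_matches_beam_theory(self, cantilever):
        p = cantilever
        I = p["b"] * p["h"] ** 3 / 12
        M_theory = 3 * p["E"] * I * p["delta"] / p["L"] ** 2
        f = p["result"].nodal_internal_forces
        base = p["mesh"].nodes[p["fixed"]]
        M = np.cross(base - base.mean(0), f[p["fixed"]]).sum(0)
        assert abs(M[1]) == pytest.approx(M_theory, rel=0.05)

    def test_global_equilibrium(self, cantilever):
        f = cantilever["result"].nodal_internal_forces
        assert np.abs(f.sum(0)).max() <= 1e-6 * np.abs(f).max() * len(f) ** 0.5

    def test_reactions_balance_between_supports(self, cantilever):
        f = cantilever["result"].nodal_internal_forces
        Rf = f[cantilever["fixed"]].sum(0)
        Rd = f[cantilever["tip"]].sum(0)
        interior = np.setdiff1d(
            np.arange(len(f)), np.concatenate([cantilever["fixed"], cantilever["tip"]])
        )
        assert np.abs(f[interior]).max() < 1e-6 * np.abs(f).max()
        np.testing.assert_allclose(Rf, -Rd, atol=1e-6 * np.abs(f).max())

    def test_response_linear_in_imposed_displacement(self, cantilever):
        system = cantilever["system"]
        res2 = system.solve_step(RigidTransform(np.eye(3), [0, 0, 2 * cantilever["delta"]]))
        ref = 2 * cantilever["result"].element_stress
        np.testing.assert_allclose(
            res2.element_stress, ref, rtol=1e-9, atol=1e-9 * np.abs(ref).max()
        )

    def test_linear_step_ramp_scales_exactly(self, cantilever):
        system = cantilever["system"]
        T = RigidTransform(np.eye(3), [0, 0, cantilever["delta"]])
        from phalanxfem.kinematics import make_displacement_steps

        results = system.solve_steps(make_displacement_steps(T, n=5), mode="linear")
        u5 = results[-1].nodal_displacements
        for k, res in enumerate(results, start=1):
            np.testing.assert_allclose(
                res.nodal_displacements, (k / 5) * u5, rtol=0, atol=1e-15
            )

    def test_unconstrained_solve_rejected(self):
        mesh = box_mesh(2, 1, 1, 0.5, 100.0, 0.3)
        system = FESystem(mesh)
        with pytest.raises(ValueError, match="constraints"):
            system.solve_step(RigidTransform.identity())

    def test_incremental_mode_matches_linear_for_tiny_motion(self, cantilever):
        from phalanxfem.kinematics import make_displacement_steps

        system = cantilever["system"]
        T = RigidTransform(np.eye(3), [0, 0, 1e-4])
        steps = make_displacement_steps(T, n=2)
        lin = system.solve_steps(steps, mode="linear")[-1]
        inc = system.solve_steps(steps, mode="incremental")[-1]
        np.testing.assert_allclose(
            inc.nodal_displacements, lin.nodal_displacements,
            atol=1e-9 + 1e-4 * np.abs(lin.nodal_displacements).max(),
        )


class TestContact:
    def test_penalty_plane_stops_penetration(self):
        """Driving a block toward a contact plane: without contact the face
        crosses it; with the penalty it stops at the plane (to the penalty
        compliance)."""
        from phalanxfem.fem.system import ContactPlane

        mesh = box_mesh(2.0, 1.0, 1.0, 0.5, 1000.0, 0.3)
        system = FESystem(mesh)
        x = mesh.nodes[:, 0]
        left = np.nonzero(x < 1e-9)[0]
        right = np.nonzero(x > 2.0 - 1e-9)[0]
        # drive the left face +1.0 in x (all DOFs); the right face is free
        system.set_constraints(np.zeros(0, dtype=int), left)
        plane = ContactPlane(right, point=(2.5, 0.0, 0.0), normal=(-1.0, 0.0, 0.0))
        T = RigidTransform(np.eye(3), (1.0, 0.0, 0.0))
        free_res = system.solve_step(T)
        x_free = (mesh.nodes + free_res.nodal_displacements)[right, 0]
        assert x_free.max() > 2.9  # penetrates without contact
        res = system.solve_step(T, contact=[plane])
        x_contact = (mesh.nodes + res.nodal_displacements)[right, 0]
        assert x_contact.max() <= 2.5 + 1e-3  # stopped at the plane
        # contact reaction is compressive on the block
        assert res.nodal_internal_forces[right, 0].sum() < 0

    def test_inactive_contact_changes_nothing(self, cantilever):
        from phalanxfem.fem.system import ContactPlane

        p = cantilever
        plane = ContactPlane(p["tip"], point=(50.0, 0, 0), normal=(-1.0, 0, 0))
        T = RigidTransform(np.eye(3), [0, 0, p["delta"]])
        res = p["system"].solve_step(T, contact=[plane])
        np.testing.assert_allclose(
            res.nodal_displacements, p["result"].nodal_displacements, atol=1e-12
        )


class TestTies:
    @staticmethod
    def _tied_pair():
        """Two stacked boxes with coincident interface nodes, tied node-to-node."""
        a = box_mesh(2.0, 1.0, 1.0, 0.5, 1000.0, 0.3)
        b = box_mesh(2.0, 1.0, 1.0, 0.5, 1000.0, 0.3)
        b.nodes = b.nodes + np.array([2.0, 0.0, 0.0])
        combined = combine_meshes(a, b, "a", "b")
        an = combined.node_sets["a_nodes"]
        bn = combined.node_sets["b_nodes"]
        ai = an[np.abs(combined.nodes[an, 0] - 2.0) < 1e-9]
        bi = bn[np.abs(combined.nodes[bn, 0] - 2.0) < 1e-9]
        from scipy.spatial import cKDTree

        d, j = cKDTree(combined.nodes[ai]).query(combined.nodes[bi])
        assert d.max() < 1e-9
        ties = np.column_stack([bi, ai[j]])
        return combined, ties

    def test_tie_count_is_three_dofs_per_slave(self):
        combined, ties = self._tied_pair()
        system = FESystem(combined, ties)
        assert system.K_red.shape[0] == 3 * (combined.n_nodes - len(ties))

    def test_tied_coincident_matches_merged_mesh(self):
        combined, ties = self._tied_pair()
        system = FESystem(combined, ties)
        x = combined.nodes[:, 0]
        system.set_constraints(
            np.nonzero(x < 1e-9)[0], np.nonzero(x > 4.0 - 1e-9)[0]
        )
        T = RigidTransform.from_axis_angle((0, 1, 0), 0.5, (0.01, 0.0, 0.05))
        res = system.solve_step(T)

        merged = box_mesh(4.0, 1.0, 1.0, 0.5, 1000.0, 0.3)
        msys = FESystem(merged)
        mx = merged.nodes[:, 0]
        msys.set_constraints(
            np.nonzero(mx < 1e-9)[0], np.nonzero(mx > 4.0 - 1e-9)[0]
        )
        mres = msys.solve_step(T)

        # compare displacements at matching coordinates
        from scipy.spatial import cKDTree

        tree = cKDTree(merged.nodes)
        d, j = tree.query(combined.nodes)
        assert d.max() < 1e-9
        scale = np.abs(mres.nodal_displacements).max()
        assert np.abs(
            res.nodal_displacements - mres.nodal_displacements[j]
        ).max() < 1e-8 * scale

    def test_rigid_motion_of_tied_assembly_is_zero_energy(self):
        combined, ties = self._tied_pair()
        system = FESystem(combined, ties)
        X = combined.nodes
        u = np.cross(np.array([0.1, 0.4, 0.2]), X - X.mean(0)) + np.array([1.0, -0.5, 0.2])
        # coincident slave/master nodes see identical rigid displacements
        e = u.ravel() @ (system.K @ u.ravel())
        assert abs(e) < 1e-8 * abs(system.K.data).max()

    def test_duplicate_slave_rejected(self):
        combined, ties = self._tied_pair()
        bad = np.vstack([ties, ties[:1]])
        with pytest.raises(ValueError, match="slave"):
            FESystem(combined, bad)
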