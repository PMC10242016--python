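"""FEM solver: Kuhn meshing, assembly, analytic conduction oracles."""

import numpy as np
import pytest
import scipy.sparse as sp

from ctistim import mesh_fem, phantom
from ctistim.containers import Grid, LabelVolume, TensorMap


def _box_labels(shape, h=2.0):
    grid = Grid(shape, (h, h, h), (0.0, 0.0, 0.0))
    return LabelVolume(grid, np.ones(shape, np.int16), {0: "air", 1: "scalp"})


class TestMesh:
    def test_single_voxel_splits_into_six_tets_conserving_volume(self):
        mesh = mesh_fem.build_mesh(_box_labels((1, 1, 1), h=2.0))
        vols = mesh.element_volumes()
        assert len(vols) == 6
        assert np.all(vols > 0)
        assert np.isclose(vols.sum(), 8.0, rtol=1e-14)

    def test_element_count_six_per_nonair_voxel(self, small_labels):
        mesh = mesh_fem.build_mesh(small_labels)
        n_head = int((small_labels.labels != 0).sum())
        elems, owner = mesh.tetrahedra()
        assert len(elems) == 6 * n_head
        assert mesh.n_voxels == n_head

    def test_all_elements_positive_volume(self, small_labels):
        mesh = mesh_fem.build_mesh(small_labels)
        assert np.all(mesh.element_volumes() > 0)

    def test_element_quality_uniform_for_regular_grid(self):
        mesh = mesh_fem.build_mesh(_box_labels((2, 2, 2)))
        q = mesh.element_quality()
        assert np.all((q > 0) & (q <= 1.0))
        assert np.allclose(q, q[0])  # all Kuhn tets congruent on a cubic grid

    def test_montage_without_exposed_faces_rejected(self, small_labels):
        lab = small_labels.copy()
        m = phantom.place_electrodes_1020(lab, ("Cz", "O1"), pad_size_mm=(20.0, 20.0))
        # meshing the *pristine* labels loses the electrode voxels
        with pytest.raises(ValueError, match="attach"):
            mesh_fem.build_mesh(small_labels, m)


class TestAssembly:
    def test_constant_vector_in_null_space(self):
        prob = mesh_fem.box_problem((4, 4, 4), (2.0, 2.0, 2.0), 0.3, 1e-3)
        system = mesh_fem.assemble_system(prob, cathode_dirichlet=False)
        v = np.ones(system.K.shape[0])
        assert np.allclose(system.K @ v, 0.0, atol=1e-12)

    def test_load_vector_sums_to_zero_with_both_electrodes_neumann(self):
        prob = mesh_fem.box_problem((4, 4, 4), (2.0, 2.0, 2.0), 0.3, 1e-3)
        system = mesh_fem.assemble_system(prob, cathode_dirichlet=False)
        assert np.isclose(system.f.sum(), 0.0, atol=1e-18)
        assert np.isclose(system.f[system.f > 0].sum(), 1e-3, rtol=1e-12)

    def test_stiffness_matches_hand_assembled_p1_elements(self):
        """Composite per-voxel assembly equals element-by-element P1 assembly."""
        sigma = 0.7
        prob = mesh_fem.box_problem((1, 1, 1), (2.0, 3.0, 1.5), sigma, 1e-3)
        system = mesh_fem.assemble_system(prob, cathode_dirichlet=False)
        mesh = prob.mesh
        elems, _ = mesh.tetrahedra()
        K_ref = np.zeros((mesh.n_nodes, mesh.n_nodes))
        for tet in elems:
            x = mesh.node_coords[tet]  # mm
            E = (x[1:] - x[0]).T
            V = np.linalg.det(E) / 6.0
            G = np.zeros((3, 4))
            G[:, 1:] = np.linalg.inv(E).T
            G[:, 0] = -G[:, 1:].sum(axis=1)
            K_ref[np.ix_(tet, tet)] += sigma * V * (G.T @ G) * 1e-3  # mm -> SI
        assert np.allclose(system.K.toarray(), K_ref, rtol=1e-12, atol=1e-15)

    def test_non_psd_tensor_rejected_with_location(self):
        shape = (2, 2, 2)
        grid = Grid(shape, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
        full = np.tile(np.eye(3), shape + (1, 1)) * 0.3
        full[1, 0, 1] = np.diag([0.3, -0.2, 0.3])
        C = TensorMap.from_full(grid, full, np.ones(shape, bool))
        labels = LabelVolume(grid, np.ones(shape, np.int16), {0: "air", 1: "scalp"})
        mesh = mesh_fem.build_mesh(labels)
        prob = mesh_fem.StimulationProblem(
            mesh=mesh, conductivity=C,
            anode=mesh_fem.plate_faces(mesh, 2, 1),
            cathode=mesh_fem.plate_faces(mesh, 2, -1), current_I=1e-3,
        )
        with pytest.raises(ValueError, match="positive-semidefinite"):
            mesh_fem.assemble_system(prob)


class TestSolve:
    def test_slab_ohms_law(self):
        sigma, I = 0.14, 2e-3
        shape, h = (10, 10, 20), 2.0
        prob = mesh_fem.box_problem(shape, (h, h, h), sigma, I)
        sol = mesh_fem.solve_problem(prob)
        A = shape[0] * shape[1] * h * h * 1e-6
        L = shape[2] * h * 1e-3
        assert np.isclose(sol.u.max(), I * L / (sigma * A), rtol=1e-2)
        Jm = sol.J_mag[sol.mask]
        assert np.abs(Jm - I / A).max() / (I / A) < 0.01

    def test_linearity_in_current(self):
        prob1 = mesh_fem.box_problem((6, 6, 6), (2.0, 2.0, 2.0), 0.3, 1e-3)
        prob2 = mesh_fem.box_problem((6, 6, 6), (2.0, 2.0, 2.0), 0.3, 2e-3)
        u1, _ = mesh_fem.solve_potential(mesh_fem.assemble_system(prob1), rel_tol=1e-10)
        u2, _ = mesh_fem.solve_potential(mesh_fem.assemble_system(prob2), rel_tol=1e-10)
        assert np.allclose(u2, 2.0 * u1, atol=1e-8)

    def test_zero_load_gives_zero_potential(self):
        prob = mesh_fem.box_problem((4, 4, 4), (2.0, 2.0, 2.0), 0.3, 1e-3)
        system = mesh_fem.assemble_system(prob)
        system.f[:] = 0.0
        u, diag = mesh_fem.solve_potential(system)
        assert np.all(u == 0.0)
        assert diag["iterations"] == 0

    def test_determinism(self):
        prob = mesh_fem.box_problem((6, 6, 12), (2.0, 2.0, 2.0), 0.14, 2e-3)
        u1, _ = mesh_fem.solve_potential(mesh_fem.assemble_system(prob))
        u2, _ = mesh_fem.solve_potential(mesh_fem.assemble_system(prob))
        assert np.array_equal(u1, u2)

    def test_isotropic_conductivity_gives_parallel_j_and_e(self):
        prob = mesh_fem.box_problem((6, 6, 10), (2.0, 2.0, 2.0), 0.3, 1e-3,
                                    patch_half_voxels=2)
        sol = mesh_fem.solve_problem(prob)
        E = sol.E[sol.mask]
        J = sol.J[sol.mask]
        cross = np.linalg.norm(np.cross(E, J), axis=1)
        assert np.all(cross <= 1e-9 * np.linalg.norm(E, axis=1) * np.linalg.norm(J, axis=1) + 1e-30)

    def test_two_layer_series_slab(self):
        s1, s2, I = 0.14, 0.47, 2e-3
        shape, h = (8, 8, 16), 2.0
        field = np.full(shape, s1)
        field[:, :, 8:] = s2
        prob = mesh_fem.box_problem(shape, (h, h, h), field, I)
        sol = mesh_fem.solve_problem(prob)
        A = shape[0] * shape[1] * h * h * 1e-6
        Jz = -sol.J[..., 2][sol.mask]
        assert np.abs(Jz - I / A).max() / (I / A) < 0.01  # normal J continuous
        # E jumps by the conductivity ratio across the interface
        E_bot = sol.E_mag[:, :, :8].mean()
        E_top = sol.E_mag[:, :, 8:].mean()
        assert np.isclose(E_bot / E_top, s2 / s1, rtol=0.01)

    def test_mesh_refinement_reduces_patch_resistance_error(self):
        """Spreading resistance converges monotonically under refinement."""
        sigma, I = 0.3, 1e-3
        L = 24.0  # box edge, mm

        def resistance(n):
            h = L / n
            prob = mesh_fem.box_problem((n, n, n), (h, h, h), sigma, I,
                                        patch_half_voxels=max(1, n // 6))
            sol = mesh_fem.solve_problem(prob, rel_tol=1e-10)
            return float(sol.u[prob.anode.unique_nodes()].mean()) / I

        coarse = [resistance(n) for n in (6, 12, 18)]
        ref = resistance(30)
        errs = [abs(r - ref) for r in coarse]
        assert errs[0] > errs[1] > errs[2]


class TestConservationAndReciprocity:
    def test_anode_flux_and_net_flux_on_slab(self):
        prob = mesh_fem.box_problem((10, 10, 20), (2.0, 2.0, 2.0), 0.14, 2e-3)
        sol = mesh_fem.solve_problem(prob)
        rep = mesh_fem.check_current_conservation(sol, prob)
        assert 0.99 <= rep["anode_flux_ratio"] <= 1.01
        assert abs(rep["net_flux_fraction"]) <= 0.01

    def test_electrode_swap_negates_potential(self):
        prob = mesh_fem.box_problem((8, 8, 12), (2.0, 2.0, 2.0), 0.3, 1e-3,
                                    patch_half_voxels=2)
        swapped = mesh_fem.StimulationProblem(
            mesh=prob.mesh, conductivity=prob.conductivity,
            anode=prob.cathode, cathode=prob.anode, current_I=prob.current_I,
        )
        u1, _ = mesh_fem.solve_potential(mesh_fem.assemble_system(prob, cathode_dirichlet=False))
        u2, _ = mesh_fem.solve_potential(mesh_fem.assemble_system(swapped, cathode_dirichlet=False))
        assert np.allclose(u1, -u2, atol=1e-3 * np.abs(u1).max())


class TestAnisotropy:
    def test_stretch_equivalence(self):
        """diag(a,b,c) box resistance equals the coordinate-scaled isotropic
        solve divided by sqrt(det C), within 2%."""
        I = 1e-3
        n, h = 10, 2.0
        diag = np.array([0.6, 0.3, 0.15])
        tens = np.zeros((n, n, n, 3, 3))
        tens[...] = np.diag(diag)
        probA = mesh_fem.box_problem((n, n, n), (h, h, h), tens, I, patch_half_voxels=2)
        solA = mesh_fem.solve_problem(probA, rel_tol=1e-10)
        R_aniso = float(solA.u[probA.anode.unique_nodes()].mean()) / I
        scale = 1.0 / np.sqrt(diag)
        probI = mesh_fem.box_problem((n, n, n), tuple(h * s for s in scale), 1.0, I,
                                     patch_half_voxels=2)
        solI = mesh_fem.solve_problem(probI, rel_tol=1e-10)
        R_iso = float(solI.u[probI.anode.unique_nodes()].mean()) / I
        assert abs(R_aniso - R_iso / np.sqrt(np.prod(diag))) / R_aniso < 0.02

    def test_energy_identity(self):
        prob = mesh_fem.box_problem((8, 8, 16), (2.0, 2.0, 2.0), 0.14, 2e-3)
        sol = mesh_fem.solve_problem(prob)
        C = prob.element_tensors()
        Ev = sol.E.reshape(-1, 3)[prob.mesh.voxel_flat]
        energy = float(np.einsum("vi,vij,vj->", Ev, C, Ev) * prob.mesh.grid.voxel_volume * 1e-9)
        I_du = prob.current_I * float(sol.u[prob.anode.unique_nodes()].mean())
        assert abs(energy - I_du) / I_du < 0.01


class TestCondensedElectrodes:
    def test_condensed_matches_high_conductivity_elements(self, small_labels):
        """Equipotential condensation agrees with meshing the plate at
        5.99e7 S/m (solved at coarse tolerance) to well under a percent."""
        from ctistim import cti_recon

        lab = small_labels.copy()
        m = phantom.place_electrodes_1020(lab, ("Cz", "O1"), pad_size_mm=(20.0, 20.0))
        C = cti_recon.assign_isotropic(lab)
        mesh = mesh_fem.build_mesh(lab, m)
        p_cond = mesh_fem.montage_problem(mesh, C, m, condense_electrodes=True)
        p_full = mesh_fem.montage_problem(mesh, C, m, condense_electrodes=False)
        sol_c = mesh_fem.solve_problem(p_cond, rel_tol=1e-8)
        sol_f = mesh_fem.solve_problem(p_full, rel_tol=2e-5)  # attainable-accuracy limit
        brain = lab.mask("GM", "WM")
        jc, jf = sol_c.J_mag[brain], sol_f.J_mag[brain]
        assert np.abs(jc - jf).max() / jc.max() < 5e-3
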