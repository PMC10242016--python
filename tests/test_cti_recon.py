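"""Conductivity tensor reconstruction: eta formula, assignments, DWI fit round trips."""

import numpy as np
import pytest

from ctistim import cti_recon, phantom
from ctistim.containers import Grid, LabelVolume, TensorMap


def _scalar(x):
    return np.asarray(float(x))


class TestEta:
    def test_worked_example_four_significant_figures(self):
        # (1-0.4)*0.5 / (0.4*0.41*2e-3 + 0.6*1.5e-3) = 0.3 / 1.228e-3
        eta = cti_recon.eta_scale(_scalar(0.5), _scalar(0.4), _scalar(2.0e-3), _scalar(1.5e-3), 0.41)
        assert np.isclose(float(eta), 0.3 / 1.228e-3, rtol=1e-12)
        assert abs(float(eta) - 244.3) < 0.05

    def test_collapse_at_zero_intracellular_fraction(self):
        eta = cti_recon.eta_scale(_scalar(0.5), _scalar(0.0), _scalar(2.0e-3), _scalar(1.5e-3), 0.41)
        assert np.isclose(float(eta), 0.5 / 1.5e-3, rtol=1e-15)

    def test_vanishes_as_v_int_approaches_one(self):
        vs = np.array([0.9, 0.99, 0.999, 1.0 - 1e-12])
        eta = cti_recon.eta_scale(np.full(4, 0.5), vs, np.full(4, 2e-3), np.full(4, 1.5e-3), 0.41)
        assert np.all(np.diff(eta) < 0)
        assert eta[-1] < 1e-9

    def test_strictly_increasing_in_sigma_h(self):
        sig = np.linspace(0.1, 2.0, 50)
        eta = cti_recon.eta_scale(sig, np.full(50, 0.4), np.full(50, 2e-3), np.full(50, 1.5e-3), 0.41)
        assert np.all(np.diff(eta) > 0)

    def test_nonpositive_denominator_flagged_not_raised(self, caplog):
        shape = (2, 2, 2)
        lam_ext = np.full(shape, 1.5e-3)
        lam_ext[0, 0, 0] = -2.0e-3  # nonphysical input
        v = np.full(shape, 0.0)
        em = cti_recon.compute_eta(np.full(shape, 0.5), v, np.full(shape, 2e-3), lam_ext)
        assert not em.mask[0, 0, 0]
        assert em.mask.sum() == 7
        assert em.eta[0, 0, 0] == 0.0

    def test_beta_must_be_positive(self):
        with pytest.raises(ValueError, match="beta"):
            cti_recon.compute_eta(np.ones((1, 1, 1)), np.zeros((1, 1, 1)),
                                  np.ones((1, 1, 1)), np.ones((1, 1, 1)), beta=0.0)


class TestReconstructTensor:
    def test_scaling_of_eigenvalues_and_units(self):
        # eta = 244.3 on D with eigenvalues (2.7, 0.9, 0.9)e-3 mm^2/s gives
        # C eigenvalues (0.660, 0.220, 0.220) S/m
        grid = Grid((1, 1, 1), (1, 1, 1), (0, 0, 0))
        D_full = np.diag([2.7e-3, 0.9e-3, 0.9e-3])[None, None, None]
        D = TensorMap.from_full(grid, D_full, np.ones(grid.shape, bool), "mm^2/s")
        eta_val = 0.3 / 1.228e-3
        em = cti_recon.EtaMap(grid, np.full(grid.shape, eta_val), 0.41, np.ones(grid.shape, bool))
        C = cti_recon.reconstruct_tensor(em, D)
        ev = np.sort(np.linalg.eigvalsh(C.full()[0, 0, 0]))[::-1]
        assert np.allclose(ev, [0.660, 0.220, 0.220], atol=5e-4)
        assert C.units == "S/m"

    def test_zero_eta_gives_zero_tensor(self):
        grid = Grid((2, 2, 2), (1, 1, 1), (0, 0, 0))
        D = TensorMap.isotropic(grid, np.full(grid.shape, 1.5e-3), np.ones(grid.shape, bool))
        em = cti_recon.EtaMap(grid, np.zeros(grid.shape), 0.41, np.ones(grid.shape, bool))
        C = cti_recon.reconstruct_tensor(em, D)
        assert np.allclose(C.components, 0.0)

    def test_collapse_recovers_high_frequency_conductivity(self):
        # v_int = 0 and isotropic D: C = sigma_H * I to machine precision
        grid = Grid((3, 3, 3), (1, 1, 1), (0, 0, 0))
        sigma = np.full(grid.shape, 0.5)
        lam_ext = np.full(grid.shape, 1.5e-3)
        em = cti_recon.compute_eta(sigma, np.zeros(grid.shape), np.full(grid.shape, 2e-3), lam_ext, grid=grid)
        D = TensorMap.isotropic(grid, lam_ext, np.ones(grid.shape, bool))
        C = cti_recon.reconstruct_tensor(em, D)
        eye_comp = np.zeros(6)
        eye_comp[[0, 3, 5]] = 0.5
        assert np.allclose(C.components, eye_comp, rtol=1e-14, atol=1e-16)

    def test_eigenvectors_preserved_and_psd(self):
        rng = np.random.default_rng(11)
        grid = Grid((4, 4, 4), (1, 1, 1), (0, 0, 0))
        A = rng.normal(size=grid.shape + (3, 3))
        D_full = np.einsum("...ik,...jk->...ij", A, A) * 1e-3  # PSD by construction
        D = TensorMap.from_full(grid, D_full, np.ones(grid.shape, bool))
        eta = rng.uniform(0, 300, grid.shape)
        em = cti_recon.EtaMap(grid, eta, 0.41, np.ones(grid.shape, bool))
        C = cti_recon.reconstruct_tensor(em, D)
        assert np.all(C.eigenvalues() >= -1e-12)
        # shared eigenvectors: C and D commute
        comm = np.einsum("...ij,...jk->...ik", C.full(), D.full()) - np.einsum(
            "...ij,...jk->...ik", D.full(), C.full()
        )
        assert np.allclose(comm, 0.0, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        g1 = Grid((2, 2, 2), (1, 1, 1), (0, 0, 0))
        g2 = Grid((3, 3, 3), (1, 1, 1), (0, 0, 0))
        D = TensorMap.isotropic(g2, np.ones(g2.shape), np.ones(g2.shape, bool))
        em = cti_recon.EtaMap(g1, np.ones(g1.shape), 0.41, np.ones(g1.shape, bool))
        with pytest.raises(ValueError, match="grid"):
            cti_recon.reconstruct_tensor(em, D)


class TestAssignments:
    def test_isotropic_literature_values(self, small_labels):
        C = cti_recon.assign_isotropic(small_labels)
        for tissue, sigma in (("WM", 0.14), ("CSF", 1.79), ("air", 1e-15)):
            m = small_labels.mask(tissue)
            assert np.allclose(C.components[m][:, [0, 3, 5]], sigma)
            assert np.allclose(C.components[m][:, [1, 2, 4]], 0.0)

    def test_unknown_label_named(self, small_labels):
        table = dict(cti_recon.TISSUE_CONDUCTIVITY)
        del table["skull"]
        with pytest.raises(KeyError, match="skull"):
            cti_recon.assign_isotropic(small_labels, table)

    def test_hybrid_rules(self, small_labels, small_truth):
        _, C_true = small_truth
        lab = small_labels.copy()
        m = phantom.place_electrodes_1020(lab, ("Cz", "O1"), pad_size_mm=(20.0, 20.0))
        hyb = cti_recon.hybrid_assignment(lab, C_true)
        scalp = lab.mask("scalp")
        assert np.allclose(hyb.components[scalp][:, [0, 3, 5]], 0.47)
        wm = lab.mask("WM")
        assert np.array_equal(hyb.components[wm], C_true.components[wm])
        sponge = lab.mask("sponge")
        assert np.allclose(hyb.components[sponge][:, [0, 3, 5]], 1.00)
        electrode = lab.mask("electrode")
        assert np.allclose(hyb.components[electrode][:, [0, 3, 5]], 5.99e7)

    def test_hybrid_falls_back_on_invalid_brain_voxels(self, small_labels, small_truth):
        _, C_true = small_truth
        broken = TensorMap(C_true.grid, C_true.components.copy(), C_true.mask.copy())
        wm_idx = np.argwhere(small_labels.mask("WM"))[0]
        broken.mask[tuple(wm_idx)] = False
        hyb = cti_recon.hybrid_assignment(small_labels, broken)
        assert np.allclose(hyb.components[tuple(wm_idx)][[0, 3, 5]], 0.14)


def _single_voxel_dwi(v, lam, fiber, D_full, bvals=None, bvecs=None):
    if bvals is None:
        bvals, bvecs = phantom.two_shell_scheme()
    frac = phantom.dwi_forward_model(
        np.array([v]), np.array([lam]), np.array(fiber)[None], D_full[None], bvals, bvecs
    )
    grid = Grid((1, 1, 1), (1, 1, 1), (0, 0, 0))
    return phantom.DWISet(
        grid=grid, signals=frac.reshape(1, 1, 1, -1), bvals=bvals, bvecs=bvecs,
        mask=np.ones(grid.shape, bool),
    )


class TestTwoCompartmentFit:
    def test_pure_extracellular_voxel(self):
        # v_int = 0 and isotropic D: recover v <= 0.02, MD within 2%
        dwi = _single_voxel_dwi(0.0, 2.0e-3, [np.nan] * 3, 1.5e-3 * np.eye(3))
        fit = cti_recon.fit_two_compartment(dwi)
        assert fit.mask[0, 0, 0]
        assert fit.v_int[0, 0, 0] <= 0.02
        assert abs(fit.lam_ext[0, 0, 0] - 1.5e-3) / 1.5e-3 < 0.02

    def test_stick_plus_tensor_voxel(self):
        f = np.array([0.6, 0.0, 0.8])
        t = 3 * 1.5e-3 / 5.0
        D = t * np.eye(3) + (3 * t - t) * np.outer(f, f)
        dwi = _single_voxel_dwi(0.4, 2.0e-3, f, D)
        fit = cti_recon.fit_two_compartment(dwi)
        assert abs(fit.v_int[0, 0, 0] - 0.4) <= 0.05
        w, V = np.linalg.eigh(fit.D_e.full()[0, 0, 0])
        angle = np.degrees(np.arccos(np.clip(abs(V[:, 2] @ f), 0, 1)))
        assert angle < 5.0

    def test_duplicate_directions_do_not_change_estimates(self):
        f = np.array([0.0, 0.6, 0.8])
        t = 0.9e-3
        D = t * np.eye(3) + 2 * t * np.outer(f, f)
        bvals, bvecs = phantom.two_shell_scheme()
        dwi1 = _single_voxel_dwi(0.5, 2.0e-3, f, D, bvals, bvecs)
        bvals2 = np.concatenate([bvals, bvals[1:]])
        bvecs2 = np.concatenate([bvecs, bvecs[1:]])
        dwi2 = _single_voxel_dwi(0.5, 2.0e-3, f, D, bvals2, bvecs2)
        fit1 = cti_recon.fit_two_compartment(dwi1)
        fit2 = cti_recon.fit_two_compartment(dwi2)
        assert np.allclose(fit1.v_int, fit2.v_int, atol=1e-6)
        assert np.allclose(fit1.lam, fit2.lam, atol=1e-8)
        assert np.allclose(fit1.D_e.components, fit2.D_e.components, atol=1e-8)

    def test_all_zero_voxel_masked_not_raised(self, small_dwi):
        sig = small_dwi.signals.copy()
        sig[0, 0, 0] = 0.0
        dwi = phantom.DWISet(grid=small_dwi.grid, signals=sig, bvals=small_dwi.bvals,
                             bvecs=small_dwi.bvecs)
        fit = cti_recon.fit_two_compartment(dwi)
        assert not fit.mask[0, 0, 0]

    def test_single_shell_rejected(self):
        bvals = np.concatenate([[0.0], np.full(30, 800.0)])
        bvecs = np.concatenate([np.zeros((1, 3)),
                                phantom.two_shell_scheme(n_inner=30)[1][1:31]])
        grid = Grid((1, 1, 1), (1, 1, 1), (0, 0, 0))
        dwi = phantom.DWISet(grid=grid, signals=np.ones((1, 1, 1, 31)), bvals=bvals, bvecs=bvecs)
        with pytest.raises(ValueError, match="shell"):
            cti_recon.fit_two_compartment(dwi)


class TestRoundTrip:
    def test_reconstruction_matches_ground_truth(self, small_labels, small_maps, small_truth, small_fit):
        """Noiseless round trip: phantom truth vs reconstructed C within 5%
        Frobenius relative error on >= 95% of brain voxels."""
        D_true, C_true = small_truth
        fit = small_fit
        em = cti_recon.compute_eta(
            small_maps.sigma_H, fit.v_int, fit.lam, fit.lam_ext,
            mask=fit.mask, grid=fit.grid,
        )
        C_est = cti_recon.reconstruct_tensor(em, fit.D_e)
        m = small_maps.mask
        num = np.linalg.norm(C_est.components[m] - C_true.components[m], axis=1)
        den = np.linalg.norm(C_true.components[m], axis=1)
        frac_ok = float(((num / den) < 0.05).mean())
        assert frac_ok >= 0.95
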