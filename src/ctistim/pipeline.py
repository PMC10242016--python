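"""End-to-end orchestration: phantom -> DWI -> reconstruction -> FEM -> report.

A :class:`RunConfig` (YAML-serializable, unknown keys rejected) drives
:func:`run_full`, which generates the phantom, simulates and refits the
diffusion data, assembles the tensor-based and isotropic conductivity
models, solves every montage/model combination, and writes ROI/rD/slice
reports plus a manifest into a run directory.  :func:`validate_suite` runs
the battery of analytic oracles (slab, two-layer, anisotropy stretch,
conservation, reciprocity, conductivity-formula collapses, rD hand cases)
and reports pass/fail per check.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import cti_recon, io, mesh_fem, phantom, response
from .containers import TensorMap

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full", "validate_suite", "stage_seed"]


@dataclass
class RunConfig:
    """All knobs of a full run, with explicit defaults.

    The defaults mirror the study conditions: 80 mm phantom at 2 mm
    voxels, montages C3-FP2 and F4-F3 with 2 mA injected current, two-shell
    DWI (b = 800/2,200 s/mm^2), beta = 0.41, solver tolerance 1e-6.
    """

    outer_radius_mm: float = 80.0
    voxel_size_mm: float = 2.0
    layer_thicknesses: dict = field(
        default_factory=lambda: dict(phantom.DEFAULT_LAYERS)
    )
    fiber_model: str = "radial"
    montages: list = field(default_factory=lambda: ["C3-FP2", "F4-F3"])
    current_I: float = 2.0e-3
    beta: float = 0.41
    solver_rel_tol: float = 1.0e-6
    seed: int = 0
    snr: Optional[float] = None
    model: str = "both"  # cti | isotropic | both
    include_csf: bool = False
    pad_size_mm: float = 50.0
    n_streamline_seeds: int = 25
    write_vtk: bool = False

    def __post_init__(self):
        if self.model not in ("cti", "isotropic", "both"):
            raise ValueError(f"model must be cti/isotropic/both, not {self.model!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(base_seed: int, stage: str) -> int:
    """Derive a per-stage RNG seed (< 2^31) from the run seed."""
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _models(config: RunConfig) -> list[str]:
    return {"both": ["cti", "iso"], "cti": ["cti"], "isotropic": ["iso"]}[config.model]


def run_full(config: RunConfig, out_dir) -> dict:
    """Execute the whole pipeline into ``out_dir``; returns the results.

    Any stage failure aborts with the stage name; outputs of completed
    stages are left on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "stages": {},
        "artifacts": [],
    }
    results: dict = {}
    stage = "init"

    def record(name: str, t0: float, files: list[str]):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 2)}
        manifest["artifacts"].extend(files)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    try:
        stage = "phantom"
        t0 = time.time()
        base = phantom.make_layered_sphere_phantom(
            outer_radius_mm=config.outer_radius_mm,
            layer_thicknesses=config.layer_thicknesses,
            voxel_size_mm=config.voxel_size_mm,
        )
        maps = phantom.make_microstructure_maps(base, fiber_model=config.fiber_model)
        D_true, C_true = phantom.ground_truth_tensors(maps, beta=config.beta)
        io.save_labels(out / "labels.nii", base)
        for nm, arr in (
            ("sigma_H", maps.sigma_H),
            ("v_int", maps.v_int),
            ("lam", maps.lam),
            ("lam_ext", maps.lam_ext),
        ):
            io.save_volume(out / f"{nm}.nii", arr, base.grid)
        record("phantom", t0, ["labels.nii", "sigma_H.nii", "v_int.nii", "lam.nii", "lam_ext.nii"])
        results["labels"] = base
        results["maps"] = maps

        conductivities: dict[str, TensorMap] = {}
        if "cti" in _models(config):
            stage = "dwi"
            t0 = time.time()
            dwi = phantom.simulate_dwi(
                maps,
                D_true,
                snr=config.snr,
                seed=stage_seed(config.seed, "dwi") if config.snr is not None else None,
            )
            io.save_dwi(out / "dwi", dwi)
            record("dwi", t0, ["dwi.nii", "dwi.bval", "dwi.bvec"])

            stage = "recon"
            t0 = time.time()
            fit = cti_recon.fit_two_compartment(dwi)
            eta = cti_recon.compute_eta(
                maps.sigma_H, fit.v_int, fit.lam, fit.lam_ext,
                beta=config.beta, mask=fit.mask, grid=fit.grid,
            )
            C_cti = cti_recon.reconstruct_tensor(eta, fit.D_e)
            io.save_tensor_map(out / "C_cti.nii", C_cti)
            io.save_volume(out / "eta.nii", eta.eta, base.grid)
            record("recon", t0, ["C_cti.nii", "eta.nii"])
            results["fit"] = fit
            results["C_cti"] = C_cti

        stage = "solve"
        solutions: dict[tuple[str, str], mesh_fem.FieldSolution] = {}
        montage_objs: dict[str, phantom.ElectrodeMontage] = {}
        for mname in config.montages:
            t0 = time.time()
            lab = base.copy()
            montage = phantom.place_electrodes_1020(
                lab, mname,
                pad_size_mm=(config.pad_size_mm, config.pad_size_mm),
                current_I=config.current_I,
            )
            montage_objs[montage.name] = montage
            mesh = mesh_fem.build_mesh(lab, montage)
            for model in _models(config):
                stage = f"solve:{mname}:{model}"
                if model == "cti":
                    C = cti_recon.hybrid_assignment(lab, results["C_cti"])
                else:
                    C = cti_recon.assign_isotropic(lab)
                prob = mesh_fem.montage_problem(mesh, C, montage)
                sol = mesh_fem.solve_problem(prob, rel_tol=config.solver_rel_tol)
                solutions[(montage.name, model)] = sol
                tag = f"{montage.name}_{model}"
                io.save_volume(out / f"J_mag_{tag}.nii", sol.J_mag, base.grid)
                io.save_volume(out / f"E_mag_{tag}.nii", sol.E_mag, base.grid)
                io.save_volume(out / f"J_vec_{tag}.nii", sol.J, base.grid)
                if config.write_vtk:
                    io.write_vtk_mesh(
                        out / f"mesh_{tag}.vtk", mesh,
                        {"J_mag": sol.J_mag.ravel()[mesh.voxel_flat]},
                    )
                record(
                    f"solve:{montage.name}:{model}", t0,
                    [f"J_mag_{tag}.nii", f"E_mag_{tag}.nii", f"J_vec_{tag}.nii"],
                )
                t0 = time.time()
        results["solutions"] = solutions
        results["montages"] = montage_objs

        stage = "report"
        t0 = time.time()
        files = []
        if set(_models(config)) == {"cti", "iso"}:
            rep = response.montage_report(
                solutions, base, montage_objs, include_csf=config.include_csf
            )
            rep["roi_statistics"].to_csv(out / "roi_statistics.csv", index=False)
            rep["slice_statistics"].to_csv(out / "slice_statistics.csv", index=False)
            (out / "relative_difference.json").write_text(
                json.dumps(rep["relative_difference_pct"], indent=1, sort_keys=True)
            )
            files += ["roi_statistics.csv", "slice_statistics.csv", "relative_difference.json"]
            results["report"] = rep
        else:
            frames = []
            rois = response.roi_masks(base, include_csf=config.include_csf)
            for (mname, model), sol in solutions.items():
                df = response.roi_statistics(sol, base, rois, model=model).to_frame()
                df.insert(0, "montage", mname)
                frames.append(df)
            import pandas as pd

            stats = pd.concat(frames, ignore_index=True)
            stats.to_csv(out / "roi_statistics.csv", index=False)
            files.append("roi_statistics.csv")
            results["report"] = {"roi_statistics": stats}

        # streamlines seeded under each anode (first available model)
        for mname, montage in montage_objs.items():
            model = _models(config)[0]
            sol = solutions[(mname, model)]
            seeds = _anode_seeds(base, montage, config.n_streamline_seeds)
            lines = response.trace_streamlines(
                sol.J, base.grid, sol.mask, seeds, step_mm=config.voxel_size_mm
            )
            io.write_vtk_polylines(out / f"streamlines_{mname}.vtk", lines)
            files.append(f"streamlines_{mname}.vtk")
        record("report", t0, files)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return results


def _anode_seeds(labels, montage, n: int) -> np.ndarray:
    """Seed points in gray matter under the anode patch (deterministic)."""
    gm = labels.mask("GM")
    p = labels.grid.voxel_centers()
    r = np.linalg.norm(p, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...i,i->...", p, montage.anode_dir) / r
    under = gm & (cosang > np.cos(np.radians(20.0)))
    pts = p[under]
    if len(pts) == 0:
        pts = p[gm]
    step = max(1, len(pts) // n)
    return pts[::step][:n]


# ---------------------------------------------------------------------------
# analytic oracle battery


def _check(name: str, passed: bool, detail: dict) -> dict:
    return {"name": name, "passed": bool(passed), **detail}


def validate_suite(quick: bool = False) -> dict:
    """Run every analytic oracle; returns ``{"passed": bool, "checks": [...]}``.

    The battery covers: homogeneous slab (Ohm's law), two-layer series
    slab, anisotropy stretch-equivalence, current conservation and
    reciprocity, the conductivity-formula collapses and worked example, and
    the relative-difference hand cases.
    """
    checks = []
    n = 8 if quick else 12

    # homogeneous slab: du = I L / (sigma A), |J| = I / A
    sigma, I = 0.14, 2e-3
    shape = (n, n, 2 * n)
    h = 2.0
    prob = mesh_fem.box_problem(shape, (h, h, h), sigma, I)
    sol = mesh_fem.solve_problem(prob)
    A = shape[0] * shape[1] * h * h * 1e-6
    L = shape[2] * h * 1e-3
    du = float(sol.u.max())
    du_exp = I * L / (sigma * A)
    Jm = sol.J_mag[sol.mask]
    j_err = float(np.abs(Jm - I / A).max() / (I / A))
    du_err = abs(du - du_exp) / du_exp
    checks.append(
        _check("slab_ohms_law", du_err < 0.01 and j_err < 0.01,
               {"du": du, "du_expected": du_exp, "J_max_rel_err": j_err})
    )

    # conservation on the slab
    rep = mesh_fem.check_current_conservation(sol, prob)
    checks.append(
        _check(
            "conservation",
            0.99 <= rep["anode_flux_ratio"] <= 1.01 and abs(rep["net_flux_fraction"]) <= 0.01,
            {"anode_flux_ratio": rep["anode_flux_ratio"], "net_flux_fraction": rep["net_flux_fraction"]},
        )
    )

    # energy identity: sum E.C.E dV = I * mean anode potential
    C_el = prob.element_tensors()
    Ev = sol.E.reshape(-1, 3)[prob.mesh.voxel_flat]
    energy = float(np.einsum("vi,vij,vj->", Ev, C_el, Ev) * prob.mesh.grid.voxel_volume * 1e-9)
    u_an = float(sol.u[prob.anode.unique_nodes()].mean())
    checks.append(
        _check("energy_identity", abs(energy - I * u_an) / (I * u_an) < 0.01,
               {"energy": energy, "I_du": I * u_an})
    )

    # two-layer series slab
    s1, s2 = 0.14, 0.47
    field = np.full(shape, s1)
    field[:, :, shape[2] // 2:] = s2
    prob2 = mesh_fem.box_problem(shape, (h, h, h), field, I)
    sol2 = mesh_fem.solve_problem(prob2)
    Jz = sol2.J[..., 2][sol2.mask]
    jz_err = float(np.abs(-Jz - I / A).max() / (I / A))  # normal J continuous = uniform
    half = shape[2] // 2
    zc = prob2.mesh.grid.voxel_centers()[..., 2]
    u_nodes = sol2.u
    # voltage drop per layer from potentials at the boundary planes
    nid = prob2.mesh._node_id
    u_grid = u_nodes[nid[:, :, [0, half, shape[2]]]]
    drop1 = float((u_grid[:, :, 1] - u_grid[:, :, 0]).mean())
    drop2 = float((u_grid[:, :, 2] - u_grid[:, :, 1]).mean())
    ratio_err = abs(drop1 / drop2 - s2 / s1) / (s2 / s1)
    checks.append(
        _check("two_layer_series", jz_err < 0.01 and ratio_err < 0.01,
               {"J_normal_max_rel_err": jz_err, "drop_ratio": drop1 / drop2, "expected": s2 / s1})
    )

    # anisotropy stretch-equivalence with patch electrodes
    diag = np.array([2.0, 1.0, 0.5]) * 0.2
    tens = np.zeros(shape + (3, 3))
    tens[...] = np.diag(diag)
    probA = mesh_fem.box_problem(shape, (h, h, h), tens, I, patch_half_voxels=n // 4)
    solA = mesh_fem.solve_problem(probA)
    R_aniso = float(solA.u[probA.anode.unique_nodes()].mean()) / I
    scale = 1.0 / np.sqrt(diag)
    # same index-space patch on the coordinate-stretched isotropic box
    probI = mesh_fem.box_problem(
        shape, tuple(h * s for s in scale), 1.0, I, patch_half_voxels=n // 4
    )
    solI = mesh_fem.solve_problem(probI)
    R_iso = float(solI.u[probI.anode.unique_nodes()].mean()) / I
    R_equiv = R_iso / np.sqrt(np.prod(diag))
    stretch_err = abs(R_aniso - R_equiv) / R_equiv
    checks.append(
        _check("anisotropy_stretch", stretch_err < 0.02,
               {"R_aniso": R_aniso, "R_stretched_iso": R_equiv, "rel_err": stretch_err})
    )

    # reciprocity: pure-Neumann operator, swapped electrodes negate u
    probS = mesh_fem.StimulationProblem(
        mesh=prob.mesh, conductivity=prob.conductivity,
        anode=prob.cathode, cathode=prob.anode, current_I=I,
    )
    u_fwd, _ = mesh_fem.solve_potential(mesh_fem.assemble_system(prob, cathode_dirichlet=False))
    u_swp, _ = mesh_fem.solve_potential(mesh_fem.assemble_system(probS, cathode_dirichlet=False))
    rec_err = float(np.max(np.abs(u_fwd + u_swp)) / np.max(np.abs(u_fwd)))
    checks.append(_check("reciprocity", rec_err < 1e-3, {"rel_err": rec_err}))

    # conductivity-formula collapses and worked example
    eta0 = cti_recon.eta_scale(np.array(0.5), np.array(0.0), np.array(2e-3), np.array(1.5e-3), 0.41)
    eta1 = cti_recon.eta_scale(np.array(0.5), np.array(1.0 - 1e-12), np.array(2e-3), np.array(1.5e-3), 0.41)
    eta_w = float(cti_recon.eta_scale(np.array(0.5), np.array(0.4), np.array(2e-3), np.array(1.5e-3), 0.41))
    checks.append(
        _check(
            "eta_collapses",
            np.isclose(eta0, 0.5 / 1.5e-3) and eta1 < 1e-9 and abs(eta_w - 244.3) / 244.3 < 5e-4,
            {"eta_vint0": float(eta0), "eta_vint1": float(eta1), "eta_worked": eta_w},
        )
    )

    # relative-difference hand cases
    ok = True
    same = response.relative_difference(np.ones(4), np.ones(4), np.ones(4, bool)).rd["roi"]
    zero = response.relative_difference(np.ones(4), np.zeros(4), np.ones(4, bool)).rd["roi"]
    two = response.relative_difference(
        np.array([2.0, 1.0]), np.array([1.0, 1.0]), np.ones(2, bool)
    ).rd["roi"]
    ok = np.isclose(same, 0.0) and np.isclose(zero, 100.0) and np.isclose(two, 100.0 / 3.0)
    checks.append(_check("relative_difference_hand_cases", ok,
                         {"identical": same, "zero_iso": zero, "two_voxel": two}))

    return {"passed": all(c["passed"] for c in checks), "checks": checks}
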