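"""Low-frequency conductivity tensor reconstruction from CTI inputs.

The core relation is the cross-property law

    C = (1 - v_int) * sigma_H / (v_int * beta * lam + (1 - v_int) * lam_ext) * D_e^w
      = eta * D_e^w

where sigma_H is the high-frequency (Larmor) conductivity, v_int the
intracellular volume fraction, beta the intracellular/extracellular ion
concentration ratio, lam the intrinsic diffusion coefficient, lam_ext the
extracellular mean diffusivity, and D_e^w the extracellular water diffusion
tensor.  Unit convention throughout: diffusivities in mm^2/s, conductivity
in S/m; eta therefore carries units of S.s/mm^2/m such that eta * D_e^w is
in S/m (numerically, eta is simply the quotient of the maps as given).

The microstructure quantities are estimated from two-shell DWI with a
simplified two-compartment (intracellular stick + extracellular
axisymmetric tensor) fit: orientation from a log-linear tensor fit of the
inner shell, (v_int, lam) from per-shell spherical means, the extracellular
axial/radial diffusivities from a log-linear fit of the stick-corrected
signals, and an optional joint Gauss-Newton refinement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import erf

from .containers import Grid, LabelVolume, TensorMap

logger = logging.getLogger(__name__)

__all__ = [
    "TISSUE_CONDUCTIVITY",
    "EtaMap",
    "TwoCompartmentFit",
    "eta_scale",
    "fit_two_compartment",
    "compute_eta",
    "reconstruct_tensor",
    "assign_isotropic",
    "hybrid_assignment",
]

#: Isotropic literature conductivities (S/m) for the comparator model.
TISSUE_CONDUCTIVITY: dict[str, float] = {
    "air": 1e-15,
    "scalp": 0.47,
    "skull": 0.01,
    "eye": 2.00,
    "CSF": 1.79,
    "GM": 0.27,
    "WM": 0.14,
    "electrode": 5.99e7,
    "sponge": 1.00,
}

# physical clipping ranges for the fit
_V_BOUNDS = (0.0, 0.999)
_DIFF_BOUNDS = (1e-5, 4e-3)  # mm^2/s


@dataclass
class EtaMap:
    """Per-voxel scale factor eta linking D_e^w (mm^2/s) to C (S/m)."""

    grid: Grid
    eta: np.ndarray
    beta: float
    mask: np.ndarray

    def __post_init__(self):
        self.eta = np.asarray(self.eta, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        on = self.eta[self.mask]
        if on.size and (np.any(~np.isfinite(on)) or np.any(on < 0)):
            raise ValueError("eta must be finite and non-negative on the mask")


@dataclass
class TwoCompartmentFit:
    """Microstructure estimates from the two-compartment DWI fit."""

    grid: Grid
    v_int: np.ndarray
    lam: np.ndarray
    lam_ext: np.ndarray
    D_e: TensorMap
    mask: np.ndarray  # voxels with a valid, convergent fit
    s0: np.ndarray


def eta_scale(
    sigma_H: np.ndarray,
    v_int: np.ndarray,
    lam: np.ndarray,
    lam_ext: np.ndarray,
    beta: float,
) -> np.ndarray:
    """eta = (1 - v_int) sigma_H / (v_int beta lam + (1 - v_int) lam_ext).

    Vectorized over arrays; no masking (callers handle invalid voxels).
    """
    v = np.asarray(v_int, dtype=float)
    denom = v * beta * np.asarray(lam, float) + (1.0 - v) * np.asarray(lam_ext, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (1.0 - v) * np.asarray(sigma_H, float) / denom


def _stick_mean(x: np.ndarray) -> np.ndarray:
    """Spherical mean of exp(-x (g.f)^2) over uniform directions g.

    Equals sqrt(pi/(4x)) erf(sqrt(x)); -> 1 as x -> 0.
    """
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    big = x > 1e-9
    sx = np.sqrt(x[big])
    out[big] = np.sqrt(np.pi) / (2.0 * sx) * erf(sx)
    return out


def _smt_model(b: np.ndarray, v: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Spherical-mean signal of the two-compartment model per shell.

    Extracellular space uses the tortuosity closure (axial lam, radial
    (1 - v) lam), so the spherical means depend on (v, lam) only.
    ``b``: (S,) shells; ``v``, ``lam``: (N,).  Returns (N, S).
    """
    b = np.asarray(b, float)[None, :]
    v_ = v[:, None]
    lam_ = lam[:, None]
    t = (1.0 - v_) * lam_
    intra = _stick_mean(b * lam_)
    extra = np.exp(-b * t) * _stick_mean(b * (lam_ - t))
    return v_ * intra + (1.0 - v_) * extra


def _fit_smt(shell_means: np.ndarray, shells: np.ndarray, n_iter: int = 40) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (v, lam) from the two per-shell spherical means.

    Damped Newton on the 2x2 system with finite-difference Jacobian,
    clipped to physical bounds each step.
    """
    n = shell_means.shape[0]
    v = np.full(n, 0.35)
    lam = np.full(n, 1.8e-3)
    eps_v, eps_l = 1e-5, 1e-8
    for _ in range(n_iter):
        r = _smt_model(shells, v, lam) - shell_means
        J00 = (_smt_model(shells, v + eps_v, lam) - _smt_model(shells, v - eps_v, lam)) / (2 * eps_v)
        J01 = (_smt_model(shells, v, lam + eps_l) - _smt_model(shells, v, lam - eps_l)) / (2 * eps_l)
        # solve 2x2 least squares (exact for 2 shells) per voxel
        a = np.einsum("ns,ns->n", J00, J00) + 1e-12
        bq = np.einsum("ns,ns->n", J00, J01)
        c = np.einsum("ns,ns->n", J01, J01) + 1e-18
        g0 = np.einsum("ns,ns->n", J00, r)
        g1 = np.einsum("ns,ns->n", J01, r)
        det = a * c - bq * bq
        det = np.where(np.abs(det) < 1e-30, 1e-30, det)
        dv = (c * g0 - bq * g1) / det
        dl = (a * g1 - bq * g0) / det
        step = 0.5  # damping keeps the iteration inside the basin
        v = np.clip(v - step * dv, _V_BOUNDS[0], _V_BOUNDS[1])
        lam = np.clip(lam - step * dl, _DIFF_BOUNDS[0], _DIFF_BOUNDS[1])
    return v, lam


def _dti_orientation(s: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-linear tensor fit of the inner shell; returns (eigvecs desc-major, eigvals)."""
    b_inner = bvals[bvals > 0].min()
    sel = np.isclose(bvals, b_inner)
    g = bvecs[sel]
    design = -b_inner * np.stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]],
        axis=1,
    )
    logs = np.log(np.clip(s[:, sel], 1e-8, None))
    coeff = logs @ np.linalg.pinv(design).T  # (N, 6): Dxx Dyy Dzz Dxy Dxz Dyz
    D = np.zeros(s.shape[:1] + (3, 3))
    D[:, 0, 0], D[:, 1, 1], D[:, 2, 2] = coeff[:, 0], coeff[:, 1], coeff[:, 2]
    D[:, 0, 1] = D[:, 1, 0] = coeff[:, 3]
    D[:, 0, 2] = D[:, 2, 0] = coeff[:, 4]
    D[:, 1, 2] = D[:, 2, 1] = coeff[:, 5]
    w, V = np.linalg.eigh(D)
    return V[:, :, ::-1], w[:, ::-1]  # descending


def _fit_extracellular(
    s: np.ndarray, bvals: np.ndarray, c2: np.ndarray, v: np.ndarray, lam: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Axial/radial extracellular diffusivities (l, t) from stick-corrected
    log-signals: ln E_ext = -b t - b (l - t) (g.f)^2, linear least squares."""
    b = bvals[None, :]
    stick = np.exp(-b * lam[:, None] * c2)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_ext = (s - v[:, None] * stick) / (1.0 - v[:, None])
    y = np.log(np.clip(e_ext, 1e-8, None))  # (N, G)
    # design per voxel: y = t * (-b) + (l - t) * (-b c2)
    x1 = -b * np.ones_like(c2)
    x2 = -b * c2
    a11 = np.einsum("ng,ng->n", x1, x1)
    a12 = np.einsum("ng,ng->n", x1, x2)
    a22 = np.einsum("ng,ng->n", x2, x2)
    r1 = np.einsum("ng,ng->n", x1, y)
    r2 = np.einsum("ng,ng->n", x2, y)
    det = a11 * a22 - a12 * a12
    det = np.where(np.abs(det) < 1e-30, 1e-30, det)
    t = (a22 * r1 - a12 * r2) / det
    dl = (a11 * r2 - a12 * r1) / det
    l = t + dl
    t = np.clip(t, _DIFF_BOUNDS[0], _DIFF_BOUNDS[1])
    l = np.clip(l, _DIFF_BOUNDS[0], _DIFF_BOUNDS[1])
    return l, t


def _refine_joint(
    s: np.ndarray,
    bvals: np.ndarray,
    c2: np.ndarray,
    v: np.ndarray,
    lam: np.ndarray,
    l: np.ndarray,
    t: np.ndarray,
    n_iter: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Joint Gauss-Newton refinement of (v, lam, l, t) with fixed orientation."""
    b = bvals[None, :]
    for _ in range(n_iter):
        A = np.exp(-b * lam[:, None] * c2)
        B = np.exp(-b * t[:, None] - b * (l - t)[:, None] * c2)
        m = v[:, None] * A + (1.0 - v[:, None]) * B
        r = m - s
        Jv = A - B
        Jlam = -v[:, None] * b * c2 * A
        Jt = -(1.0 - v[:, None]) * b * (1.0 - c2) * B
        Jl = -(1.0 - v[:, None]) * b * c2 * B
        J = np.stack([Jv, Jlam, Jt, Jl], axis=-1)  # (N, G, 4)
        JtJ = np.einsum("ngp,ngq->npq", J, J)
        JtJ += 1e-10 * np.eye(4)[None]
        Jtr = np.einsum("ngp,ng->np", J, r)
        delta = np.linalg.solve(JtJ, Jtr[..., None])[..., 0]
        v = np.clip(v - delta[:, 0], _V_BOUNDS[0], _V_BOUNDS[1])
        lam = np.clip(lam - delta[:, 1], _DIFF_BOUNDS[0], _DIFF_BOUNDS[1])
        t = np.clip(t - delta[:, 2], _DIFF_BOUNDS[0], _DIFF_BOUNDS[1])
        l = np.clip(l - delta[:, 3], _DIFF_BOUNDS[0], _DIFF_BOUNDS[1])
    return v, lam, l, t


def fit_two_compartment(
    dwi,
    mask: Optional[np.ndarray] = None,
    refine: bool = True,
    chunk: int = 20000,
) -> TwoCompartmentFit:
    """Fit the stick-plus-tensor model voxel-wise to two-shell DWI.

    Per voxel: (1) a log-linear tensor fit of the inner shell provides the
    candidate D_e^w orientation, (2) per-shell spherical means are fitted to
    the model's spherical means for (v_int, lam), (3) extracellular
    axial/radial diffusivities come from a stick-corrected log-linear fit
    (optionally followed by a joint Gauss-Newton refinement), and
    lam_ext = trace(D_e^w)/3.  Estimates are clipped to physical ranges
    (v_int in [0, 1), diffusivities in (0, 4e-3) mm^2/s).

    All-zero voxels are masked out rather than raising; non-convergent
    voxels are flagged invalid in the returned mask.
    """
    grid = dwi.grid
    bvals = np.asarray(dwi.bvals, float)
    bvecs = np.asarray(dwi.bvecs, float)
    shells = np.unique(bvals[bvals > 0])
    if shells.size < 2:
        raise ValueError("at least two nonzero shells are required")
    if np.sum(np.isclose(bvals, shells[-1])) < 6:
        raise ValueError("at least six directions are required on the outer shell")

    sig = dwi.signals.reshape(-1, bvals.size)
    b0 = bvals == 0
    s0 = sig[:, b0].mean(axis=1)
    base = np.ones(sig.shape[0], dtype=bool) if mask is None else np.asarray(mask, bool).ravel()
    if dwi.mask is not None:
        base = base & dwi.mask.ravel()
    valid_in = base & (s0 > 0) & np.isfinite(sig).all(axis=1)
    idx = np.where(valid_in)[0]

    nz = bvals > 0
    bz = bvals[nz]
    gz = bvecs[nz]

    N = sig.shape[0]
    v_out = np.zeros(N)
    lam_out = np.zeros(N)
    l_out = np.zeros(N)
    t_out = np.zeros(N)
    f_out = np.zeros((N, 3))
    ok = np.zeros(N, dtype=bool)

    for start in range(0, idx.size, chunk):
        ii = idx[start : start + chunk]
        s = sig[ii] / s0[ii, None]
        s_nz = np.clip(s[:, nz], 1e-8, None)

        V, _ = _dti_orientation(s, bvals, bvecs)
        f = V[:, :, 0]  # principal eigenvector
        c2 = (f @ gz.T) ** 2

        means = np.stack(
            [s_nz[:, np.isclose(bz, bb)].mean(axis=1) for bb in shells], axis=1
        )
        v, lam = _fit_smt(means, shells)
        l, t = _fit_extracellular(s_nz, bz, c2, v, lam)
        if refine:
            v, lam, l, t = _refine_joint(s_nz, bz, c2, v, lam, l, t)

        m = v[:, None] * np.exp(-bz[None] * lam[:, None] * c2) + (
            1.0 - v[:, None]
        ) * np.exp(-bz[None] * t[:, None] - bz[None] * (l - t)[:, None] * c2)
        rms = np.sqrt(np.mean((m - s_nz) ** 2, axis=1))
        params_finite = (
            np.isfinite(v) & np.isfinite(lam) & np.isfinite(l) & np.isfinite(t)
        )
        # rms threshold flags genuinely non-convergent voxels while leaving
        # noise-level misfit alone (Rician noise at SNR 20 gives rms ~ 0.05)
        good = params_finite & np.isfinite(rms) & (rms < 0.2)

        v_out[ii], lam_out[ii] = v, lam
        l_out[ii], t_out[ii] = l, t
        f_out[ii] = f
        ok[ii] = good

    n_bad = int(valid_in.sum() - ok.sum())
    if n_bad:
        logger.info("two-compartment fit: %d voxels flagged non-convergent", n_bad)

    shape = grid.shape
    eye = np.eye(3)
    D_full = t_out[:, None, None] * eye + (l_out - t_out)[:, None, None] * (
        f_out[:, :, None] * f_out[:, None, :]
    )
    D_full[~ok] = 0.0
    D_map = TensorMap.from_full(grid, D_full.reshape(shape + (3, 3)), ok.reshape(shape), units="mm^2/s")
    lam_ext = ((l_out + 2.0 * t_out) / 3.0).reshape(shape)

    return TwoCompartmentFit(
        grid=grid,
        v_int=v_out.reshape(shape),
        lam=lam_out.reshape(shape),
        lam_ext=np.where(ok.reshape(shape), lam_ext, 0.0),
        D_e=D_map,
        mask=ok.reshape(shape),
        s0=s0.reshape(shape),
    )


def compute_eta(
    sigma_H: np.ndarray,
    v_int: np.ndarray,
    lam: np.ndarray,
    lam_ext: np.ndarray,
    beta: float = 0.41,
    mask: Optional[np.ndarray] = None,
    grid: Optional[Grid] = None,
) -> EtaMap:
    """Voxel-wise scale factor eta of the cross-property relation.

    Voxels where the denominator is non-positive are flagged invalid (their
    count is logged) rather than raising: such values signal nonphysical
    inputs, not a programming error.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    sigma_H = np.asarray(sigma_H, float)
    shape = sigma_H.shape
    for name, arr in (("v_int", v_int), ("lam", lam), ("lam_ext", lam_ext)):
        if np.asarray(arr).shape != shape:
            raise ValueError(f"{name} is not co-registered with sigma_H (shape mismatch)")
    m = np.ones(shape, bool) if mask is None else np.asarray(mask, bool)
    denom = np.asarray(v_int) * beta * np.asarray(lam) + (1.0 - np.asarray(v_int)) * np.asarray(lam_ext)
    bad = m & (denom <= 0)
    if bad.any():
        logger.warning("compute_eta: %d voxels with non-positive denominator flagged invalid", int(bad.sum()))
    m = m & ~bad
    eta = np.where(m, eta_scale(sigma_H, v_int, lam, lam_ext, beta), 0.0)
    eta = np.where(np.isfinite(eta) & (eta >= 0), eta, 0.0)
    if grid is None:
        grid = Grid(shape=shape, voxel_size=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))
    return EtaMap(grid=grid, eta=eta, beta=beta, mask=m)


def reconstruct_tensor(eta: EtaMap, D_e: TensorMap) -> TensorMap:
    """Low-frequency conductivity tensor C = eta * D_e^w (S/m).

    Eigenvectors of C equal those of D_e^w; the validity mask is the
    intersection of both inputs'.
    """
    if eta.eta.shape != D_e.grid.shape:
        raise ValueError("eta and D_e grids do not match")
    C = D_e.scaled(np.where(eta.mask, eta.eta, np.nan), units="S/m")
    C.mask &= eta.mask
    C.components[~C.mask] = 0.0
    return C


def assign_isotropic(
    labels: LabelVolume, table: Optional[dict[str, float]] = None
) -> TensorMap:
    """Isotropic literature-value conductivity tensor sigma(tissue) * I per voxel."""
    table = TISSUE_CONDUCTIVITY if table is None else table
    sigma = np.zeros(labels.grid.shape)
    for code in np.unique(labels.labels):
        tissue = labels.label_table[int(code)]
        if tissue not in table:
            raise KeyError(f"no conductivity for label {tissue!r}")
        sigma[labels.labels == code] = table[tissue]
    mask = np.ones(labels.grid.shape, bool)
    return TensorMap.isotropic(labels.grid, sigma, mask, units="S/m")


def hybrid_assignment(
    labels: LabelVolume,
    C_cti: TensorMap,
    table: Optional[dict[str, float]] = None,
) -> TensorMap:
    """Tensor-model conductivity: reconstructed tensors in WM/GM/CSF,
    literature isotropic values everywhere else.

    Brain voxels whose reconstructed tensor is invalid fall back to the
    literature value; the fallback count is logged.
    """
    table = TISSUE_CONDUCTIVITY if table is None else table
    if not C_cti.grid.same_geometry(labels.grid):
        raise ValueError("C_cti grid does not match labels grid")
    out = assign_isotropic(labels, table)
    brain = labels.mask("WM", "GM", "CSF")
    use = brain & C_cti.mask
    n_fallback = int((brain & ~C_cti.mask).sum())
    if n_fallback:
        logger.warning("hybrid_assignment: %d brain voxels fell back to literature values", n_fallback)
    out.components[use] = C_cti.components[use]
    return out
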