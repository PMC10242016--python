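"""Synthetic layered-sphere head phantoms for conductivity-tensor stimulation studies.

The phantom stands in for a segmented human head: concentric shells of
scalp, skull, CSF and gray matter around a white-matter core, with
piecewise-constant microstructure (high-frequency conductivity sigma_H,
intracellular volume fraction v_int, intrinsic diffusivity lambda,
extracellular mean diffusivity lambda_ext), a coherent white-matter fiber
field, simulated two-shell diffusion MRI, and 10-20-system sponge-pad
electrode montages projected onto the scalp.

Everything downstream (tensor reconstruction, FEM solves, response
statistics) can therefore be exercised against known ground truth without
any acquired data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import Grid, LabelVolume, TensorMap
from .cti_recon import eta_scale

__all__ = [
    "LABEL_TABLE",
    "DEFAULT_LAYERS",
    "DEFAULT_TISSUE_PARAMS",
    "TEN_TWENTY_ANGLES",
    "MicrostructureMaps",
    "DWISet",
    "ElectrodeMontage",
    "make_layered_sphere_phantom",
    "make_microstructure_maps",
    "ground_truth_tensors",
    "two_shell_scheme",
    "simulate_dwi",
    "place_electrodes_1020",
    "patch_contact_area",
]

#: Fixed label coding shared by the whole package.
LABEL_TABLE: dict[int, str] = {
    0: "air",
    1: "scalp",
    2: "skull",
    3: "CSF",
    4: "GM",
    5: "WM",
    6: "eye",
    7: "sponge",
    8: "electrode",
}

#: Default shell thicknesses (mm), ordered outside-in; the remainder is WM.
DEFAULT_LAYERS: dict[str, float] = {"scalp": 6.0, "skull": 6.0, "CSF": 3.0, "GM": 4.0}

# Per-tissue microstructure ground truth.  sigma_H in S/m; diffusivities in
# mm^2/s; aniso_ratio is the longitudinal/transverse extracellular
# diffusivity ratio.  Values are plausible in-vivo brain magnitudes; the
# resulting low-frequency tensor means land near the literature isotropic
# values (WM ~0.15, GM ~0.30, CSF 2.0 S/m) so the tensor and isotropic
# models are comparable but not identical.
DEFAULT_TISSUE_PARAMS: dict[str, dict[str, float]] = {
    "WM": dict(sigma_H=0.35, v_int=0.60, lam=2.0e-3, lam_ext=0.9e-3, aniso_ratio=3.0),
    "GM": dict(sigma_H=0.60, v_int=0.55, lam=2.0e-3, lam_ext=1.0e-3, aniso_ratio=1.0),
    "CSF": dict(sigma_H=2.00, v_int=0.00, lam=3.0e-3, lam_ext=3.0e-3, aniso_ratio=1.0),
}

#: 10-20 electrode positions as (inclination from vertex, azimuth) in degrees.
#: Azimuth is measured from the anterior (+y) axis, positive toward the
#: right (+x).  Standard arc fractions of the 10-20 system on a sphere.
TEN_TWENTY_ANGLES: dict[str, tuple[float, float]] = {
    "Cz": (0.0, 0.0),
    "C3": (36.0, -90.0),
    "C4": (36.0, 90.0),
    "Fz": (36.0, 0.0),
    "Pz": (36.0, 180.0),
    "FP1": (72.0, -18.0),
    "FP2": (72.0, 18.0),
    "F3": (50.0, -40.0),
    "F4": (50.0, 40.0),
    "T7": (72.0, -90.0),
    "T8": (72.0, 90.0),
    "O1": (72.0, -162.0),
    "O2": (72.0, 162.0),
}

_BRAIN_TISSUES = ("CSF", "GM", "WM")


@dataclass
class MicrostructureMaps:
    """Piecewise ground-truth microstructure on the phantom grid.

    ``fiber_dir`` holds a unit vector per voxel where an intracellular
    'stick' compartment exists (GM and WM); NaN elsewhere.  ``aniso_ratio``
    is the per-voxel extracellular longitudinal/transverse ratio.
    """

    grid: Grid
    sigma_H: np.ndarray
    v_int: np.ndarray
    lam: np.ndarray
    lam_ext: np.ndarray
    fiber_dir: np.ndarray  # (*shape, 3), NaN where undefined
    aniso_ratio: np.ndarray
    mask: np.ndarray  # brain voxels (CSF/GM/WM)

    def validate(self) -> None:
        m = self.mask
        if np.any((self.v_int[m] < 0) | (self.v_int[m] >= 1)):
            raise ValueError("v_int must lie in [0, 1)")
        if np.any(self.sigma_H[m] <= 0):
            raise ValueError("sigma_H must be positive inside head tissue")
        if np.any(self.lam[m] <= 0) or np.any(self.lam_ext[m] <= 0):
            raise ValueError("diffusivities must be positive")
        f = self.fiber_dir[m]
        defined = np.isfinite(f).all(axis=-1)
        norms = np.linalg.norm(f[defined], axis=-1)
        if defined.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("fiber_dir must be unit-norm where defined")


@dataclass
class DWISet:
    """Multi-shell diffusion-weighted signals with gradient table.

    ``signals`` has shape ``(*grid.shape, n_gradients)``; b-values in
    s/mm^2 (including b=0 volumes); ``bvecs`` unit vectors for b > 0.
    ``snr`` is the Rician signal-to-noise at b = 0 (None = noiseless).
    """

    grid: Grid
    signals: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    snr: Optional[float] = None
    seed: Optional[int] = None
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must be (n_gradients, 3)")
        if not np.any(self.bvals == 0):
            raise ValueError("at least one b=0 volume is required")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if nz.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("bvecs must be unit vectors for b > 0")
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative")

    @property
    def shells(self) -> np.ndarray:
        """Distinct nonzero b-values, ascending."""
        return np.unique(self.bvals[self.bvals > 0])


@dataclass
class ElectrodeMontage:
    """An anode/cathode sponge-pad pair attached to the scalp.

    ``anode_mask``/``cathode_mask`` flag the electrode-label voxels of each
    patch; ``*_sponge_mask`` the saline sponge voxels underneath.  Current
    flows from the anode into the head and out of the cathode; ``current_I``
    is in amperes.
    """

    name: str
    anode: str
    cathode: str
    pad_size_mm: tuple[float, float]
    sponge_thickness_mm: float
    electrode_thickness_mm: float
    current_I: float
    anode_mask: np.ndarray
    cathode_mask: np.ndarray
    anode_sponge_mask: np.ndarray
    cathode_sponge_mask: np.ndarray
    anode_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    cathode_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        if self.current_I <= 0:
            raise ValueError("current_I must be positive")
        if np.any(self.anode_mask & self.cathode_mask):
            raise ValueError("anode and cathode patches overlap")


def _radius_grid(grid: Grid) -> np.ndarray:
    return np.linalg.norm(grid.voxel_centers(), axis=-1)


def make_layered_sphere_phantom(
    outer_radius_mm: float = 80.0,
    layer_thicknesses: dict[str, float] | None = None,
    voxel_size_mm: float = 2.0,
    pad_mm: float = 8.0,
    cc_block: bool = True,
) -> LabelVolume:
    """Concentric-shell spherical head phantom on an isotropic voxel grid.

    Shells are ordered scalp, skull, CSF, GM from the outside in, with the
    remainder a WM core; everything beyond ``outer_radius_mm`` is air.  The
    grid is centered on the sphere and extends ``pad_mm`` beyond the scalp
    so electrode/sponge layers can be attached later.  Deterministic: no
    randomness is involved.

    Parameters
    ----------
    outer_radius_mm:
        Scalp outer radius (mm).
    layer_thicknesses:
        Shell thicknesses in mm for ``scalp``, ``skull``, ``CSF``, ``GM``.
    voxel_size_mm:
        Isotropic voxel edge length (mm); must not exceed the thinnest layer.
    pad_mm:
        Air margin beyond the scalp, in mm.
    cc_block:
        If True, mark a midline WM block as a corpus-callosum-analog ROI.
    """
    layers = dict(DEFAULT_LAYERS if layer_thicknesses is None else layer_thicknesses)
    missing = [t for t in ("scalp", "skull", "CSF", "GM") if t not in layers]
    if missing:
        raise ValueError(f"layer_thicknesses missing {missing}")
    if any(t <= 0 for t in layers.values()):
        raise ValueError("layer thicknesses must be positive")
    if sum(layers.values()) >= outer_radius_mm:
        raise ValueError("layer thicknesses must sum to less than the outer radius")
    thinnest = min(layers.values())
    if voxel_size_mm > thinnest:
        raise ValueError(
            f"voxel size {voxel_size_mm} mm exceeds thinnest layer ({thinnest} mm); "
            "that layer would vanish on the grid"
        )

    h = float(voxel_size_mm)
    half = int(math.ceil((outer_radius_mm + pad_mm) / h))
    n = 2 * half + 1
    grid = Grid(
        shape=(n, n, n),
        voxel_size=(h, h, h),
        origin=(-half * h, -half * h, -half * h),
    )
    r = _radius_grid(grid)

    # shell outer radii, outside-in
    bounds = []
    edge = outer_radius_mm
    for t in ("scalp", "skull", "CSF", "GM"):
        bounds.append((t, edge))
        edge -= layers[t]
    wm_outer = edge  # WM core radius

    labels = np.zeros(grid.shape, dtype=np.int16)  # air
    code = {v: k for k, v in LABEL_TABLE.items()}
    labels[r <= bounds[0][1]] = code["scalp"]
    labels[r <= bounds[1][1]] = code["skull"]
    labels[r <= bounds[2][1]] = code["CSF"]
    labels[r <= bounds[3][1]] = code["GM"]
    labels[r <= wm_outer] = code["WM"]

    cc_mask = None
    if cc_block:
        p = grid.voxel_centers()
        cc_mask = (
            (labels == code["WM"])
            & (np.abs(p[..., 0]) <= 6.0)
            & (np.abs(p[..., 1]) <= 25.0)
            & (p[..., 2] >= 0.0)
            & (p[..., 2] <= 25.0)
        )

    return LabelVolume(grid=grid, labels=labels, label_table=dict(LABEL_TABLE), cc_mask=cc_mask)


def _fiber_field(grid: Grid, mask: np.ndarray, fiber_model: str) -> np.ndarray:
    """Unit fiber direction per masked voxel; NaN outside the mask."""
    f = np.full(grid.shape + (3,), np.nan)
    if fiber_model == "uniform-x":
        f[mask] = (1.0, 0.0, 0.0)
        return f
    p = grid.voxel_centers()
    r = np.linalg.norm(p, axis=-1)
    if fiber_model == "radial":
        with np.errstate(invalid="ignore", divide="ignore"):
            d = p / r[..., None]
        d[r < 1e-9] = (1.0, 0.0, 0.0)  # center voxel: arbitrary fixed direction
        f[mask] = d[mask]
    elif fiber_model == "tangential":
        # azimuthal direction z_hat x r_hat: horizontal circles around the
        # vertical axis (left-right near the midline top, like callosal fibers)
        d = np.stack([-p[..., 1], p[..., 0], np.zeros_like(r)], axis=-1)
        nrm = np.linalg.norm(d, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = d / nrm[..., None]
        d[nrm < 1e-9] = (1.0, 0.0, 0.0)  # on the z-axis the azimuth is degenerate
        f[mask] = d[mask]
    else:
        raise ValueError(f"unknown fiber_model {fiber_model!r}")
    return f


def make_microstructure_maps(
    labels: LabelVolume,
    tissue_params: dict[str, dict[str, float]] | None = None,
    fiber_model: str = "radial",
) -> MicrostructureMaps:
    """Piecewise-constant microstructure maps from a label volume.

    Each brain tissue (CSF, GM, WM) receives its parameter set from
    ``tissue_params``; CSF is cell-free (``v_int = 0``, isotropic).  GM and
    WM receive a coherent fiber direction per ``fiber_model`` (``radial``,
    ``tangential`` or ``uniform-x``) so the intracellular stick compartment
    is defined wherever ``v_int > 0``.
    """
    params = DEFAULT_TISSUE_PARAMS if tissue_params is None else tissue_params
    grid = labels.grid
    present = {labels.label_table[c] for c in np.unique(labels.labels)}
    needed = [t for t in _BRAIN_TISSUES if t in present]
    for t in needed:
        if t not in params:
            raise KeyError(f"tissue_params missing entry for tissue {t!r}")

    sigma_H = np.zeros(grid.shape)
    v_int = np.zeros(grid.shape)
    lam = np.zeros(grid.shape)
    lam_ext = np.zeros(grid.shape)
    ratio = np.ones(grid.shape)
    mask = np.zeros(grid.shape, dtype=bool)
    for t in needed:
        m = labels.mask(t)
        mask |= m
        p = params[t]
        sigma_H[m] = p["sigma_H"]
        v_int[m] = p["v_int"]
        lam[m] = p["lam"]
        lam_ext[m] = p["lam_ext"]
        ratio[m] = p.get("aniso_ratio", 1.0)
    if "CSF" in needed:
        v_int[labels.mask("CSF")] = 0.0

    fiber_mask = mask & (v_int > 0)
    fiber = _fiber_field(grid, fiber_mask, fiber_model)

    maps = MicrostructureMaps(
        grid=grid,
        sigma_H=sigma_H,
        v_int=v_int,
        lam=lam,
        lam_ext=lam_ext,
        fiber_dir=fiber,
        aniso_ratio=ratio,
        mask=mask,
    )
    maps.validate()
    return maps


def _axisymmetric_tensor(
    lam_ext: np.ndarray, ratio: np.ndarray, fiber: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Full (*shape,3,3) tensor with mean diffusivity lam_ext, axial/radial
    eigenvalue ratio ``ratio`` about ``fiber``; isotropic where fiber is NaN."""
    t = 3.0 * lam_ext / (ratio + 2.0)
    l = ratio * t
    f = np.where(np.isfinite(fiber), fiber, 0.0)
    has_fiber = np.isfinite(fiber).all(axis=-1)
    eye = np.eye(3)
    outer = f[..., :, None] * f[..., None, :]
    D = t[..., None, None] * eye + np.where(
        has_fiber[..., None, None], (l - t)[..., None, None] * outer, 0.0
    )
    # voxels without a fiber are isotropic at lam_ext regardless of ratio
    D_iso = lam_ext[..., None, None] * eye
    D = np.where(has_fiber[..., None, None], D, D_iso)
    D[~mask] = 0.0
    return D


def ground_truth_tensors(
    maps: MicrostructureMaps,
    anisotropy_ratio: float | None = None,
    beta: float = 0.41,
) -> tuple[TensorMap, TensorMap]:
    """Ground-truth extracellular diffusion tensor and conductivity tensor.

    ``D_e^w`` is axially symmetric about the fiber direction with mean
    diffusivity lam_ext and axial/radial ratio taken from the maps (or a
    global override).  The true conductivity tensor is ``C = eta * D_e^w``
    with the same scale factor the reconstruction estimates — this is the
    round-trip oracle, not the reconstruction itself.
    """
    ratio = (
        np.full(maps.grid.shape, float(anisotropy_ratio))
        if anisotropy_ratio is not None
        else maps.aniso_ratio
    )
    if np.any(ratio < 1.0):
        raise ValueError("anisotropy_ratio must be >= 1")
    D = _axisymmetric_tensor(maps.lam_ext, ratio, maps.fiber_dir, maps.mask)
    D_map = TensorMap.from_full(maps.grid, D, maps.mask, units="mm^2/s")
    eta = eta_scale(maps.sigma_H, maps.v_int, maps.lam, maps.lam_ext, beta)
    eta = np.where(maps.mask, eta, 0.0)
    C_map = D_map.scaled(eta, units="S/m")
    return D_map, C_map


def _fibonacci_sphere(n: int, hemisphere: bool = True) -> np.ndarray:
    """Deterministic, nearly uniform unit directions (spherical Fibonacci)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    if hemisphere:
        z = 1.0 - i / n  # upper hemisphere only (antipodal symmetry of DWI)
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def two_shell_scheme(
    n_inner: int = 30,
    n_outer: int = 64,
    b_inner: float = 800.0,
    b_outer: float = 2200.0,
    n_b0: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-shell gradient table: b = 800 (30 dirs) and 2,200 s/mm^2 (64 dirs)
    by default, plus ``n_b0`` unweighted volumes.  Directions are a
    deterministic spherical-Fibonacci set."""
    bvals = np.concatenate(
        [np.zeros(n_b0), np.full(n_inner, b_inner), np.full(n_outer, b_outer)]
    )
    bvecs = np.concatenate(
        [np.zeros((n_b0, 3)), _fibonacci_sphere(n_inner), _fibonacci_sphere(n_outer)]
    )
    return bvals, bvecs


def dwi_forward_model(
    v_int: np.ndarray,
    lam: np.ndarray,
    fiber: np.ndarray,
    D_full: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
) -> np.ndarray:
    """Stick-plus-tensor signal fractions S/S0 for flat voxel arrays.

    ``S/S0 = v_int exp(-b lam (g.f)^2) + (1 - v_int) exp(-b g^T D_e^w g)``.
    Inputs are flattened over voxels: v_int/lam ``(N,)``, fiber ``(N,3)``
    (NaN treated as no stick), D_full ``(N,3,3)``.
    Returns ``(N, n_gradients)``.
    """
    f = np.where(np.isfinite(fiber), fiber, 0.0)
    c = f @ bvecs.T  # (N, G) g.f
    gDg = np.einsum("gi,nij,gj->ng", bvecs, D_full, bvecs)
    b = bvals[None, :]
    intra = np.exp(-b * lam[:, None] * c**2)
    extra = np.exp(-b * gDg)
    return v_int[:, None] * intra + (1.0 - v_int[:, None]) * extra


def simulate_dwi(
    maps: MicrostructureMaps,
    D_e_true: TensorMap,
    bvals: np.ndarray | None = None,
    bvecs: np.ndarray | None = None,
    snr: float | None = None,
    seed: int | None = None,
    s0: float = 1.0,
) -> DWISet:
    """Simulate two-compartment DWI signals on the phantom.

    Noiseless signals follow the stick-plus-tensor model; if ``snr`` is
    finite, Rician noise (magnitude of two independent Gaussian channels
    with sigma = s0/snr) is applied, reproducibly for a given ``seed``.
    """
    if bvals is None or bvecs is None:
        bvals, bvecs = two_shell_scheme()
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive (or None for noiseless)")
        if seed is None:
            raise ValueError("seed is required when snr is finite")

    grid = maps.grid
    mask = maps.mask
    idx = np.where(mask.ravel())[0]
    frac = dwi_forward_model(
        maps.v_int.ravel()[idx],
        maps.lam.ravel()[idx],
        maps.fiber_dir.reshape(-1, 3)[idx],
        D_e_true.full().reshape(-1, 3, 3)[idx],
        bvals,
        bvecs,
    )
    signals = np.zeros((np.prod(grid.shape), bvals.size))
    signals[idx] = s0 * frac
    signals = signals.reshape(grid.shape + (bvals.size,))

    if snr is not None:
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        n1 = rng.normal(0.0, sigma, signals.shape)
        n2 = rng.normal(0.0, sigma, signals.shape)
        noisy = np.sqrt((signals + n1) ** 2 + n2**2)
        signals = np.where(mask[..., None], noisy, 0.0)

    return DWISet(
        grid=grid, signals=signals, bvals=bvals, bvecs=bvecs, snr=snr, seed=seed, mask=mask
    )


def _direction_from_angles(incl_deg: float, azim_deg: float) -> np.ndarray:
    """Unit vector from inclination-from-vertex and azimuth-from-anterior."""
    inc = math.radians(incl_deg)
    az = math.radians(azim_deg)
    return np.array(
        [math.sin(inc) * math.sin(az), math.sin(inc) * math.cos(az), math.cos(inc)]
    )


def _tangent_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0])
    if abs(float(d @ helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, d)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _patch_shells(
    labels: LabelVolume,
    direction: np.ndarray,
    pad_size: tuple[float, float],
    sponge_t: float,
    electrode_t: float,
    scalp_radius: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (sponge, electrode) of air voxels forming the pad column."""
    grid = labels.grid
    p = grid.voxel_centers()
    r = np.linalg.norm(p, axis=-1)
    air = labels.labels == labels.code("air")
    shell = air & (r >= scalp_radius - 1e-9) & (r < scalp_radius + sponge_t + electrode_t)
    if not shell.any():
        return np.zeros(grid.shape, bool), np.zeros(grid.shape, bool)

    e1, e2 = _tangent_frame(direction)
    with np.errstate(invalid="ignore", divide="ignore"):
        phat = p / r[..., None]
    cosang = np.clip(np.einsum("...i,i->...", phat, direction), -1.0, 1.0)
    ang = np.arccos(cosang)
    tang = phat - cosang[..., None] * direction
    tnorm = np.linalg.norm(tang, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tdir = tang / tnorm[..., None]
    tdir = np.where(tnorm[..., None] > 1e-12, tdir, 0.0)
    s = scalp_radius * ang  # geodesic distance from patch center on the scalp
    u = s * np.einsum("...i,i->...", tdir, e1)
    v = s * np.einsum("...i,i->...", tdir, e2)
    in_patch = shell & (np.abs(u) <= pad_size[0] / 2) & (np.abs(v) <= pad_size[1] / 2)
    sponge = in_patch & (r < scalp_radius + sponge_t)
    electrode = in_patch & ~sponge
    return sponge, electrode


def place_electrodes_1020(
    labels: LabelVolume,
    montage_name: str | tuple[str, str],
    pad_size_mm: tuple[float, float] = (50.0, 50.0),
    current_I: float = 2.0e-3,
    sponge_thickness_mm: float = 3.0,
    electrode_thickness_mm: float = 2.0,
) -> ElectrodeMontage:
    """Attach a 10-20-system sponge-pad electrode pair to the phantom scalp.

    The montage name is ``"ANODE-CATHODE"`` (e.g. ``"C3-FP2"``, ``"F4-F3"``)
    using positions from :data:`TEN_TWENTY_ANGLES`.  Square pads (default
    50 x 50 mm) are centered on the 10-20 direction and projected onto the
    outer scalp sphere; a saline sponge layer (3 mm) and a conductor layer
    (2 mm) are written into the label volume **in place**.

    Returns the :class:`ElectrodeMontage`; raises if the patches would
    overlap existing sponge/electrode labels or each other.
    """
    if isinstance(montage_name, str):
        parts = montage_name.split("-")
        if len(parts) != 2:
            raise ValueError(f"montage name {montage_name!r} is not 'ANODE-CATHODE'")
        anode_name, cathode_name = parts
    else:
        anode_name, cathode_name = montage_name
    for nm in (anode_name, cathode_name):
        if nm not in TEN_TWENTY_ANGLES:
            raise ValueError(f"unknown 10-20 position {nm!r}")

    grid = labels.grid
    p = grid.voxel_centers()
    r = np.linalg.norm(p, axis=-1)
    head = labels.labels != labels.code("air")
    # electrode/sponge voxels from a previous montage are not part of the scalp sphere
    anat = head & ~labels.mask("sponge", "electrode")
    if not anat.any():
        raise ValueError("label volume contains no head voxels")
    # outermost anatomical voxel center approximates the scalp sphere radius
    scalp_radius = float(r[anat].max())

    masks = {}
    for role, nm in (("anode", anode_name), ("cathode", cathode_name)):
        d = _direction_from_angles(*TEN_TWENTY_ANGLES[nm])
        sponge, electrode = _patch_shells(
            labels, d, pad_size_mm, sponge_thickness_mm, electrode_thickness_mm, scalp_radius
        )
        if not electrode.any() or not sponge.any():
            raise ValueError(f"montage patch {nm} could not be attached to the scalp")
        masks[role] = (sponge, electrode, d)

    a_sp, a_el, a_dir = masks["anode"]
    c_sp, c_el, c_dir = masks["cathode"]
    new = a_sp | a_el | c_sp | c_el
    if np.any((a_sp | a_el) & (c_sp | c_el)):
        raise ValueError("anode and cathode patches overlap")
    if np.any(new & labels.mask("sponge", "electrode")):
        raise ValueError("patches overlap an existing montage")

    labels.labels[a_sp | c_sp] = labels.code("sponge")
    labels.labels[a_el | c_el] = labels.code("electrode")

    return ElectrodeMontage(
        name=f"{anode_name}-{cathode_name}",
        anode=anode_name,
        cathode=cathode_name,
        pad_size_mm=tuple(pad_size_mm),
        sponge_thickness_mm=sponge_thickness_mm,
        electrode_thickness_mm=electrode_thickness_mm,
        current_I=current_I,
        anode_mask=a_el,
        cathode_mask=c_el,
        anode_sponge_mask=a_sp,
        cathode_sponge_mask=c_sp,
        anode_dir=a_dir,
        cathode_dir=c_dir,
    )


def patch_contact_area(labels: LabelVolume, patch_mask: np.ndarray) -> float:
    """Radially projected footprint area (mm^2) of one pad column.

    Sums the inward-facing exposed faces of the patch voxels (faces whose
    neighbor lies outside the patch and whose outward normal points toward
    the head center), each weighted by |n . r_hat|: projected radially, the
    staircase envelope covers the underlying spherical patch exactly once.
    """
    grid = labels.grid
    hx, hy, hz = grid.voxel_size
    face_area = {0: hy * hz, 1: hx * hz, 2: hx * hy}
    p = grid.voxel_centers()
    with np.errstate(invalid="ignore", divide="ignore"):
        phat = p / np.linalg.norm(p, axis=-1, keepdims=True)
    phat = np.nan_to_num(phat)
    total = 0.0
    for axis in range(3):
        for side in (-1, 1):
            neigh = np.roll(patch_mask, -side, axis=axis)
            # roll wraps; voxels at the rolled-in border cannot be neighbors
            sl = [slice(None)] * 3
            sl[axis] = -1 if side == 1 else 0
            neigh[tuple(sl)] = False
            exposed = patch_mask & ~neigh
            if not exposed.any():
                continue
            ncomp = side * phat[exposed][:, axis]
            inward = ncomp < 0  # face looks toward the head center
            total += face_area[axis] * np.abs(ncomp[inward]).sum()
    return float(total)
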