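"""Tissue-response quantification: ROI statistics, model differences, streamlines.

Compares the electric field and current density of the conductivity-tensor
head model against the isotropic literature-value model: per-ROI mean +/-
std of |E| and |J|, the relative-difference statistic

    rD = sum_i |J_CTI,i - J_ISO,i| / sum_i J_CTI,i * 100 %

over an ROI (magnitudes per voxel), signed difference maps on selected
slices, current-density streamlines seeded under the anode, and per-slice
statistics for montage comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import Grid, LabelVolume
from .mesh_fem import FieldSolution
from .phantom import ElectrodeMontage

__all__ = [
    "ROIStatistics",
    "RDReport",
    "StreamlineSet",
    "roi_masks",
    "roi_statistics",
    "relative_difference",
    "difference_map",
    "trace_streamlines",
    "slice_statistics",
    "montage_report",
]


@dataclass
class ROIStatistics:
    """Mean +/- population std of |E| (V/m) and |J| (A/m^2) per ROI."""

    model: str
    stats: dict[str, dict[str, float]]  # roi -> {E_mean, E_std, J_mean, J_std, n_voxels}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.stats, orient="index")
        df.index.name = "roi"
        df.insert(0, "model", self.model)
        return df.reset_index()


@dataclass
class RDReport:
    """Relative difference (%) per ROI plus the per-voxel |difference| map."""

    rd: dict[str, float]
    difference_map: np.ndarray  # |J_cti - J_iso| per voxel (A/m^2)


@dataclass
class StreamlineSet:
    """Current-density streamlines: polylines in mm with per-point |J|."""

    lines: list[np.ndarray]  # each (n_points, 3)
    magnitudes: list[np.ndarray]  # each (n_points,)
    step_mm: float


def roi_masks(
    labels: LabelVolume, include_csf: bool = False
) -> dict[str, np.ndarray]:
    """Standard analysis ROIs: GM, WM, entire brain, and the
    corpus-callosum-analog block when the phantom defines one.

    The entire-brain ROI is GM + WM by default (CSF excluded unless
    requested)."""
    rois = {"GM": labels.mask("GM"), "WM": labels.mask("WM")}
    brain = rois["GM"] | rois["WM"]
    if include_csf:
        brain = brain | labels.mask("CSF")
    rois["brain"] = brain
    if labels.cc_mask is not None and labels.cc_mask.any():
        rois["CC"] = labels.cc_mask
    return rois


def roi_statistics(
    fields: FieldSolution,
    labels: LabelVolume,
    rois: Optional[dict[str, np.ndarray]] = None,
    model: str = "",
) -> ROIStatistics:
    """Arithmetic mean and population standard deviation of the field
    magnitudes over each ROI's voxels."""
    if rois is None:
        rois = roi_masks(labels)
    E = fields.E_mag
    J = fields.J_mag
    out = {}
    for name, m in rois.items():
        m = np.asarray(m, bool)
        if not m.any():
            raise ValueError(f"ROI {name!r} contains no voxels")
        out[name] = {
            "E_mean": float(E[m].mean()),
            "E_std": float(E[m].std()),  # population convention (ddof=0)
            "J_mean": float(J[m].mean()),
            "J_std": float(J[m].std()),
            "n_voxels": int(m.sum()),
        }
    return ROIStatistics(model=model, stats=out)


def relative_difference(
    J_cti_mag: np.ndarray,
    J_iso_mag: np.ndarray,
    roi_mask: np.ndarray | dict[str, np.ndarray],
    vector_difference: tuple[np.ndarray, np.ndarray] | None = None,
) -> RDReport:
    """Relative difference rD (%) between current-density magnitudes.

    The default numerator is the absolute difference of per-voxel
    magnitudes.  Passing the two vector fields via ``vector_difference``
    switches the numerator to the magnitude of the vector difference (the
    alternative reading), keeping the same denominator.
    """
    J_cti_mag = np.asarray(J_cti_mag, float)
    J_iso_mag = np.asarray(J_iso_mag, float)
    if J_cti_mag.shape != J_iso_mag.shape:
        raise ValueError("magnitude maps are not on a common grid")
    if vector_difference is not None:
        vc, vi = vector_difference
        diff = np.linalg.norm(np.asarray(vc) - np.asarray(vi), axis=-1)
    else:
        diff = np.abs(J_cti_mag - J_iso_mag)

    masks = roi_mask if isinstance(roi_mask, dict) else {"roi": np.asarray(roi_mask, bool)}
    rd = {}
    for name, m in masks.items():
        m = np.asarray(m, bool)
        denom = J_cti_mag[m].sum()
        if denom <= 0:
            raise ValueError(f"degenerate ROI {name!r}: sum of J_CTI magnitudes is zero")
        rd[name] = float(diff[m].sum() / denom * 100.0)
    return RDReport(rd=rd, difference_map=diff)


def _slice_index_from_top(labels: LabelVolume, distance_mm: float, axis: int = 2) -> int:
    """Grid index of the slice ``distance_mm`` inward from the outer scalp
    surface along ``axis`` (measured from the topmost non-air voxel)."""
    inside = labels.labels != labels.code("air")
    if not inside.any():
        raise ValueError("empty head")
    reduce_axes = tuple(a for a in range(3) if a != axis)
    prof = inside.any(axis=reduce_axes)
    top = int(np.max(np.nonzero(prof)))
    h = labels.grid.voxel_size[axis]
    idx = top - int(round(distance_mm / h))
    if idx < 0 or idx >= labels.grid.shape[axis]:
        raise ValueError(f"slice {distance_mm} mm from the surface falls outside the volume")
    return idx


def difference_map(
    field_cti: FieldSolution,
    field_iso: FieldSolution,
    slice_spec: dict,
    quantity: str = "J",
) -> np.ndarray:
    """Signed per-voxel difference (tensor - isotropic) of |E| or |J| on a slice.

    ``slice_spec`` is either ``{"axis": a, "index": i}`` or
    ``{"axis": a, "from_surface_mm": d, "labels": LabelVolume}`` (distance
    measured inward from the outer scalp surface along the axis).
    """
    if quantity not in ("E", "J"):
        raise ValueError("quantity must be 'E' or 'J'")
    a = field_cti.E_mag if quantity == "E" else field_cti.J_mag
    b = field_iso.E_mag if quantity == "E" else field_iso.J_mag
    if a.shape != b.shape:
        raise ValueError("fields are not co-registered")
    axis = int(slice_spec.get("axis", 2))
    if "index" in slice_spec:
        idx = int(slice_spec["index"])
        if idx < 0 or idx >= a.shape[axis]:
            raise ValueError(f"slice index {idx} outside volume of shape {a.shape}")
    else:
        idx = _slice_index_from_top(
            slice_spec["labels"], float(slice_spec["from_surface_mm"]), axis
        )
    return np.take(a - b, idx, axis=axis)


def _trilinear(field: np.ndarray, grid: Grid, pts: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a (*shape, k) field at world points (mm).

    Points outside the grid evaluate to zero (so interpolated masks vanish
    there and streamlines terminate instead of sliding along the border).
    """
    idx = grid.world_to_index(pts)
    shape = np.asarray(field.shape[:3])
    in_grid = np.all((idx >= 0) & (idx <= shape - 1), axis=-1)
    i0 = np.floor(idx).astype(int)
    i0 = np.clip(i0, 0, shape - 2)
    frac = np.clip(idx - i0, 0.0, 1.0)
    out = np.zeros(pts.shape[:-1] + field.shape[3:])
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[..., 0] if dx else 1 - frac[..., 0])
                    * (frac[..., 1] if dy else 1 - frac[..., 1])
                    * (frac[..., 2] if dz else 1 - frac[..., 2])
                )
                out += w[..., None] * field[i0[..., 0] + dx, i0[..., 1] + dy, i0[..., 2] + dz]
    return out * in_grid[..., None]


def trace_streamlines(
    J: np.ndarray,
    grid: Grid,
    head_mask: np.ndarray,
    seeds: np.ndarray,
    step_mm: float = 2.0,
    max_steps: int = 500,
    mag_floor: float = 1e-6,
) -> StreamlineSet:
    """Integrate streamlines of the current-density direction field.

    Fixed-step classical Runge-Kutta (RK4) on the normalized, trilinearly
    interpolated J field; each line terminates on leaving the head mask,
    when |J| falls below ``mag_floor`` (A/m^2), or after ``max_steps``.
    Seeds outside the head are skipped with a warning.
    """
    import warnings

    seeds = np.atleast_2d(np.asarray(seeds, float))
    maskf = head_mask.astype(float)

    def direction(p):
        v = _trilinear(J, grid, p[None])[0]
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.zeros(3)

    def inside(p):
        return _trilinear(maskf[..., None], grid, p[None])[0, 0] > 0.5

    lines, mags = [], []
    for seed in seeds:
        if not inside(seed):
            warnings.warn(f"streamline seed {seed} lies outside the head; skipped")
            continue
        pts = [seed.copy()]
        jm = [float(np.linalg.norm(_trilinear(J, grid, seed[None])[0]))]
        p = seed.copy()
        for _ in range(max_steps):
            k1 = direction(p)
            if np.allclose(k1, 0):
                break
            k2 = direction(p + 0.5 * step_mm * k1)
            k3 = direction(p + 0.5 * step_mm * k2)
            k4 = direction(p + step_mm * k3)
            step = (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            nrm = np.linalg.norm(step)
            if nrm < 1e-12:
                break
            p = p + step_mm * step / nrm
            if not inside(p):
                break
            mag = float(np.linalg.norm(_trilinear(J, grid, p[None])[0]))
            pts.append(p.copy())
            jm.append(mag)
            if mag < mag_floor:
                break
        lines.append(np.array(pts))
        mags.append(np.array(jm))
    return StreamlineSet(lines=lines, magnitudes=mags, step_mm=step_mm)


def slice_statistics(
    fields: FieldSolution,
    labels: LabelVolume,
    montage: ElectrodeMontage,
    intracranial_ref_mm: float = 75.0,
    axial_depths_mm: tuple[float, float] = (25.0, 75.0),
) -> pd.DataFrame:
    """Brain-masked |J| mean +/- std on three standard slices.

    S1 is the coronal slice through the anode patch center; S2 and S3 are
    axial slices 25 and 75 mm below the inner skull of a reference adult
    head (intracranial radius ~75 mm), scaled by the phantom's actual
    intracranial radius — so S3 always samples the deep center and S2 an
    upper-cortex plane regardless of phantom size.
    """
    grid = labels.grid
    brain = labels.mask("GM", "WM")
    inside = labels.labels != labels.code("air")
    r = np.linalg.norm(grid.voxel_centers(), axis=-1)
    r_outer = float(r[inside].max())
    icv = labels.mask("CSF", "GM", "WM")
    r_icv = float(r[icv].max()) + 0.5 * max(grid.voxel_size)
    scale = r_icv / intracranial_ref_mm

    # S1: coronal (y) slice through the anode center direction
    anode_y = float(montage.anode_dir[1]) * r_outer
    iy = int(round(grid.world_to_index(np.array([0.0, anode_y, 0.0]))[1]))
    iy = int(np.clip(iy, 0, grid.shape[1] - 1))
    specs = {"S1": (1, iy)}
    for name, depth in zip(("S2", "S3"), axial_depths_mm):
        z_world = r_icv - depth * scale
        iz = int(round(grid.world_to_index(np.array([0.0, 0.0, z_world]))[2]))
        if iz < 0 or iz >= grid.shape[2]:
            raise ValueError(f"slice {name} falls outside the volume")
        specs[name] = (2, iz)

    J = fields.J_mag
    rows = []
    for name, (axis, idx) in specs.items():
        msl = np.take(brain, idx, axis=axis)
        jsl = np.take(J, idx, axis=axis)
        if not msl.any():
            raise ValueError(f"slice {name} contains no brain voxels")
        rows.append(
            dict(
                slice=name,
                axis="coronal" if axis == 1 else "axial",
                index=idx,
                J_mean=float(jsl[msl].mean()),
                J_std=float(jsl[msl].std()),
                n_voxels=int(msl.sum()),
            )
        )
    return pd.DataFrame(rows)


def montage_report(
    solutions: dict[tuple[str, str], FieldSolution],
    labels: LabelVolume,
    montages: dict[str, ElectrodeMontage],
    include_csf: bool = False,
) -> dict:
    """Bundle ROI statistics, rD, and slice tables across montages and models.

    ``solutions`` maps ``(montage_name, model)`` with model in
    ``{"cti", "iso"}``.  Requires both models per montage (rD is a
    tensor-vs-isotropic comparison).
    """
    names = sorted({k[0] for k in solutions})
    for nm in names:
        for model in ("cti", "iso"):
            if (nm, model) not in solutions:
                raise ValueError(f"missing solution for montage {nm!r} model {model!r}")
        if nm not in montages:
            raise ValueError(f"montage object missing for {nm!r}")

    rois = roi_masks(labels, include_csf=include_csf)
    roi_frames = []
    rd = {}
    slice_frames = []
    for nm in names:
        cti = solutions[(nm, "cti")]
        iso = solutions[(nm, "iso")]
        for model, sol in (("cti", cti), ("iso", iso)):
            df = roi_statistics(sol, labels, rois, model=model).to_frame()
            df.insert(0, "montage", nm)
            roi_frames.append(df)
        rd[nm] = relative_difference(cti.J_mag, iso.J_mag, rois).rd
        sdf = slice_statistics(cti, labels, montages[nm])
        sdf.insert(0, "montage", nm)
        slice_frames.append(sdf)

    return {
        "roi_statistics": pd.concat(roi_frames, ignore_index=True),
        "relative_difference_pct": rd,
        "slice_statistics": pd.concat(slice_frames, ignore_index=True),
    }
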