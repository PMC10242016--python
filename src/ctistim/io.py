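"""File formats: NIfTI volumes, FSL-style gradient tables, legacy VTK.

Scalar maps and label volumes are written as NIfTI with a diagonal affine
built from the grid's voxel size and origin.  Tensor maps use a 4D NIfTI
whose 4th dimension holds the six unique components in the order
``xx, xy, xz, yy, yz, zz``.  DWI sets are a 4D NIfTI plus plain-text
``.bval``/``.bvec`` files (row vectors, whitespace-separated).  Meshes and
streamlines are written as legacy ASCII VTK, which every VTK-based viewer
reads without extra dependencies.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .containers import Grid, LabelVolume, TensorMap, TENSOR_COMPONENTS
from .phantom import DWISet

__all__ = [
    "save_volume",
    "load_volume",
    "save_labels",
    "load_labels",
    "save_tensor_map",
    "load_tensor_map",
    "save_dwi",
    "load_dwi",
    "write_vtk_mesh",
    "write_vtk_polylines",
]


def _grid_from_img(img) -> Grid:
    aff = img.affine
    vox = tuple(float(v) for v in np.diag(aff)[:3])
    if not all(v > 0 for v in vox) or not np.allclose(
        aff[:3, :3], np.diag(np.diag(aff)[:3])
    ):
        raise ValueError("only axis-aligned, positive-step affines are supported")
    return Grid(
        shape=tuple(int(s) for s in img.shape[:3]),
        voxel_size=vox,
        origin=tuple(float(v) for v in aff[:3, 3]),
    )


def save_volume(path, array: np.ndarray, grid: Grid, dtype=np.float32) -> Path:
    """Write a 3D/4D array on a grid as NIfTI."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(array).astype(dtype), grid.affine())
    nib.save(img, str(path))
    return path


def load_volume(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), _grid_from_img(img)


def save_labels(path, labels: LabelVolume) -> Path:
    """Label volume as int16 NIfTI + a JSON sidecar with the label table."""
    path = Path(path)
    save_volume(path, labels.labels, labels.grid, dtype=np.int16)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii(.gz)
    meta = {"label_table": {str(k): v for k, v in labels.label_table.items()}}
    Path(str(sidecar) + ".labels.json").write_text(json.dumps(meta, indent=1))
    return path


def load_labels(path) -> LabelVolume:
    path = Path(path)
    arr, grid = load_volume(path)
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".labels.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        table = {int(k): v for k, v in meta["label_table"].items()}
    else:
        from .phantom import LABEL_TABLE

        table = dict(LABEL_TABLE)
    return LabelVolume(grid=grid, labels=arr.astype(np.int16), label_table=table)


def save_tensor_map(path, tmap: TensorMap) -> Path:
    """Six-component 4D NIfTI, 4th dim ordered xx, xy, xz, yy, yz, zz."""
    return save_volume(path, tmap.components, tmap.grid)


def load_tensor_map(path, mask: np.ndarray | None = None) -> TensorMap:
    arr, grid = load_volume(path)
    if arr.ndim != 4 or arr.shape[3] != len(TENSOR_COMPONENTS):
        raise ValueError("tensor map must be 4D with 6 components")
    if mask is None:
        mask = np.any(arr != 0, axis=3)
    return TensorMap(grid=grid, components=np.asarray(arr, float), mask=mask)


def save_dwi(stem, dwi: DWISet) -> tuple[Path, Path, Path]:
    """4D NIfTI ``<stem>.nii`` plus FSL-style ``<stem>.bval``/``.bvec``."""
    stem = Path(stem)
    nii = stem.with_suffix(".nii")
    save_volume(nii, dwi.signals, dwi.grid)
    bval = stem.with_suffix(".bval")
    bvec = stem.with_suffix(".bvec")
    bval.write_text(" ".join(f"{b:g}" for b in dwi.bvals) + "\n")
    lines = [" ".join(f"{v:.8f}" for v in dwi.bvecs[:, ax]) for ax in range(3)]
    bvec.write_text("\n".join(lines) + "\n")
    return nii, bval, bvec


def load_dwi(nii_path, bval_path, bvec_path, mask: np.ndarray | None = None) -> DWISet:
    arr, grid = load_volume(nii_path)
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return DWISet(grid=grid, signals=np.asarray(arr, float), bvals=bvals, bvecs=bvecs, mask=mask)


def write_vtk_mesh(path, mesh, cell_data: dict[str, np.ndarray] | None = None) -> Path:
    """Legacy ASCII VTK unstructured grid of the tetrahedral mesh.

    ``cell_data`` values are per-voxel arrays (scalar or 3-vector); each is
    replicated onto the voxel's six tets.
    """
    path = Path(path)
    elems, owner = mesh.tetrahedra()
    pts = mesh.node_coords
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nctistim mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(pts)} float\n")
        np.savetxt(fh, pts, fmt="%.6g")
        fh.write(f"CELLS {len(elems)} {len(elems) * 5}\n")
        np.savetxt(fh, np.column_stack([np.full(len(elems), 4), elems]), fmt="%d")
        fh.write(f"CELL_TYPES {len(elems)}\n")
        fh.write("\n".join(["10"] * len(elems)) + "\n")  # VTK_TETRA
        if cell_data:
            fh.write(f"CELL_DATA {len(elems)}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)[owner]
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr, fmt="%.6g")
                else:
                    fh.write(f"VECTORS {name} float\n")
                    np.savetxt(fh, arr, fmt="%.6g")
    return path


def write_vtk_polylines(path, streamlines) -> Path:
    """Legacy ASCII VTK polydata of a StreamlineSet with |J| point data."""
    path = Path(path)
    lines = streamlines.lines
    mags = streamlines.magnitudes
    pts = np.concatenate(lines) if lines else np.zeros((0, 3))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nctistim streamlines\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        np.savetxt(fh, pts, fmt="%.6g")
        total = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        offset = 0
        for l in lines:
            fh.write(" ".join([str(len(l))] + [str(offset + i) for i in range(len(l))]) + "\n")
            offset += len(l)
        fh.write(f"POINT_DATA {len(pts)}\n")
        fh.write("SCALARS J_mag float 1\nLOOKUP_TABLE default\n")
        if mags:
            np.savetxt(fh, np.concatenate(mags), fmt="%.6g")
    return path
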