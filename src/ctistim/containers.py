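"""Shared voxel-grid containers used across the pipeline.

All volumes live on a common axis-aligned grid: ``world = origin + index *
voxel_size`` gives the voxel-center coordinate in mm, with axes ordered
(x, y, z) = (right, anterior, superior) and the phantom centered at the
world origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["Grid", "LabelVolume", "TensorMap", "TENSOR_COMPONENTS"]

#: Component order of the flattened symmetric tensor (4th NIfTI dimension).
TENSOR_COMPONENTS = ("xx", "xy", "xz", "yy", "yz", "zz")

# (row, col) index of each flattened component in the 3x3 tensor
_COMP_IJ = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


@dataclass(frozen=True)
class Grid:
    """Voxel geometry: shape, per-axis voxel size (mm) and world origin (mm)."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self):
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if any(h <= 0 for h in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``(*shape, 3)``."""
        axes = [
            self.origin[a] + self.voxel_size[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points (mm)."""
        p = np.asarray(points, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def affine(self) -> np.ndarray:
        """NIfTI-style 4x4 affine mapping voxel index to world mm."""
        A = np.eye(4)
        A[:3, :3] = np.diag(self.voxel_size)
        A[:3, 3] = self.origin
        return A

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def same_geometry(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class LabelVolume:
    """3D integer tissue-label image with voxel geometry.

    ``label_table`` maps integer codes to tissue names; background outside
    the head is coded ``air``.  ``cc_mask`` optionally marks a midline
    white-matter block used as a corpus-callosum-analog ROI.
    """

    grid: Grid
    labels: np.ndarray
    label_table: dict[int, str]
    cc_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid shape")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"voxel codes {sorted(missing)} absent from label_table")

    def code(self, tissue: str) -> int:
        for k, v in self.label_table.items():
            if v == tissue:
                return k
        raise KeyError(f"tissue {tissue!r} not in label table")

    def mask(self, *tissues: str) -> np.ndarray:
        """Boolean mask of voxels whose label is any of ``tissues``."""
        codes = [self.code(t) for t in tissues]
        return np.isin(self.labels, codes)

    def copy(self) -> "LabelVolume":
        return LabelVolume(
            grid=self.grid,
            labels=self.labels.copy(),
            label_table=dict(self.label_table),
            cc_mask=None if self.cc_mask is None else self.cc_mask.copy(),
        )


@dataclass
class TensorMap:
    """Per-voxel symmetric 3x3 tensor field (conductivity S/m or diffusivity mm^2/s).

    Stored as six unique components in the order ``xx, xy, xz, yy, yz, zz``
    (last axis).  Tensors are zero outside the validity ``mask``.
    """

    grid: Grid
    components: np.ndarray  # (*shape, 6)
    mask: np.ndarray  # (*shape,) bool
    units: str = ""

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != self.grid.shape + (6,):
            raise ValueError("components must have shape (*grid.shape, 6)")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid shape")

    @classmethod
    def from_full(cls, grid: Grid, full: np.ndarray, mask: np.ndarray, units: str = "") -> "TensorMap":
        """Build from a ``(*shape, 3, 3)`` array (symmetrized)."""
        full = np.asarray(full, dtype=float)
        sym = 0.5 * (full + np.swapaxes(full, -1, -2))
        comp = np.stack([sym[..., i, j] for i, j in _COMP_IJ], axis=-1)
        comp = np.where(np.asarray(mask, bool)[..., None], comp, 0.0)
        return cls(grid=grid, components=comp, mask=np.asarray(mask, bool), units=units)

    @classmethod
    def isotropic(cls, grid: Grid, scalar: np.ndarray, mask: np.ndarray, units: str = "") -> "TensorMap":
        """Isotropic field ``scalar * I`` per voxel."""
        comp = np.zeros(grid.shape + (6,))
        s = np.asarray(scalar, dtype=float)
        for k in (0, 3, 5):  # xx, yy, zz
            comp[..., k] = s
        comp = np.where(np.asarray(mask, bool)[..., None], comp, 0.0)
        return cls(grid=grid, components=comp, mask=np.asarray(mask, bool), units=units)

    def full(self) -> np.ndarray:
        """Expand to a ``(*shape, 3, 3)`` symmetric array."""
        out = np.zeros(self.grid.shape + (3, 3))
        for k, (i, j) in enumerate(_COMP_IJ):
            out[..., i, j] = self.components[..., k]
            out[..., j, i] = self.components[..., k]
        return out

    def eigenvalues(self) -> np.ndarray:
        """Ascending eigenvalues per voxel, shape ``(*shape, 3)``."""
        return np.linalg.eigvalsh(self.full())

    def scaled(self, factor: np.ndarray, units: str | None = None) -> "TensorMap":
        """Voxel-wise scalar multiple (mask intersected with finite factor)."""
        f = np.asarray(factor, dtype=float)
        comp = self.components * f[..., None]
        mask = self.mask & np.isfinite(f)
        comp = np.where(mask[..., None], comp, 0.0)
        return TensorMap(self.grid, comp, mask, self.units if units is None else units)
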