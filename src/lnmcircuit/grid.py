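"""Volume geometry and voxelwise map containers.

Every map in an analysis session lives on a single :class:`VolumeGrid`: a
template-space geometry (array shape, RAS+ voxel-to-world affine in mm, and
a boolean brain mask) against which every exchange between pipeline stages
is checked.  Voxel indices are 0-based; user-facing coordinates are world mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

#: absolute tolerance for declaring two affines "the same grid"
GRID_ATOL = 1e-6

#: correlations are clipped to +/-(1 - R_CLIP) before the Fisher transform
R_CLIP = 1e-7


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilising Fisher transform atanh(r), with r clipped to
    +/-(1 - 1e-7) so that seed self-correlations stay finite."""
    r = np.clip(np.asarray(r, dtype=np.float64), -(1.0 - R_CLIP), 1.0 - R_CLIP)
    return np.arctanh(r)


@dataclass(frozen=True)
class VolumeGrid:
    """Shared 3D template geometry.

    Parameters
    ----------
    shape : (3,) ints
        Voxels per axis.
    affine : (4, 4) float
        Voxel-index -> world-mm transform (RAS+ by convention).
    brain_mask : bool array of ``shape``
        Analysis mask; every statistic is computed within it.
    """

    shape: tuple
    affine: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape!r}")
        affine = np.asarray(self.affine, dtype=np.float64)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        mask = np.asarray(self.brain_mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(f"brain_mask shape {mask.shape} != grid shape {shape}")
        if not mask.any():
            raise ValueError("brain_mask has no voxels")
        affine = affine.copy()
        mask = mask.copy()
        affine.setflags(write=False)
        mask.setflags(write=False)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "brain_mask", mask)

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_in_mask(self) -> int:
        return int(self.brain_mask.sum())

    def matches(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.affine, other.affine, atol=GRID_ATOL, rtol=0.0)
        )

    def require_match(self, other: "VolumeGrid") -> None:
        if not self.matches(other):
            raise ValueError(
                "grids differ: shapes "
                f"{self.shape} vs {other.shape}, max affine deviation "
                f"{np.abs(self.affine - other.affine).max():.3g} (tol {GRID_ATOL})"
            )

    # ---- coordinate transforms -------------------------------------------

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (N, 3) or (3,) to world mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return xyz if xyz.shape[0] > 1 else xyz[0]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm to fractional 0-based voxel indices."""
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(np.asarray(xyz, dtype=np.float64))
        ijk = xyz @ inv[:3, :3].T + inv[:3, 3]
        return ijk if ijk.shape[0] > 1 else ijk[0]

    def mask_coords(self) -> np.ndarray:
        """World-mm centres of in-mask voxels, row order = ascending linear
        (C-order) index; this is the canonical voxel ordering everywhere."""
        ijk = np.argwhere(self.brain_mask)
        return np.atleast_2d(self.voxel_to_world(ijk))


def _validate_values(grid: VolumeGrid, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"{name} shape {values.shape} != grid shape {grid.shape}")
    return values


@dataclass(frozen=True)
class StatMap:
    """A voxelwise statistic image on a :class:`VolumeGrid`.

    ``kind`` is ``"fisher_z"`` for Fisher-transformed correlations, ``"t"``
    for t statistics (``df`` required), or ``"generic"`` for other spatial
    maps (e.g. receptor-density annotations).  NaN inside the brain mask is
    rejected; +/-inf is permitted only in t-maps, as the documented sentinel
    for zero-variance voxels with nonzero mean.
    """

    grid: VolumeGrid
    values: np.ndarray
    kind: str = "t"
    df: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("fisher_z", "t", "generic"):
            raise ValueError(f"unknown StatMap kind {self.kind!r}")
        values = _validate_values(self.grid, self.values, "StatMap values").astype(
            np.float64, copy=True
        )
        in_mask = values[self.grid.brain_mask]
        if np.isnan(in_mask).any():
            raise ValueError(
                f"StatMap has {int(np.isnan(in_mask).sum())} NaN voxels inside the brain mask"
            )
        if self.kind != "t" and np.isinf(in_mask).any():
            raise ValueError("non-finite values inside the brain mask (only t-maps may carry inf sentinels)")
        if self.kind == "t":
            if self.df is None or self.df < 1:
                raise ValueError("t-maps require df >= 1")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def values_in_mask(self) -> np.ndarray:
        return self.values[self.grid.brain_mask]


@dataclass(frozen=True)
class BinaryMap:
    """A 0/1 voxel set on a :class:`VolumeGrid`, constrained to the brain
    mask.  ``provenance`` records which operation/thresholds produced it."""

    grid: VolumeGrid
    values: np.ndarray
    provenance: Optional[dict] = None

    def __post_init__(self):
        raw = _validate_values(self.grid, self.values, "BinaryMap values")
        uniq = np.unique(raw)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError(f"BinaryMap values must be 0/1, found values {uniq[:5]}")
        values = raw.astype(bool)
        outside = values & ~self.grid.brain_mask
        if outside.any():
            raise ValueError(
                f"BinaryMap has {int(outside.sum())} voxels outside the brain mask"
            )
        values = values.copy()
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def values_in_mask(self) -> np.ndarray:
        return self.values[self.grid.brain_mask]


@dataclass(frozen=True)
class Bold4D:
    """A 4D BOLD series on a :class:`VolumeGrid`; frames along the last
    axis, in acquisition order."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 4 or data.shape[:3] != self.grid.shape:
            raise ValueError(
                f"Bold4D data must be (x, y, z, T) on the grid; got {data.shape}"
            )
        if data.shape[3] < 1:
            raise ValueError("Bold4D needs at least one frame")
        object.__setattr__(self, "data", data)

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[3])

    def in_mask_series(self) -> np.ndarray:
        """(n_in_mask, T) float64 series matrix, canonical voxel order."""
        return self.data[self.grid.brain_mask].astype(np.float64)


Volume = Union[StatMap, BinaryMap, Bold4D]


def dice(a: BinaryMap, b: BinaryMap) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|) between two binary maps."""
    a.grid.require_match(b.grid)
    inter = int((a.values & b.values).sum())
    denom = a.n_voxels + b.n_voxels
    if denom == 0:
        raise ValueError("Dice undefined for two empty maps")
    return 2.0 * inter / denom
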