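"""Voxel grids, brain masks and coarse-graining.

All volumes live on axis-aligned RAS grids with 0-based indices and
half-open blocks.  A :class:`VoxelMask` fixes the bijection between
in-mask voxel coordinates and the 0..P-1 feature indices used by the
classifier; every downstream object (difference operator, weight maps,
atlas aggregation) is expressed in that index space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "VoxelMask",
    "threshold_mask",
    "downsample_mean",
    "coarse_grid_shape",
]


@dataclass
class VoxelGrid:
    """A 3D scalar volume with a physical voxel size in mm."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (8.0, 8.0, 8.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        """Axis-aligned RAS affine (voxel index -> mm)."""
        a = np.diag(list(self.voxel_size_mm) + [1.0])
        return a


@dataclass
class VoxelMask:
    """Boolean in-brain mask plus the voxel<->feature index bijection.

    Feature index j corresponds to the j-th True voxel in C (row-major)
    order of the flattened grid.
    """

    inside: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (8.0, 8.0, 8.0)
    flat_indices: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.ndim != 3:
            raise ValueError("mask must be 3D")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.flat_indices = np.flatnonzero(self.inside.ravel())

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.inside.shape

    @property
    def n_features(self) -> int:
        return int(self.flat_indices.size)

    def coords(self) -> np.ndarray:
        """(P, 3) integer voxel coordinates of the in-mask voxels in feature order."""
        return np.stack(np.unravel_index(self.flat_indices, self.dims), axis=1)

    def feature_of_flat(self, flat: np.ndarray) -> np.ndarray:
        """Map flat voxel indices to feature indices (-1 when out of mask)."""
        lut = np.full(self.inside.size, -1, dtype=np.int64)
        lut[self.flat_indices] = np.arange(self.n_features)
        return lut[np.asarray(flat)]

    def embed(self, values: np.ndarray, fill: float = 0.0) -> VoxelGrid:
        """Scatter a length-P feature vector back into a full volume."""
        values = np.asarray(values)
        if values.shape != (self.n_features,):
            raise ValueError(f"expected {self.n_features} values, got {values.shape}")
        vol = np.full(self.inside.size, fill, dtype=float)
        vol[self.flat_indices] = values
        return VoxelGrid(vol.reshape(self.dims), self.voxel_size_mm)

    def boundary_shell(self) -> np.ndarray:
        """Feature indices of in-mask voxels with an out-of-mask face neighbour."""
        pad = np.pad(self.inside, 1, constant_values=False)
        core = np.ones_like(self.inside, dtype=bool)
        for ax in range(3):
            for shift in (-1, 1):
                core &= np.roll(pad, shift, axis=ax)[1:-1, 1:-1, 1:-1]
        shell = self.inside & ~core
        return self.feature_of_flat(np.flatnonzero(shell.ravel()))


def threshold_mask(template: VoxelGrid, threshold: float = 0.1) -> VoxelMask:
    """Select voxels whose template value strictly exceeds ``threshold``.

    Emulates keeping voxels with mean gray-matter probability above a
    cutoff in a population template; an empty selection is an error.
    """
    data = template.data
    if data.min() < 0 or data.max() > 1:
        raise ValueError("template values must lie in [0, 1]")
    inside = data > threshold
    if not inside.any():
        raise ValueError("threshold produced an empty mask")
    return VoxelMask(inside, template.voxel_size_mm)


def downsample_mean(fine: VoxelGrid, block_shape: tuple[int, int, int]) -> VoxelGrid:
    """Mean-pool a fine grid into blocks; partial edge blocks average
    over the fine voxels they actually contain.  Output dims are
    ceil(fine_dims / block_shape)."""
    block = tuple(int(b) for b in block_shape)
    if any(b <= 0 for b in block):
        raise ValueError("block shape must be positive")
    d = fine.data.astype(float)
    out_dims = tuple(-(-s // b) for s, b in zip(d.shape, block))
    pad = [(0, o * b - s) for s, b, o in zip(d.shape, block, out_dims)]
    padded = np.pad(d, pad, constant_values=np.nan)
    r = padded.reshape(
        out_dims[0], block[0], out_dims[1], block[1], out_dims[2], block[2]
    )
    with np.errstate(invalid="ignore"):
        coarse = np.nanmean(r, axis=(1, 3, 5))
    vs = tuple(v * b for v, b in zip(fine.voxel_size_mm, block))
    return VoxelGrid(coarse, vs)


def coarse_grid_shape(
    fine_dims: tuple[int, int, int],
    fine_size_mm: float | tuple[float, float, float],
    coarse_size_mm: float | tuple[float, float, float],
    convention: str = "gridpoints",
) -> tuple[int, int, int]:
    """Number of coarse voxels per axis when regridding by physical size.

    The mapping from a fine extent to a coarse voxel count is a pure
    convention.  ``gridpoints`` counts coarse grid planes across the fine
    extent including both boundary planes, ``round``/``ceil``/``floor``
    apply the corresponding rounding to extent / coarse size.  With
    ``gridpoints``, a 121x145x121 grid at 1.5 mm maps to 24x28x24 at 8 mm.
    """
    fs = np.broadcast_to(np.asarray(fine_size_mm, dtype=float), (3,))
    cs = np.broadcast_to(np.asarray(coarse_size_mm, dtype=float), (3,))
    x = np.asarray(fine_dims) * fs / cs
    if convention == "gridpoints":
        out = np.round(x).astype(int) + 1
    elif convention == "round":
        out = np.round(x).astype(int)
    elif convention == "ceil":
        out = np.ceil(x).astype(int)
    elif convention == "floor":
        out = np.floor(x).astype(int)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return tuple(int(v) for v in out)
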