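"""Voxel containers shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .geometry import ScanGeometry

Channel = Literal["scatter", "particle", "gfp"]
CHANNELS: tuple[Channel, ...] = ("scatter", "particle", "gfp")

__all__ = ["VolumeImage", "TileStack", "Channel", "CHANNELS"]


@dataclass
class VolumeImage:
    """Axis-aligned 3-D voxel grid for one channel.

    ``data`` is indexed ``(z, y, x)``; ``voxel_size_um`` and ``origin_um``
    follow the same axis order. Voxels with no observed data carry NaN.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel: str = "gfp"
    timepoint_h: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VolumeImage data must be 3-D (z, y, x)")
        if min(self.voxel_size_um) <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx * 1e-9

    def with_data(self, data: np.ndarray, **overrides) -> "VolumeImage":
        """Copy of this volume with new voxel data (same grid)."""
        out = replace(self, **overrides)
        out.data = np.asarray(data)
        return out

    def same_grid(self, other: "VolumeImage", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_um, other.voxel_size_um, atol=atol)
            and np.allclose(self.origin_um, other.origin_um, atol=atol)
        )


@dataclass
class TileStack:
    """Raw sheared camera frames of one scan pass of one tile.

    ``frames`` is indexed ``(slice, row, col)`` = ``(k, v, u)``; rows map to
    y and columns to x, with successive slices displaced along x by
    ``scan.shear_per_slice_um`` in sample space.
    """

    frames: np.ndarray
    channel: str
    tile_index: tuple[int, int]  # (i=x tile, j=y tile)
    scan: ScanGeometry
    pixel_size_um: tuple[float, float] = (25.0, 25.0)  # (row=y, col=x)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)  # tile (z0, y0, x0)
    timepoint_h: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("TileStack frames must be 3-D (slice, row, col)")
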