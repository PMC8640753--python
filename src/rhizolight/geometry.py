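"""Chamber, scan and optics geometry.

Conventions used throughout the package:

* internal length unit is the micrometre (µm); public configuration is
  labelled mm/µm/h as appropriate;
* array axis order is ``(z, y, x)`` with ``z`` the detection axis through
  the thin dimension of the chamber, ``y`` the long (vertical) axis and
  ``x`` the short horizontal axis; indices are 0-based, extents half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ChamberGeometry",
    "OpticsModel",
    "ScanGeometry",
    "NoiseModel",
]


@dataclass(frozen=True)
class ChamberGeometry:
    """Cuboid mesocosm chamber, dimensions in mm.

    ``width_mm`` maps to the x axis, ``height_mm`` to y, ``depth_mm`` to z
    (the detection axis through the thin side of the chamber).
    """

    width_mm: float = 22.0
    height_mm: float = 65.0
    depth_mm: float = 3.0

    def __post_init__(self) -> None:
        if min(self.width_mm, self.height_mm, self.depth_mm) <= 0:
            raise ValueError("chamber dimensions must be positive")

    @property
    def volume_mm3(self) -> float:
        return self.width_mm * self.height_mm * self.depth_mm

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """(z, y, x) extent in µm."""
        return (self.depth_mm * 1e3, self.height_mm * 1e3, self.width_mm * 1e3)


@dataclass(frozen=True)
class OpticsModel:
    """Parametric light-sheet optics: Gaussian sheet and lateral PSF.

    The sheet thickness is treated as constant over the field of view
    (beam divergence within the Rayleigh range is ignored).
    """

    sheet_fwhm_um: float = 50.0
    lateral_fwhm_um: float = 25.0
    wavelength_nm: float = 488.0
    sheet_height_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.sheet_fwhm_um <= 0 or self.lateral_fwhm_um <= 0:
            raise ValueError("PSF FWHM values must be positive")


@dataclass(frozen=True)
class ScanGeometry:
    """Geometry of one tiled 45°-axis scan.

    ``slice_step_um`` is the stage step along the tilted scan axis. With
    scan angle θ the deskewed axial (z) spacing between consecutive frames
    is ``slice_step·cosθ`` and the in-frame lateral shift per slice is
    ``slice_step·sinθ`` (k·step/√2 at 45°).
    """

    scan_angle_deg: float = 45.0
    slice_step_um: float = 50.0
    slices_per_tile: int = 200
    tile_grid: tuple[int, int] = (1, 10)  # (n_horizontal=x, n_vertical=y)
    tile_overlap_fraction: float = 0.2
    vertical_step_mm: float = 4.0
    footprint_mm: tuple[float, float] = (20.0, 60.0)  # (x, y)
    chamber: ChamberGeometry = field(default_factory=ChamberGeometry)

    def __post_init__(self) -> None:
        if not (0 <= self.tile_overlap_fraction < 1):
            raise ValueError("tile overlap fraction must lie in [0, 1)")
        if self.slice_step_um <= 0 or self.slices_per_tile < 1:
            raise ValueError("invalid slice step or count")

    @property
    def scan_angle_rad(self) -> float:
        return math.radians(self.scan_angle_deg)

    @property
    def axial_step_um(self) -> float:
        """z spacing between deskewed slices: step·cosθ."""
        return self.slice_step_um * math.cos(self.scan_angle_rad)

    @property
    def shear_per_slice_um(self) -> float:
        """In-frame x displacement per slice: step·sinθ."""
        return self.slice_step_um * math.sin(self.scan_angle_rad)

    @property
    def imaged_volume_mm3(self) -> float:
        """Scan footprint swept through depth, clipped to the chamber.

        The scan can address more depth than the chamber holds; the imaged
        sample volume is the footprint times the chamber thickness.
        """
        fx, fy = self.footprint_mm
        swept_depth = self.axial_step_um * self.slices_per_tile / 1e3
        depth = min(swept_depth, self.chamber.depth_mm) if swept_depth > 0 else self.chamber.depth_mm
        return fx * fy * min(depth, self.chamber.depth_mm)


@dataclass(frozen=True)
class NoiseModel:
    """Detector model for the forward renderer.

    ``vignetting_min`` parameterizes the default separable cosine fall-off
    field (value at frame corners); an explicit 2-D field can be passed to
    the renderer instead.
    """

    photon_gain: float = 1.0
    read_noise_sd: float = 0.0
    background_offset: float = 0.0
    vignetting_min: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.vignetting_min <= 1):
            raise ValueError("vignetting minimum must lie in (0, 1]")
        if self.read_noise_sd < 0:
            raise ValueError("read noise must be non-negative")


def vignetting_field(shape: tuple[int, int], minimum: float = 0.6):
    """Separable cosine fall-off illumination field, 1 at centre, ``minimum``
    at the corners; values in (0, 1]."""
    import numpy as np

    if not (0 < minimum <= 1):
        raise ValueError("minimum must lie in (0, 1]")
    ny, nx = shape
    # per-axis fall-off sqrt(minimum) so the corner product equals minimum
    edge = math.sqrt(minimum)
    wy = edge + (1 - edge) * np.cos(np.linspace(-np.pi / 2, np.pi / 2, ny)) if ny > 1 else np.ones(1)
    wx = edge + (1 - edge) * np.cos(np.linspace(-np.pi / 2, np.pi / 2, nx)) if nx > 1 else np.ones(1)
    return np.outer(wy, wx)
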