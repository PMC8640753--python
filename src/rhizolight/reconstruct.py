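"""Deskew, light-sheet PSF and Richardson–Lucy deconvolution."""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import fftconvolve

from .geometry import OpticsModel
from .volume import TileStack, VolumeImage

__all__ = ["shear_correct", "LightSheetPSF", "make_lightsheet_psf", "lr_deconvolve"]


def shear_correct(tile: TileStack) -> VolumeImage:
    """Invert the 45°-scan shear of one raw tile stack.

    The inverse single-axis shear is applied with nearest-neighbour
    interpolation: output voxel (k, v, u) on the axis-aligned grid with
    axial spacing ``step·cosθ`` takes frame pixel
    ``(k, v, round(u − k·step·sinθ/dx))``. Voxels with no source pixel are
    filled with NaN.
    """
    scan = tile.scan
    if scan.scan_angle_deg is None or not math.isfinite(scan.scan_angle_deg):
        raise ValueError("tile metadata carries no valid scan angle")
    dy, dx = tile.pixel_size_um
    nk, nv, nu = tile.frames.shape
    shear_px = scan.shear_per_slice_um / dx

    out = np.full((nk, nv, nu), np.nan)
    u = np.arange(nu)
    for k in range(nk):
        src = np.rint(u - k * shear_px).astype(int)
        ok = (src >= 0) & (src < nu)
        out[k, :, ok] = tile.frames[k][:, src[ok]].T
    return VolumeImage(
        data=out,
        voxel_size_um=(scan.axial_step_um, dy, dx),
        origin_um=tile.origin_um,
        channel=tile.channel,
        timepoint_h=tile.timepoint_h,
    )


class LightSheetPSF:
    """Separable anisotropic Gaussian PSF on the volume's voxel grid.

    Axial (z, detection) sigma comes from the sheet FWHM, in-plane sigma
    from the lateral FWHM; the kernel is truncated at 3σ and normalized to
    unit sum.
    """

    def __init__(self, kernel: np.ndarray, sheet_fwhm_um: float, lateral_fwhm_um: float):
        kernel = np.asarray(kernel, dtype=float)
        if kernel.min() < 0:
            raise ValueError("PSF kernel must be non-negative")
        if abs(kernel.sum() - 1.0) > 1e-6:
            raise ValueError("PSF kernel must sum to 1")
        self.kernel = kernel
        self.sheet_fwhm_um = sheet_fwhm_um
        self.lateral_fwhm_um = lateral_fwhm_um


_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # ≈ 1/2.355


def make_lightsheet_psf(optics: OpticsModel, voxel_size_um) -> LightSheetPSF:
    """Build the Gaussian light-sheet PSF sampled at the voxel size."""
    dz, dy, dx = voxel_size_um
    fwhms = (optics.sheet_fwhm_um, optics.lateral_fwhm_um, optics.lateral_fwhm_um)
    for f, v in zip(fwhms, (dz, dy, dx)):
        if f < v:
            raise ValueError(
                f"PSF FWHM {f} µm undersampled by voxel size {v} µm"
            )
    axes = []
    for f, v in zip(fwhms, (dz, dy, dx)):
        sigma = f * _FWHM_TO_SIGMA / v  # voxels
        half = max(1, int(math.ceil(3 * sigma)))
        x = np.arange(-half, half + 1)
        axes.append(np.exp(-0.5 * (x / sigma) ** 2))
    kernel = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
    kernel /= kernel.sum()
    return LightSheetPSF(kernel, optics.sheet_fwhm_um, optics.lateral_fwhm_um)


def _conv_reflect(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same' convolution with reflective edge padding (FFT-based)."""
    pads = [(s // 2, s // 2) for s in kernel.shape]
    padded = np.pad(data, pads, mode="reflect")
    full = fftconvolve(padded, kernel, mode="same")
    sl = tuple(slice(p, p + n) for (p, _), n in zip(pads, data.shape))
    return full[sl]


def lr_deconvolve(
    volume: VolumeImage, psf: LightSheetPSF, iterations: int = 10
) -> VolumeImage:
    """Richardson–Lucy deconvolution (multiplicative ML updates under a
    Poisson noise model).

    The estimate is initialized with the data; edges are handled by
    reflective padding. With a normalized PSF the update conserves total
    intensity, keeps the estimate non-negative, and never decreases the
    Poisson likelihood of the blurred estimate given the data.
    """
    if iterations < 1:
        raise ValueError("iterations must be ≥ 1")
    data = np.asarray(volume.data, dtype=float)
    finite = np.isfinite(data)
    if np.any(data[finite] < 0):
        raise ValueError("Richardson–Lucy requires non-negative input voxels")
    work = np.where(finite, data, 0.0)

    kernel = psf.kernel
    kernel_t = kernel[::-1, ::-1, ::-1]
    # denominator floor keeps 0/0 regions inert without overflowing
    floor = 1e-12 * max(1.0, float(work.max()))
    est = work.copy()
    for _ in range(iterations):
        blurred = _conv_reflect(est, kernel)
        ratio = np.where(work > 0, work / np.maximum(blurred, floor), 0.0)
        est = est * _conv_reflect(ratio, kernel_t)
    est = np.clip(est, 0.0, None)
    est[~finite] = np.nan
    return volume.with_data(est)


def poisson_loglike(estimate: np.ndarray, psf: LightSheetPSF, data: np.ndarray) -> float:
    """Poisson log-likelihood (up to data-only constants) of ``data`` given
    a blurred ``estimate``; the quantity Richardson–Lucy ascends."""
    blurred = np.maximum(_conv_reflect(estimate, psf.kernel), np.finfo(float).tiny)
    finite = np.isfinite(data)
    d = data[finite]
    b = blurred[finite]
    return float(np.sum(d * np.log(b) - b))
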