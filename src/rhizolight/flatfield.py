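"""Mode-based flat-field estimation and Laplacian-pyramid correction.

Packed soil is a textured material: grains repeat across the field of
view, so the per-pixel *mode* of intensity over many frames estimates the
illumination/detection profile up to a global constant. The correction is
a multiplicative weight matrix (reference mode / local mode) applied to
the band-pass levels of a Laplacian pyramid so that low-frequency shading
is corrected without ringing at texture edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .volume import VolumeImage

__all__ = ["FlatFieldModel", "estimate_flatfield", "apply_flatfield"]

WEIGHT_CLIP = (0.2, 5.0)


@dataclass
class FlatFieldModel:
    """Multiplicative flat-field correction.

    ``weight_matrix`` has the camera frame shape; correcting a frame equal
    to the estimated illumination field yields a flat frame.
    """

    weight_matrix: np.ndarray
    mode_reference: float
    neighborhood_px: int = 9
    pyramid_levels: int = 3

    def __post_init__(self) -> None:
        if np.any(self.weight_matrix <= 0):
            raise ValueError("flat-field weights must be positive")


def estimate_flatfield(
    frames: np.ndarray,
    neighborhood_px: int = 9,
    bin_width: float | None = None,
    n_bins: int = 256,
    pyramid_levels: int = 3,
) -> FlatFieldModel:
    """Estimate the flat-field weight matrix from a stack of frames.

    For every pixel, intensities from the whole dataset within a square
    neighbourhood are pooled into a histogram (bin width defaulting to
    1/256 of the dynamic range) and the mode taken; the weight is the
    global reference mode divided by the local mode, clipped to [0.2, 5].

    Parameters
    ----------
    frames
        (n_frames, H, W) array; ≥ 20 frames recommended.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be (n_frames, H, W)")
    finite = np.isfinite(frames)
    lo = float(np.nanmin(frames))
    hi = float(np.nanmax(frames))
    if not np.isfinite(lo) or hi <= 0:
        raise ValueError("degenerate dataset: no positive intensities to estimate a flat field")
    if hi == lo:
        # perfectly flat input: mode is the constant everywhere, weights 1
        return FlatFieldModel(np.ones(frames.shape[1:]), hi, neighborhood_px, pyramid_levels)
    if bin_width is None:
        bin_width = (hi - lo) / n_bins
    nb = max(1, int(math.ceil((hi - lo) / bin_width)) + 1)
    idx = np.clip(((frames - lo) / bin_width), 0, nb - 1)
    idx = np.where(finite, idx, 0).astype(np.int32)

    # per-pixel histogram over the dataset, then box-filtered over the
    # neighbourhood: counts[b, y, x] = #frames with bin b near (y, x)
    h, w = frames.shape[1:]
    counts = np.zeros((nb, h, w), dtype=np.float32)
    for b in range(nb):
        counts[b] = np.sum((idx == b) & finite, axis=0)
        counts[b] = ndi.uniform_filter(counts[b], size=neighborhood_px, mode="nearest")
    local_mode_bin = np.argmax(counts, axis=0)
    local_mode = lo + (local_mode_bin + 0.5 + _parabolic_offset(counts, local_mode_bin)) * bin_width

    total_hist = counts.reshape(nb, -1).sum(axis=1)
    ref_bin = int(np.argmax(total_hist))
    ref_off = 0.0
    if 0 < ref_bin < nb - 1:
        denom = total_hist[ref_bin - 1] - 2 * total_hist[ref_bin] + total_hist[ref_bin + 1]
        if denom < 0:
            ref_off = float(np.clip(0.5 * (total_hist[ref_bin - 1] - total_hist[ref_bin + 1]) / denom, -0.5, 0.5))
    reference = lo + (ref_bin + 0.5 + ref_off) * bin_width
    if reference <= 0:
        raise ValueError("degenerate dataset: reference mode is non-positive")

    with np.errstate(divide="ignore"):
        weights = np.where(local_mode > 0, reference / np.maximum(local_mode, 1e-30), WEIGHT_CLIP[1])
    # the illumination/detection profile is smooth; suppress residual
    # per-pixel mode noise at the neighbourhood scale
    weights = ndi.gaussian_filter(weights, neighborhood_px / 2, mode="nearest")
    weights = np.clip(weights, *WEIGHT_CLIP)
    return FlatFieldModel(weights, reference, neighborhood_px, pyramid_levels)


def _parabolic_offset(counts: np.ndarray, peak_bin: np.ndarray) -> np.ndarray:
    """Sub-bin refinement of per-pixel histogram peaks by fitting a
    parabola through the peak bin and its neighbours."""
    nb = counts.shape[0]
    grid = np.indices(peak_bin.shape)
    lo_bin = np.clip(peak_bin - 1, 0, nb - 1)
    hi_bin = np.clip(peak_bin + 1, 0, nb - 1)
    c0 = counts[(lo_bin, *grid)]
    c1 = counts[(peak_bin, *grid)]
    c2 = counts[(hi_bin, *grid)]
    denom = c0 - 2 * c1 + c2
    off = np.zeros(peak_bin.shape)
    ok = (denom < 0) & (peak_bin > 0) & (peak_bin < nb - 1)
    off[ok] = np.clip(0.5 * (c0[ok] - c2[ok]) / denom[ok], -0.5, 0.5)
    return off


# ---------------------------------------------------------------- pyramids

def _reduce(img: np.ndarray) -> np.ndarray:
    return ndi.zoom(ndi.gaussian_filter(img, 1.0, mode="nearest"), 0.5, order=1, grid_mode=True, mode="nearest")


def _expand(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    factors = (shape[0] / img.shape[0], shape[1] / img.shape[1])
    return ndi.zoom(img, factors, order=1, grid_mode=True, mode="nearest")


def _laplacian_pyramid(img: np.ndarray, levels: int):
    gauss = [img]
    for _ in range(levels - 1):
        if min(gauss[-1].shape) < 4:
            break
        gauss.append(_reduce(gauss[-1]))
    lap = []
    for i in range(len(gauss) - 1):
        lap.append(gauss[i] - _expand(gauss[i + 1], gauss[i].shape))
    lap.append(gauss[-1])
    return lap


def _reconstruct(lap) -> np.ndarray:
    img = lap[-1]
    for level in lap[-2::-1]:
        img = level + _expand(img, level.shape)
    return img


def correct_frame(
    frame: np.ndarray, model: FlatFieldModel, level_gains=None
) -> np.ndarray:
    """Apply the weight matrix to one frame through its Laplacian pyramid.

    The frame is decomposed into band-pass levels; each level is expanded
    back to frame resolution, scaled by the weight matrix (optionally
    attenuated per level via ``level_gains``, finest first), and the
    bands summed. With one pyramid level, or uniform gains, this equals
    plain per-pixel multiplication.
    """
    if frame.shape != model.weight_matrix.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match weight matrix "
            f"{model.weight_matrix.shape}"
        )
    levels = max(1, model.pyramid_levels)
    if levels == 1:
        return np.clip(frame * model.weight_matrix, 0.0, None)
    lap = _laplacian_pyramid(frame, levels)
    if level_gains is None:
        level_gains = [1.0] * len(lap)
    shapes = [frame.shape]
    for lv in lap[1:]:
        shapes.append(lv.shape)
    out = np.zeros_like(frame, dtype=float)
    for i, (lv, gain) in enumerate(zip(lap, level_gains)):
        full = lv
        for target in shapes[i - 1 :: -1] if i else []:
            full = _expand(full, target)
        out += gain * full * model.weight_matrix
    return np.clip(out, 0.0, None)


def apply_flatfield(volume: VolumeImage | np.ndarray, model: FlatFieldModel):
    """Correct every frame of a stack or volume (axis 0 = slices).

    Returns the same type as the input. NaN fill voxels pass through
    unchanged.
    """
    is_volume = isinstance(volume, VolumeImage)
    data = np.asarray(volume.data if is_volume else volume, dtype=float)
    finite = np.isfinite(data)
    work = np.where(finite, data, 0.0)
    out = np.empty_like(work)
    for k in range(work.shape[0]):
        out[k] = correct_frame(work[k], model)
    out[~finite] = np.nan
    if is_volume:
        return volume.with_data(out)
    return out
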