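"""Synthetic mesocosm phantoms.

Ground-truth scenes — a particle packing, a root that elongates over hourly
time points, and a bacterial density field with near-root accumulation,
pulsatile hotspots and small-pore preference — rendered through the
light-sheet forward model (45° scan shear, Gaussian PSF, vignetting,
detector noise). Every downstream stage of the pipeline is tested against
these phantoms because the programmed parameters are known exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .geometry import ChamberGeometry, NoiseModel, OpticsModel, ScanGeometry, vignetting_field
from .volume import TileStack, VolumeImage

__all__ = [
    "ParticlePacking",
    "RootModel",
    "BacteriaFieldSpec",
    "PackingError",
    "CoverageError",
    "make_particle_packing",
    "rasterize_particles",
    "grow_root",
    "rasterize_root",
    "bacteria_density_field",
    "render_scan",
    "MesocosmPhantom",
]


class PackingError(RuntimeError):
    """Raised when a target porosity cannot be reached by sequential addition."""


class CoverageError(RuntimeError):
    """Raised when the configured tile grid does not cover the truth volume."""


# --------------------------------------------------------------------------
# particle packing

@dataclass
class ParticlePacking:
    """Random sequential addition packing of non-overlapping spheres.

    ``particles`` rows are ``(z, y, x, radius)`` in µm. Porosity is the
    analytic void fraction 1 − Σ(4/3 π r³) / V.
    """

    particles: np.ndarray  # (n, 4): z, y, x, radius in µm
    domain: ChamberGeometry

    @property
    def porosity(self) -> float:
        if len(self.particles) == 0:
            return 1.0
        solid = np.sum(4.0 / 3.0 * np.pi * self.particles[:, 3] ** 3)
        return float(1.0 - solid / (self.domain.volume_mm3 * 1e9))

    @property
    def n_particles(self) -> int:
        return len(self.particles)


def make_particle_packing(
    chamber: ChamberGeometry,
    size_range_um: tuple[float, float] = (250.0, 1250.0),
    target_porosity: float = 0.45,
    seed: int = 0,
    tolerance: float = 0.02,
    max_failures: int = 20000,
) -> ParticlePacking:
    """Pack non-overlapping spheres until the porosity reaches the target.

    Grain *diameters* are drawn uniformly from ``size_range_um`` (sandy-soil
    grain sizes, 0.25–1.25 mm by default). Spheres are inserted by random
    sequential addition, larger grains first to approach dense packings,
    and must lie fully inside the chamber. Insertion never overshoots:
    a grain that would push the porosity below the target is rejected.

    Raises
    ------
    PackingError
        if the target porosity is unreachable (jamming); the message names
        the achieved porosity.
    """
    dmin, dmax = size_range_um
    if not (0 < dmin < dmax):
        raise ValueError("size range must satisfy 0 < min < max")
    if not (0 < target_porosity <= 1):
        raise ValueError("target porosity must lie in (0, 1]")

    ext = np.array(chamber.extent_um)  # (z, y, x)
    volume_um3 = float(np.prod(ext))
    rng = np.random.default_rng(seed)

    if target_porosity >= 1.0:
        return ParticlePacking(np.empty((0, 4)), chamber)

    centers: list[np.ndarray] = []
    radii: list[float] = []
    solid = 0.0
    porosity = 1.0
    tries_per_grain = max(50, max_failures // 100)

    reached = False
    while not reached:
        # draw a batch of diameters, largest first: large grains placed
        # early pack better under sequential addition
        batch = np.sort(rng.uniform(dmin, dmax, size=512))[::-1]
        placed_any = False
        for d in batch:
            r = d / 2.0
            if 2 * r > min(ext):
                continue
            vol = 4.0 / 3.0 * math.pi * r**3
            if 1.0 - (solid + vol) / volume_um3 < target_porosity:
                continue  # this grain would overshoot the target
            carr = np.asarray(centers) if centers else None
            rarr = np.asarray(radii) if centers else None
            for _ in range(tries_per_grain):
                c = rng.uniform(r, ext - r)
                if carr is not None:
                    d2 = np.sum((carr - c) ** 2, axis=1)
                    if np.any(d2 < (rarr + r) ** 2):
                        continue
                centers.append(c)
                radii.append(r)
                solid += vol
                porosity = 1.0 - solid / volume_um3
                placed_any = True
                break
            if porosity - target_porosity <= tolerance:
                reached = True
                break
        if not reached and not placed_any:
            break  # jammed: a whole batch of grains found no room

    if porosity - target_porosity > tolerance:
        raise PackingError(
            f"target porosity {target_porosity:.3f} unreachable; "
            f"achieved {porosity:.3f} with {len(centers)} grains"
        )

    if centers:
        particles = np.column_stack([np.asarray(centers), np.asarray(radii)])
    else:
        particles = np.empty((0, 4))
    return ParticlePacking(particles, chamber)


def rasterize_particles(
    packing: ParticlePacking, voxel_size_um: float
) -> np.ndarray:
    """Boolean (z, y, x) mask of particle interiors at the given voxel size.

    A voxel belongs to a grain when its centre lies inside the sphere.
    """
    ext = np.array(packing.domain.extent_um)
    shape = tuple(int(round(e / voxel_size_um)) for e in ext)
    mask = np.zeros(shape, dtype=bool)
    s = voxel_size_um
    for z, y, x, r in packing.particles:
        lo = [max(0, int((c - r) / s)) for c in (z, y, x)]
        hi = [min(n, int((c + r) / s) + 2) for c, n in zip((z, y, x), shape)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        d2 = (
            ((zz + 0.5) * s - z) ** 2
            + ((yy + 0.5) * s - y) ** 2
            + ((xx + 0.5) * s - x) ** 2
        )
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r
    return mask


# --------------------------------------------------------------------------
# root

@dataclass
class RootModel:
    """Elongating root: ordered centerline polyline with a radius profile.

    The tip is the last centerline node; arc length grows linearly with
    time at ``elongation_rate_um_h``.
    """

    centerline: np.ndarray  # (n, 3) µm, (z, y, x), base → tip
    radius_profile: np.ndarray  # (n,) µm
    elongation_rate_um_h: float
    timepoint_h: float
    truncated: bool = False

    @property
    def tip_position(self) -> np.ndarray:
        return self.centerline[-1]

    @property
    def length_um(self) -> float:
        seg = np.diff(self.centerline, axis=0)
        return float(np.sum(np.linalg.norm(seg, axis=1)))


def grow_root(
    base: Sequence[float],
    direction: Sequence[float],
    radius_um: float = 250.0,
    elongation_rate_um_h: float = 200.0,
    timepoint_h: float = 0.0,
    initial_length_um: float = 2000.0,
    chamber: ChamberGeometry | None = None,
    node_spacing_um: float = 50.0,
) -> RootModel:
    """Straight root growing from ``base`` along ``direction``.

    Arc length at time t is ``initial_length + rate·t`` (seedlings start at
    ~2 mm). If a chamber is given and the tip would leave it, the
    centerline is clipped to the chamber and the model flagged truncated.
    """
    if timepoint_h < 0 or elongation_rate_um_h < 0:
        raise ValueError("timepoint and elongation rate must be non-negative")
    if radius_um <= 0:
        raise ValueError("root radius must be positive")
    base = np.asarray(base, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    length = initial_length_um + elongation_rate_um_h * timepoint_h

    truncated = False
    if chamber is not None:
        ext = np.array(chamber.extent_um)
        # first exit of the ray from the chamber box
        with np.errstate(divide="ignore"):
            t_exit = np.where(d > 0, (ext - base) / np.where(d == 0, np.inf, d),
                              np.where(d < 0, -base / np.where(d == 0, -np.inf, d), np.inf))
        max_len = float(np.min(t_exit))
        if length > max_len:
            length = max(max_len, 0.0)
            truncated = True

    n = max(2, int(math.ceil(length / node_spacing_um)) + 1)
    t = np.linspace(0.0, length, n)
    centerline = base[None, :] + t[:, None] * d[None, :]
    radii = np.full(n, float(radius_um))
    # taper toward the tip over the last ~3 radii
    taper = min(3 * radius_um, length / 2)
    if taper > 0:
        w = np.clip((length - t) / taper, 0.2, 1.0)
        radii = radii * w
    return RootModel(centerline, radii, elongation_rate_um_h, timepoint_h, truncated)


def rasterize_root(root: RootModel, shape: tuple[int, int, int], voxel_size_um: float) -> np.ndarray:
    """Boolean (z, y, x) mask of the root body: union of spheres swept
    along the centerline with the local radius."""
    mask = np.zeros(shape, dtype=bool)
    s = voxel_size_um
    # resample centerline densely so swept spheres overlap
    pts, radii = _densify(root.centerline, root.radius_profile, s / 2)
    for (z, y, x), r in zip(pts, radii):
        lo = [max(0, int((c - r) / s)) for c in (z, y, x)]
        hi = [min(n, int((c + r) / s) + 2) for c, n in zip((z, y, x), shape)]
        if any(l >= h for l, h in zip(lo, hi)):
            continue
        zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        d2 = (
            ((zz + 0.5) * s - z) ** 2
            + ((yy + 0.5) * s - y) ** 2
            + ((xx + 0.5) * s - x) ** 2
        )
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r
    return mask


def _densify(points: np.ndarray, radii: np.ndarray, spacing: float):
    seg = np.diff(points, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total == 0:
        return points[:1], radii[:1]
    n = max(2, int(math.ceil(total / spacing)) + 1)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(t, arclen, points[:, k])
    r = np.interp(t, arclen, radii)
    return out, r


# --------------------------------------------------------------------------
# bacterial density field

@dataclass(frozen=True)
class BacteriaFieldSpec:
    """Programmed bacterial density field (CFU·mL⁻¹).

    The field is the sum of a bulk background, a near-root accumulation
    decaying exponentially with distance from the root surface, and
    pulsatile hotspots active when ``(t mod period) < duration``. Voxels in
    pores narrower than ``pore_bias_threshold_um`` are weighted by
    ``pore_bias_strength`` (small-pore preference). Optional temporal
    envelopes program the colonization timeline: a Gaussian bulk envelope
    peaking at ``bulk_peak_h`` and a near-root envelope peaking at
    ``root_peak_h``.
    """

    source_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hotspot_period_h: float = 4.0
    hotspot_duration_h: float = 2.0
    pore_bias_threshold_um: float = 400.0
    pore_bias_strength: float = 3.0
    root_accumulation_scale_um: float = 500.0
    background_density: float = 2.0e7
    root_density: float = 2.0e8
    hotspot_density: float = 4.0e8
    hotspot_sigma_um: float = 300.0
    n_hotspots: int = 6
    hotspot_min_separation_um: float = 1000.0
    phase_jitter_h: float = 0.0
    bulk_peak_h: float | None = None
    root_peak_h: float | None = None
    bulk_envelope_sigma_h: float = 4.0
    root_envelope_sigma_h: float = 8.0

    def __post_init__(self) -> None:
        if not (self.hotspot_period_h > self.hotspot_duration_h > 0):
            raise ValueError("hotspot period must exceed duration, both > 0")
        if self.pore_bias_strength < 1:
            raise ValueError("pore bias strength must be ≥ 1")
        if min(self.background_density, self.root_density, self.hotspot_density) < 0:
            raise ValueError("densities must be non-negative")

    def hotspot_active(self, timepoint_h: float, phase_h: float = 0.0) -> bool:
        return ((timepoint_h - phase_h) % self.hotspot_period_h) < self.hotspot_duration_h


def _envelope(t: float, peak: float | None, sigma: float) -> float:
    if peak is None:
        return 1.0
    return math.exp(-0.5 * ((t - peak) / sigma) ** 2)


def place_hotspots(
    spec: BacteriaFieldSpec,
    pore_mask: np.ndarray,
    voxel_size_um: float,
    seed: int,
) -> np.ndarray:
    """Seeded Poisson-disc–style hotspot centres inside the pore space.

    The first centre is the pore voxel nearest the inoculation source;
    the rest are drawn by rejection with a minimum separation.
    """
    rng = np.random.default_rng(seed)
    cand = np.argwhere(pore_mask)
    if len(cand) == 0 or spec.n_hotspots == 0:
        return np.empty((0, 3))
    phys = (cand + 0.5) * voxel_size_um
    src = np.asarray(spec.source_point, dtype=float)
    first = phys[np.argmin(np.sum((phys - src) ** 2, axis=1))]
    centres = [first]
    order = rng.permutation(len(phys))
    for idx in order:
        if len(centres) >= spec.n_hotspots:
            break
        p = phys[idx]
        d2 = np.sum((np.asarray(centres) - p) ** 2, axis=1)
        if np.all(d2 >= spec.hotspot_min_separation_um**2):
            centres.append(p)
    return np.asarray(centres)


def bacteria_density_field(
    spec: BacteriaFieldSpec,
    root_mask: np.ndarray,
    pore_size_map: np.ndarray,
    voxel_size_um: float,
    timepoint_h: float,
    seed: int = 0,
    hotspot_centres: np.ndarray | None = None,
) -> np.ndarray:
    """Ground-truth bacterial density (CFU·mL⁻¹) per voxel at one time.

    ``root_mask`` and ``pore_size_map`` must share the grid. The density
    lives in the pore liquid: it is zero inside grains and inside the root.
    """
    if root_mask.shape != pore_size_map.shape:
        raise ValueError(
            f"grid mismatch: root mask {root_mask.shape} vs pore map {pore_size_map.shape}"
        )
    pore_mask = pore_size_map > 0
    shape = root_mask.shape

    field = np.zeros(shape, dtype=float)
    field += spec.background_density * _envelope(
        timepoint_h, spec.bulk_peak_h, spec.bulk_envelope_sigma_h
    )

    if root_mask.any() and spec.root_density > 0:
        d_root = ndi.distance_transform_edt(~root_mask, sampling=voxel_size_um)
        field += (
            spec.root_density
            * _envelope(timepoint_h, spec.root_peak_h, spec.root_envelope_sigma_h)
            * np.exp(-d_root / spec.root_accumulation_scale_um)
        )

    if spec.n_hotspots > 0 and spec.hotspot_density > 0:
        if hotspot_centres is None:
            hotspot_centres = place_hotspots(spec, pore_mask, voxel_size_um, seed)
        rng = np.random.default_rng(seed + 1)
        phases = (
            rng.uniform(0, spec.phase_jitter_h, size=len(hotspot_centres))
            if spec.phase_jitter_h > 0
            else np.zeros(len(hotspot_centres))
        )
        zz, yy, xx = np.meshgrid(
            (np.arange(shape[0]) + 0.5) * voxel_size_um,
            (np.arange(shape[1]) + 0.5) * voxel_size_um,
            (np.arange(shape[2]) + 0.5) * voxel_size_um,
            indexing="ij",
            sparse=True,
        )
        for centre, phase in zip(hotspot_centres, phases):
            if not spec.hotspot_active(timepoint_h, phase):
                continue
            d2 = (zz - centre[0]) ** 2 + (yy - centre[1]) ** 2 + (xx - centre[2]) ** 2
            field += spec.hotspot_density * np.exp(-0.5 * d2 / spec.hotspot_sigma_um**2)

    bias = np.ones(shape)
    small = pore_mask & (pore_size_map < spec.pore_bias_threshold_um)
    bias[small] = spec.pore_bias_strength
    field *= bias

    field[~pore_mask] = 0.0
    field[root_mask] = 0.0
    return np.clip(field, 0.0, None)


# --------------------------------------------------------------------------
# forward renderer

def render_scan(
    truth: dict[str, VolumeImage],
    scan: ScanGeometry,
    optics: OpticsModel,
    noise: NoiseModel,
    vignetting: np.ndarray | None = None,
) -> list[TileStack]:
    """Render ground-truth channel volumes into raw sheared tile stacks.

    For each tile the truth volume (pre-blurred by the anisotropic
    Gaussian light-sheet PSF: sheet FWHM along the detection axis z,
    lateral FWHM in-plane) is sampled on planes sheared by the scan angle:
    frame pixel (k, v, u) maps to sample coordinates
    ``z = k·step·cosθ``, ``y = y0 + v·dy``, ``x = x0 + (u − pad)·dx + k·step·sinθ``.
    Vignetting multiplies each frame, then an offset and Gaussian read
    noise (seeded from ``noise.rng_seed``, per tile and channel) are added.
    Adjacent tiles share ``tile_overlap_fraction`` of their extent.
    """
    ref = next(iter(truth.values()))
    dz, dy, dx = ref.voxel_size_um
    if dz > scan.slice_step_um + 1e-9:
        raise ValueError("truth voxel size must not exceed the slice step")
    nz, ny, nx = ref.shape
    theta = scan.scan_angle_rad
    axial = scan.axial_step_um
    shear = scan.shear_per_slice_um

    n_slices = int(math.ceil((nz * dz) / axial)) if axial > 0 else nz
    if n_slices > scan.slices_per_tile:
        raise CoverageError(
            f"{scan.slices_per_tile} slices cover {scan.slices_per_tile * axial:.0f} µm axially; "
            f"truth depth is {nz * dz:.0f} µm"
        )

    ni, nj = scan.tile_grid
    ov = scan.tile_overlap_fraction
    tiles_nx, strides_x = _tile_layout(nx, ni, ov)
    tiles_ny, strides_y = _tile_layout(ny, nj, ov)

    pad = int(math.ceil((n_slices - 1) * shear / dx)) if shear > 0 else 0

    # pre-blur every channel with the light-sheet PSF
    sig = np.array([optics.sheet_fwhm_um, optics.lateral_fwhm_um, optics.lateral_fwhm_um])
    sig = sig / 2.355 / np.array([dz, dy, dx])
    blurred = {}
    for ch, vol in truth.items():
        data = np.nan_to_num(np.asarray(vol.data, dtype=float))
        blurred[ch] = ndi.gaussian_filter(data, sig, mode="constant") if sig.max() > 1e-6 else data

    out: list[TileStack] = []
    k = np.arange(n_slices)
    for j in range(nj):
        for i in range(ni):
            y0_px, x0_px = strides_y[j], strides_x[i]
            t_ny, t_nx = tiles_ny, tiles_nx
            n_u = t_nx + pad
            # sample coordinates in truth index space
            zc = (k * axial) / dz  # (K,)
            yc = y0_px + np.arange(t_ny)  # (V,)
            xc_base = x0_px - pad + np.arange(n_u)  # (U,) frame col → x px at k=0
            for ci, ch in enumerate(sorted(truth.keys())):
                zz = np.broadcast_to(zc[:, None, None], (n_slices, t_ny, n_u))
                yy = np.broadcast_to(yc[None, :, None], (n_slices, t_ny, n_u))
                xx = xc_base[None, None, :] + (k[:, None, None] * shear) / dx
                # grid-constant: samples straddling the truth boundary blend
                # with a zero background instead of vanishing outright
                frames = ndi.map_coordinates(
                    blurred[ch],
                    np.stack([zz, yy, np.broadcast_to(xx, zz.shape)]),
                    order=1,
                    mode="grid-constant",
                    cval=0.0,
                )
                frames *= noise.photon_gain
                if vignetting is not None:
                    frames *= vignetting[None, :, :]
                elif noise.vignetting_min < 1:
                    frames *= vignetting_field((t_ny, n_u), noise.vignetting_min)[None]
                frames += noise.background_offset
                if noise.read_noise_sd > 0:
                    rng = np.random.default_rng(
                        np.random.SeedSequence([noise.rng_seed, i, j, ci])
                    )
                    frames = frames + rng.normal(0, noise.read_noise_sd, frames.shape)
                out.append(
                    TileStack(
                        frames=np.clip(frames, 0.0, None),
                        channel=ch,
                        tile_index=(i, j),
                        scan=scan,
                        pixel_size_um=(dy, dx),
                        origin_um=(
                            ref.origin_um[0],
                            ref.origin_um[1] + y0_px * dy,
                            ref.origin_um[2] + (x0_px - pad) * dx,
                        ),
                        timepoint_h=ref.timepoint_h,
                    )
                )
    return out


def _tile_layout(n: int, n_tiles: int, overlap: float) -> tuple[int, list[int]]:
    """Tile size (px) and start offsets covering [0, n) with the given
    overlap fraction between neighbours."""
    if n_tiles == 1:
        return n, [0]
    size = int(math.ceil(n / (n_tiles - (n_tiles - 1) * overlap)))
    stride = size - int(round(size * overlap))
    starts = [min(t * stride, n - size) for t in range(n_tiles)]
    if starts[-1] + size < n:
        raise CoverageError(f"tile grid leaves [{starts[-1] + size}, {n}) uncovered")
    return size, starts


# --------------------------------------------------------------------------
# assembled phantom

@dataclass
class MesocosmPhantom:
    """A complete synthetic mesocosm on a common truth grid.

    Holds the static scene (grains, pore-size map) and produces per-time
    channel volumes: ``scatter`` (root), ``particle`` (grain fluorescence)
    and ``gfp`` (bacterial density mapped to counts through the linear
    intensity↔OD↔CFU calibration).
    """

    chamber: ChamberGeometry
    packing: ParticlePacking
    field_spec: BacteriaFieldSpec
    voxel_size_um: float = 25.0
    root_base: tuple[float, float, float] = (0.0, 0.0, 0.0)
    root_direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    root_radius_um: float = 250.0
    elongation_rate_um_h: float = 200.0
    initial_root_length_um: float = 2000.0
    scatter_intensity: float = 1000.0
    particle_intensity: float = 800.0
    # intensity = a·OD + b; CFU·mL⁻¹ = c·OD — links gfp counts to density
    calib_a: float = 1000.0
    calib_b: float = 50.0
    calib_c: float = 2.0e8
    # keep hotspot centres at least this far from the root's full
    # trajectory (0 = no constraint); separates pulsatile soil hotspots
    # from the near-root accumulation term when both are programmed
    hotspot_exclusion_um: float = 0.0
    final_timepoint_h: float = 42.0
    seed: int = 0

    def __post_init__(self) -> None:
        self._particle_mask = rasterize_particles(self.packing, self.voxel_size_um)
        self._pore_size: np.ndarray | None = None
        self._hotspots: np.ndarray | None = None

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self._particle_mask.shape

    @property
    def particle_mask(self) -> np.ndarray:
        return self._particle_mask

    def root_at(self, timepoint_h: float) -> RootModel:
        return grow_root(
            self.root_base,
            self.root_direction,
            radius_um=self.root_radius_um,
            elongation_rate_um_h=self.elongation_rate_um_h,
            timepoint_h=timepoint_h,
            initial_length_um=self.initial_root_length_um,
            chamber=self.chamber,
        )

    def root_mask_at(self, timepoint_h: float) -> np.ndarray:
        mask = rasterize_root(self.root_at(timepoint_h), self.grid_shape, self.voxel_size_um)
        return mask & ~np.zeros_like(mask)  # root may overlap grains; root wins

    def pore_size_map(self) -> np.ndarray:
        """True local-thickness map (µm) of the static pore space
        (complement of the grains, ignoring the root)."""
        if self._pore_size is None:
            from .segment import local_thickness

            self._pore_size = local_thickness(
                ~self._particle_mask, self.voxel_size_um,
                resolution_um=self.voxel_size_um / 2,
            )
        return self._pore_size

    def hotspot_centres(self) -> np.ndarray:
        if self._hotspots is None:
            candidates = ~self._particle_mask
            if self.hotspot_exclusion_um > 0:
                final_root = self.root_mask_at(self.final_timepoint_h)
                d = ndi.distance_transform_edt(~final_root, sampling=self.voxel_size_um)
                candidates = candidates & (d > self.hotspot_exclusion_um)
            self._hotspots = place_hotspots(
                self.field_spec, candidates, self.voxel_size_um, self.seed
            )
        return self._hotspots

    def density_at(self, timepoint_h: float, root_mask: np.ndarray | None = None) -> np.ndarray:
        if root_mask is None:
            root_mask = self.root_mask_at(timepoint_h)
        pore_size = self.pore_size_map().copy()
        pore_size[root_mask] = 0.0
        return bacteria_density_field(
            self.field_spec,
            root_mask,
            pore_size,
            self.voxel_size_um,
            timepoint_h,
            seed=self.seed,
            hotspot_centres=self.hotspot_centres(),
        )

    def density_to_intensity(self, density: np.ndarray) -> np.ndarray:
        od = density / self.calib_c
        return self.calib_a * od + self.calib_b

    def truth_volumes(self, timepoint_h: float) -> dict[str, VolumeImage]:
        """Noise-free truth volumes for the three channels at one time."""
        root_mask = self.root_mask_at(timepoint_h)
        density = self.density_at(timepoint_h, root_mask)
        s = self.voxel_size_um

        def vol(data, ch):
            return VolumeImage(
                data=np.asarray(data, dtype=float),
                voxel_size_um=(s, s, s),
                channel=ch,
                timepoint_h=timepoint_h,
            )

        scatter = np.where(root_mask, self.scatter_intensity, 0.0)
        particle = np.where(self._particle_mask & ~root_mask, self.particle_intensity, 0.0)
        gfp = self.density_to_intensity(density)
        gfp[root_mask] = self.calib_b  # no free liquid inside the root
        return {
            "scatter": vol(scatter, "scatter"),
            "particle": vol(particle, "particle"),
            "gfp": vol(gfp, "gfp"),
        }
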