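"""Rhizosphere colonization indicators.

Every analyzed voxel at a time point carries three variables — pore size,
distance from the root surface, and along-root distance from the root tip
— plus the bacterial cell density estimated from GFP intensity through the
intensity↔OD₆₀₀↔CFU calibration. Voxels are classified into groups Rk
(radial shells, along-root bins, pore-size classes, rhizosphere/bulk,
tip/base) and per-group densities D, normalized densities D/⟨D⟩ and
temporal variances computed, together with colonization-kinematics
diagrams over (distance from tip × time).

Operational definitions: rhizosphere = soil closer than 0.2 mm to the
root surface; bulk = farther than 0.2 mm; root base (mature zone) =
farther than 2 mm from the tip; radial profiles restricted to a
3 mm-diameter cylinder around the root centerline; the first five time
points are discarded from temporal variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import morphology

from .segment import RootMask
from .volume import VolumeImage

__all__ = [
    "RHIZOSPHERE_CUTOFF_UM",
    "TIP_BASE_CUTOFF_UM",
    "RADIAL_CYLINDER_DIAMETER_UM",
    "DISCARD_FIRST_TIMEPOINTS",
    "DistanceMaps",
    "CalibrationModel",
    "CalibrationError",
    "PixelGroups",
    "distance_from_root",
    "centerline_and_tip",
    "fit_calibration",
    "intensity_to_density",
    "classify_pixels",
    "compute_indicators",
    "kinematics_diagram",
    "stripe_slope",
    "dominant_period",
    "timeseries_summary",
]

RHIZOSPHERE_CUTOFF_UM = 200.0
TIP_BASE_CUTOFF_UM = 2000.0
RADIAL_CYLINDER_DIAMETER_UM = 3000.0
DISCARD_FIRST_TIMEPOINTS = 5

SCHEMES = ("by_root_distance", "by_tip_distance", "by_pore_size", "rhizosphere_bulk", "tip_base")

DEFAULT_BINS = {
    "by_root_distance": np.arange(0.0, 3000.0 + 1, 100.0),
    "by_tip_distance": np.arange(0.0, 10000.0 + 1, 500.0),
    "by_pore_size": np.arange(0.0, 1000.0 + 1, 100.0),
}


# ------------------------------------------------------------- distances

def distance_from_root(root: RootMask | np.ndarray, voxel_size_um) -> np.ndarray:
    """Euclidean distance (µm) from the root surface, anisotropy-aware.

    Zero on root voxels, strictly positive outside.
    """
    mask = root.mask if isinstance(root, RootMask) else np.asarray(root, dtype=bool)
    if not mask.any():
        raise ValueError("empty root mask")
    sampling = np.broadcast_to(np.asarray(voxel_size_um, dtype=float), (3,))
    return ndi.distance_transform_edt(~mask, sampling=sampling)


@dataclass
class DistanceMaps:
    """Per-voxel geometry relative to the root."""

    from_root_surface_um: np.ndarray
    from_tip_um: np.ndarray
    centerline_um: np.ndarray  # (n, 3) physical coordinates, tip last
    arclength_from_tip_um: np.ndarray  # per centerline node
    from_centerline_um: np.ndarray | None = None


def centerline_and_tip(
    root: RootMask | np.ndarray,
    voxel_size_um,
    base_hint: tuple[int, int, int] | None = None,
) -> DistanceMaps:
    """Skeletonize the root, extract its longest geodesic path as the
    centerline, and assign every voxel the arc-length-from-tip of its
    nearest centerline node.

    The tip is the path endpoint geodesically farthest from the base end
    (the end nearest ``base_hint``, defaulting to the first seed-like
    voxel of the mask).
    """
    mask = root.mask if isinstance(root, RootMask) else np.asarray(root, dtype=bool)
    if not mask.any():
        raise ValueError("empty root mask")
    sampling = np.broadcast_to(np.asarray(voxel_size_um, dtype=float), (3,))

    # 3-D thinning can delete a perfectly even-symmetric tube outright
    # (common in synthetic rasters, never in real data); when that
    # happens, retry on a mask thickened by one voxel along z and x,
    # which breaks the symmetry at the cost of a half-voxel bias
    skel = morphology.skeletonize(mask)
    span = np.ptp(np.argwhere(mask), axis=0).max() if mask.any() else 0
    if skel.sum() < max(2, span // 2):
        thick = mask.copy()
        thick[1:] |= mask[:-1]
        thick[:, :, 1:] |= thick[:, :, :-1]
        retry = morphology.skeletonize(thick)
        if retry.sum() > skel.sum():
            skel = retry
    pts = np.argwhere(skel)
    if len(pts) < 2:
        raise ValueError(
            "degenerate skeleton (blob without elongation); review the "
            "segmentation threshold"
        )
    g = _skeleton_graph(pts, sampling)
    # longest geodesic by double sweep
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp)
    start = next(iter(comp))
    far_a = _farthest(g, start)
    far_b = _farthest(g, far_a)
    path = nx.shortest_path(g, far_a, far_b, weight="weight")

    path_vox = np.asarray(path, dtype=float)
    phys = (path_vox + 0.5) * sampling

    if base_hint is None:
        base_hint = tuple(pts[0])
    hint_phys = (np.asarray(base_hint, dtype=float) + 0.5) * sampling
    # orient base → tip: tip is the endpoint farther from the base hint
    if np.linalg.norm(phys[0] - hint_phys) > np.linalg.norm(phys[-1] - hint_phys):
        phys = phys[::-1]

    # tame the 26-connected staircase before measuring arc length
    phys = _smooth_path(phys)
    # skeletonization retracts tube ends by roughly one radius; walk each
    # endpoint out along its local tangent until the mask boundary
    phys = _extend_ends(phys, mask, sampling)

    seg = np.linalg.norm(np.diff(phys, axis=0), axis=1)
    arclen_from_base = np.concatenate([[0.0], np.cumsum(seg)])
    arclen_from_tip = arclen_from_base[-1] - arclen_from_base

    tree = cKDTree(phys)
    shape = mask.shape
    coords = np.indices(shape).reshape(3, -1).T
    coords_phys = (coords + 0.5) * sampling
    dist_cl, nearest = tree.query(coords_phys)
    from_tip = arclen_from_tip[nearest].reshape(shape)
    from_centerline = dist_cl.reshape(shape)

    from_root = ndi.distance_transform_edt(~mask, sampling=sampling)
    return DistanceMaps(
        from_root_surface_um=from_root,
        from_tip_um=from_tip,
        centerline_um=phys,
        arclength_from_tip_um=arclen_from_tip,
        from_centerline_um=from_centerline,
    )


def _skeleton_graph(pts: np.ndarray, sampling: np.ndarray) -> nx.Graph:
    """26-connectivity graph over skeleton voxels, edge weights in µm."""
    nodes = {tuple(p) for p in pts}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    # half of the 26-neighbourhood; each unordered pair visited once
    half = [
        (dz, dy, dx)
        for dz in (0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)
    ]
    for p in nodes:
        for off in half:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if q in nodes:
                w = float(np.linalg.norm(np.asarray(off) * sampling))
                g.add_edge(p, q, weight=w)
    return g


def _smooth_path(phys: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing of the polyline, endpoints pinned."""
    if len(phys) < window + 2:
        return phys
    kernel = np.ones(window) / window
    out = phys.copy()
    for k in range(3):
        out[:, k] = np.convolve(np.pad(phys[:, k], window // 2, mode="edge"), kernel, "valid")
    out[0] = phys[0]
    out[-1] = phys[-1]
    return out


def _extend_ends(phys: np.ndarray, mask: np.ndarray, sampling: np.ndarray) -> np.ndarray:
    def walk(end: np.ndarray, inner: np.ndarray):
        d = end - inner
        n = np.linalg.norm(d)
        if n == 0:
            return None
        d = d / n
        step = float(min(sampling)) / 2.0
        p = end.copy()
        last_inside = None
        for _ in range(1000):
            p = p + d * step
            idx = np.floor(p / sampling).astype(int)
            if np.any(idx < 0) or np.any(idx >= mask.shape) or not mask[tuple(idx)]:
                break
            last_inside = p.copy()
        return last_inside

    k = min(4, len(phys) - 1)
    head = walk(phys[0], phys[k])
    tail = walk(phys[-1], phys[-1 - k])
    parts = []
    if head is not None:
        parts.append(head[None, :])
    parts.append(phys)
    if tail is not None:
        parts.append(tail[None, :])
    return np.concatenate(parts, axis=0)


def _farthest(g: nx.Graph, source):
    dist = nx.single_source_dijkstra_path_length(g, source, weight="weight")
    return max(dist, key=dist.get)


# ------------------------------------------------------------ calibration

class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationModel:
    """Linear links pixel intensity → OD₆₀₀ → CFU·mL⁻¹.

    ``intensity = a·OD + b`` (least squares) and ``CFU = c·OD`` (least
    squares through the origin); density(intensity = b) = 0.
    """

    intensity_per_od: float  # a
    intensity_offset: float  # b
    cfu_per_od: float  # c
    r2_intensity_od: float = float("nan")
    r2_od_cfu: float = float("nan")

    def __post_init__(self) -> None:
        if self.intensity_per_od <= 0 or self.cfu_per_od <= 0:
            raise CalibrationError("calibration slopes must be positive")

    def density(self, intensity: np.ndarray) -> np.ndarray:
        od = (np.asarray(intensity, dtype=float) - self.intensity_offset) / self.intensity_per_od
        return np.clip(self.cfu_per_od * od, 0.0, None)


def fit_calibration(
    standards: list[tuple[float, float]],
    cfu_points: list[tuple[float, float]],
) -> CalibrationModel:
    """Fit the two calibration regressions from dilution-series standards.

    ``standards`` are (intensity, OD₆₀₀) pairs — the reference design
    uses 12 ODs spanning 1.2×10⁻³ to 3.0 by serial dilution — and
    ``cfu_points`` are (OD₆₀₀, CFU·mL⁻¹) plate counts.
    """
    standards = np.asarray(standards, dtype=float)
    cfu_points = np.asarray(cfu_points, dtype=float)
    if len(standards) < 3 or len(cfu_points) < 3:
        raise CalibrationError("need ≥ 3 points per regression")
    od = standards[:, 1]
    if od.max() <= 0 or od.max() / max(od.min(), 1e-300) < 10:
        raise CalibrationError("OD standards should span at least one decade")

    intensity = standards[:, 0]
    a, b = np.polyfit(od, intensity, 1)
    if a <= 0:
        raise CalibrationError(f"non-positive intensity/OD slope ({a:.3g})")
    resid = intensity - (a * od + b)
    ss_tot = np.sum((intensity - intensity.mean()) ** 2)
    r2_int = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else float("nan")

    od2, cfu = cfu_points[:, 0], cfu_points[:, 1]
    c = float(np.sum(od2 * cfu) / np.sum(od2**2))
    if c <= 0:
        raise CalibrationError(f"non-positive CFU/OD slope ({c:.3g})")
    resid2 = cfu - c * od2
    ss_tot2 = np.sum((cfu - cfu.mean()) ** 2)
    r2_cfu = 1.0 - np.sum(resid2**2) / ss_tot2 if ss_tot2 > 0 else float("nan")

    return CalibrationModel(float(a), float(b), c, float(r2_int), float(r2_cfu))


def intensity_to_density(gfp: VolumeImage, calib: CalibrationModel) -> np.ndarray:
    """Bacterial cell density (CFU·mL⁻¹) per voxel from GFP intensity:
    ``density = c·(I − b)/a``, clipped at zero."""
    return calib.density(gfp.data)


# ----------------------------------------------------------- pixel groups

@dataclass
class PixelGroups:
    """Partition of the analyzed soil volume into groups Rk.

    ``group_id`` is −1 outside the analyzed region; bin intervals are
    half-open [lo, hi) with boundary values falling upward.
    """

    group_id: np.ndarray
    scheme: str
    bin_edges: np.ndarray | None
    labels: list[str]

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def analyzed(self) -> np.ndarray:
        return self.group_id >= 0


def classify_pixels(
    maps: DistanceMaps,
    pores: np.ndarray | None,
    scheme: str,
    bin_edges=None,
    analyzed_mask: np.ndarray | None = None,
) -> PixelGroups:
    """Assign each analyzed voxel to exactly one group of the scheme.

    ``analyzed_mask`` restricts the domain (typically: soil voxels, i.e.
    not root); pore-size schemes additionally require pore voxels; radial
    (by_root_distance) analysis is restricted to a 3 mm-diameter cylinder
    around the root centerline.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    d_root = maps.from_root_surface_um
    shape = d_root.shape
    region = np.ones(shape, dtype=bool) if analyzed_mask is None else analyzed_mask.astype(bool)
    region = region & (d_root > 0)  # soil only, never the root body

    if scheme == "rhizosphere_bulk":
        gid = np.where(d_root < RHIZOSPHERE_CUTOFF_UM, 0, 1)
        labels = ["rhizosphere", "bulk"]
        edges = np.array([0.0, RHIZOSPHERE_CUTOFF_UM, np.inf])
    elif scheme == "tip_base":
        gid = np.where(maps.from_tip_um > TIP_BASE_CUTOFF_UM, 1, 0)
        labels = ["tip", "base"]
        edges = np.array([0.0, TIP_BASE_CUTOFF_UM, np.inf])
    else:
        if scheme == "by_root_distance":
            values = d_root
            if maps.from_centerline_um is not None:
                region = region & (maps.from_centerline_um < RADIAL_CYLINDER_DIAMETER_UM / 2)
        elif scheme == "by_tip_distance":
            values = maps.from_tip_um
        else:  # by_pore_size
            if pores is None:
                raise ValueError("pore-size scheme requires a pore-size map")
            values = pores
            region = region & (pores > 0)
        edges = np.asarray(DEFAULT_BINS[scheme] if bin_edges is None else bin_edges, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        # half-open [lo, hi); values beyond the last edge land in the last bin
        gid = np.clip(np.digitize(values, edges[1:], right=False), 0, len(edges) - 2)
        labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
        region = region & (values >= edges[0])

    gid = np.where(region, gid, -1).astype(np.int32)
    return PixelGroups(gid, scheme, edges, labels)


# ------------------------------------------------------------- indicators

def compute_indicators(
    density_fields: list[np.ndarray],
    groups: list[PixelGroups],
    timepoints_h,
    voxel_size_um,
    root_volumes_mm3: list[float] | None = None,
    per_root_volume: bool = True,
    discard_first: int = DISCARD_FIRST_TIMEPOINTS,
    normalize_over: str = "groups",
) -> pd.DataFrame:
    """Per-(time, group) colonization indicators.

    For each group Rk at time t the bacterial cell density D is the mean
    estimated density over the group's soil voxels (CFU per unit soil
    volume), optionally expressed per unit volume of root (divided by the
    segmented root volume at t). D/⟨D⟩ normalizes by the mean over the
    scheme's groups at fixed t, making patterns comparable independently
    of the colonization magnitude. The temporal variance of D/⟨D⟩ per
    group — the bacterial mobility indicator — discards the first
    ``discard_first`` time points.
    """
    times = np.asarray(timepoints_h, dtype=float)
    if len(density_fields) != len(times) or len(groups) != len(times):
        raise ValueError("density fields, groups and timepoints must align")
    if per_root_volume and root_volumes_mm3 is None:
        raise ValueError("per_root_volume=True requires root volumes")
    if normalize_over not in ("groups", "time"):
        raise ValueError("normalize_over must be 'groups' or 'time'")

    voxel_mm3 = float(np.prod(np.broadcast_to(np.asarray(voxel_size_um, float), (3,)))) * 1e-9
    rows = []
    for t_idx, (t, dens, grp) in enumerate(zip(times, density_fields, groups)):
        gid = grp.group_id
        d_vals = np.full(grp.n_groups, np.nan)
        counts = np.zeros(grp.n_groups, dtype=int)
        for k in range(grp.n_groups):
            sel = gid == k
            counts[k] = int(sel.sum())
            if counts[k]:
                d_vals[k] = float(np.nanmean(dens[sel]))
        if per_root_volume:
            rv = root_volumes_mm3[t_idx]
            d_vals = d_vals / rv if rv > 0 else np.full_like(d_vals, np.nan)
        for k in range(grp.n_groups):
            rows.append(
                {
                    "timepoint_h": t,
                    "scheme": grp.scheme,
                    "group_id": k,
                    "group_label": grp.labels[k],
                    "D": d_vals[k],
                    "voxel_count": counts[k],
                    "soil_volume_mm3": counts[k] * voxel_mm3,
                    "empty": counts[k] == 0,
                }
            )
    table = pd.DataFrame(rows)

    # D/⟨D⟩
    if normalize_over == "groups":
        mean_d = table.groupby("timepoint_h")["D"].transform("mean")
    else:
        mean_d = table.groupby("group_id")["D"].transform("mean")
    table["D_norm"] = table["D"] / mean_d

    # temporal variance of D_norm per group, first time points discarded
    keep_times = times[discard_first:]
    late = table[table["timepoint_h"].isin(keep_times)]
    if len(keep_times) >= 2:
        var = late.groupby("group_id")["D_norm"].var(ddof=0)
        table["variance"] = table["group_id"].map(var)
    else:
        table["variance"] = np.nan
    return table


# ------------------------------------------------------------- kinematics

def kinematics_diagram(
    density_fields: list[np.ndarray],
    from_tip_maps: list[np.ndarray],
    timepoints_h,
    bin_um: float = 500.0,
    max_distance_um: float | None = None,
    analyzed_masks: list[np.ndarray] | None = None,
):
    """Colonization-kinematics diagram: mean density per
    (distance-from-tip bin × time), with along-root mean and temporal
    variance profiles.

    Features fixed in the lab frame appear as diagonal stripes because the
    tip-relative distance of a fixed point grows at the elongation rate.

    Returns ``(matrix, bin_centers_um, mean_profile, variance_profile)``;
    the variance profile discards the first five time points.
    """
    times = np.asarray(timepoints_h, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if max_distance_um is None:
        max_distance_um = max(float(np.nanmax(m)) for m in from_tip_maps)
    edges = np.arange(0.0, max_distance_um + bin_um, bin_um)
    nb = len(edges) - 1
    matrix = np.full((nb, len(times)), np.nan)
    for t_idx, (dens, ftip) in enumerate(zip(density_fields, from_tip_maps)):
        sel_all = np.isfinite(dens)
        if analyzed_masks is not None:
            sel_all = sel_all & analyzed_masks[t_idx]
        bins = np.digitize(ftip, edges[1:], right=False)
        for b in range(nb):
            sel = sel_all & (bins == b)
            if sel.any():
                matrix[b, t_idx] = float(np.mean(dens[sel]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins are legal
        mean_profile = np.nanmean(matrix, axis=1)
        late = matrix[:, DISCARD_FIRST_TIMEPOINTS:]
        variance_profile = (
            np.nanvar(late, axis=1) if late.shape[1] >= 2 else np.full(nb, np.nan)
        )
    return matrix, centers, mean_profile, variance_profile


def stripe_slope(matrix: np.ndarray, bin_centers_um: np.ndarray, timepoints_h) -> float:
    """Apparent velocity (µm·h⁻¹) of the density ridge in the space–time
    diagram: linear fit of the per-time argmax bin position."""
    times = np.asarray(timepoints_h, dtype=float)
    pos, ts = [], []
    for t_idx in range(matrix.shape[1]):
        col = matrix[:, t_idx]
        if np.all(np.isnan(col)):
            continue
        pos.append(bin_centers_um[int(np.nanargmax(col))])
        ts.append(times[t_idx])
    if len(ts) < 2:
        raise ValueError("need at least two usable time points for a slope")
    return float(np.polyfit(ts, pos, 1)[0])


def dominant_period(
    series: np.ndarray, dt_h: float, min_lag: int = 2, detrend_window: int = 0
) -> float:
    """Dominant pulsation period (h) of a density time series via the
    first peak of its autocorrelation at lag ≥ ``min_lag``.

    ``detrend_window`` > 0 removes a centred moving average first, so
    pulsation rides on top of a slow colonization envelope.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if detrend_window > 1 and len(x) > detrend_window:
        kernel = np.ones(detrend_window) / detrend_window
        trend = np.convolve(np.pad(x, detrend_window // 2, mode="edge"), kernel, "valid")
        x = x - trend[: len(x)]
    x = x - x.mean()
    if len(x) < min_lag + 2 or np.allclose(x, 0):
        return float("nan")
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    ac = ac / ac[0]
    lags = np.arange(len(ac))
    best, best_val = None, -np.inf
    for lag in range(min_lag, len(ac) - 1):
        if ac[lag] >= ac[lag - 1] and ac[lag] >= ac[lag + 1] and ac[lag] > best_val:
            best, best_val = lag, ac[lag]
    if best is None:
        best = int(lags[min_lag:][np.argmax(ac[min_lag:])])
    return float(best * dt_h)


# ---------------------------------------------------------------- summary

def timeseries_summary(
    density_fields: list[np.ndarray],
    groups_rb: list[PixelGroups],
    timepoints_h,
    plateau_tolerance: float = 0.0,
) -> pd.DataFrame:
    """Rhizosphere (< 0.2 mm), bulk (> 0.2 mm) and whole-soil mean density
    versus time, with peak-time detection.

    The peak time is the earliest time point whose value is within
    ``plateau_tolerance`` (fractional) of the series maximum.
    """
    times = np.asarray(timepoints_h, dtype=float)
    rows = []
    for t, dens, grp in zip(times, density_fields, groups_rb):
        if grp.scheme != "rhizosphere_bulk":
            raise ValueError("timeseries_summary expects rhizosphere_bulk groups")
        gid = grp.group_id
        rh = gid == 0
        bk = gid == 1
        soil = gid >= 0
        rows.append(
            {
                "timepoint_h": t,
                "rhizosphere": float(np.nanmean(dens[rh])) if rh.any() else np.nan,
                "bulk": float(np.nanmean(dens[bk])) if bk.any() else np.nan,
                "total": float(np.nanmean(dens[soil])) if soil.any() else np.nan,
                "rhizosphere_voxels": int(rh.sum()),
                "bulk_voxels": int(bk.sum()),
            }
        )
    df = pd.DataFrame(rows)
    for col in ("rhizosphere", "bulk", "total"):
        df.attrs[f"peak_time_{col}"] = peak_time(df["timepoint_h"].values, df[col].values, plateau_tolerance)
    return df


def peak_time(times: np.ndarray, values: np.ndarray, plateau_tolerance: float = 0.0) -> float:
    """Earliest time whose value reaches within ``plateau_tolerance``
    (fraction of the maximum) of the series maximum."""
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        return float("nan")
    vmax = np.nanmax(values)
    thresh = vmax * (1.0 - plateau_tolerance) if vmax > 0 else vmax
    idx = np.argmax(finite & (values >= thresh))
    return float(np.asarray(times)[idx])
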