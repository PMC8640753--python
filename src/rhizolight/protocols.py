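"""Standard benchmark protocols: fixed phantom study conditions and the
measurements that recover their programmed parameters.

These protocols define desk-scale mesocosms whose ground truth encodes
the observed colonization timeline — a bulk-soil density peak at 26 h and
a rhizosphere peak in the 30–34 h window after inoculation, hotspot
pulses ~4 h apart, a 3× preference for pores below 400 µm — and then
measure those same quantities back through the full segmentation and
quantification pipeline. Chamber sizes are reduced from the instrument's
22 × 65 × 3 mm so a 23-time-point series runs at desk scale; hotspot size
and the near-root accumulation scale are chosen so that the hotspots'
volume fraction stays realistically small and volume-averaged curves
reflect the programmed envelopes, as they do in the full-size system.
"""

from __future__ import annotations

import numpy as np

from .flatfield import apply_flatfield, estimate_flatfield
from .geometry import ChamberGeometry, NoiseModel, OpticsModel, ScanGeometry
from .phantom import BacteriaFieldSpec, MesocosmPhantom, make_particle_packing, render_scan
from .quantify import (
    CalibrationModel,
    PixelGroups,
    centerline_and_tip,
    classify_pixels,
    compute_indicators,
    distance_from_root,
    dominant_period,
    intensity_to_density,
    kinematics_diagram,
    stripe_slope,
    timeseries_summary,
)
from .reconstruct import lr_deconvolve, make_lightsheet_psf, shear_correct
from .segment import local_thickness, segment_pores, segment_root
from .stitching import apply_offsets, register_offsets, stitch_tiles

__all__ = [
    "reconstruction_fidelity",
    "recovery_phantom",
    "run_recovery_series",
    "kinematics_stripe",
]


# ------------------------------------------------- reconstruction fidelity

def reconstruction_fidelity(seed: int = 11, lr_iterations: int = 10) -> dict:
    """Render a noise-free 2×2-tile mesocosm at 45°, run the full
    reconstruction chain (flat field → deskew → register → stitch →
    Richardson–Lucy), and score it against the known truth.

    Returns voxelwise Pearson r per channel and the per-grain centroid
    error (voxels), measured as the intensity centroid within each grain's
    analytic bounding sphere.
    """
    chamber = ChamberGeometry(3.0, 3.0, 1.5)
    packing = make_particle_packing(chamber, (300.0, 700.0), 0.6, seed=seed)
    phantom = MesocosmPhantom(
        chamber=chamber,
        packing=packing,
        field_spec=BacteriaFieldSpec(source_point=(750.0, 500.0, 1500.0), n_hotspots=2),
        voxel_size_um=25.0,
        root_base=(750.0, 0.0, 1500.0),
        root_radius_um=200.0,
        seed=seed,
    )
    truth = phantom.truth_volumes(25.0)
    voxel = 25.0
    scan = ScanGeometry(
        scan_angle_deg=45.0,
        slice_step_um=voxel * np.sqrt(2),
        slices_per_tile=80,
        tile_grid=(2, 2),
        tile_overlap_fraction=0.2,
        footprint_mm=(3.0, 3.0),
        chamber=chamber,
    )
    optics = OpticsModel(sheet_fwhm_um=50.0, lateral_fwhm_um=30.0)
    tiles = render_scan(truth, scan, optics, NoiseModel())

    by_channel: dict[str, list] = {}
    for t in tiles:
        by_channel.setdefault(t.channel, []).append(t)
    ff = estimate_flatfield(np.concatenate([t.frames for t in by_channel["particle"]], axis=0))
    deskewed = {}
    for ch, ch_tiles in sorted(by_channel.items()):
        vols = []
        for tile in ch_tiles:
            tile.frames = apply_flatfield(tile.frames, ff)
            vols.append(shear_correct(tile))
        deskewed[ch] = vols
    corrections = register_offsets(deskewed["particle"])
    psf = make_lightsheet_psf(optics, (voxel,) * 3)
    recon = {}
    for ch, vols in deskewed.items():
        st = stitch_tiles(apply_offsets(vols, corrections), scan, register=False)
        filled = st.with_data(np.clip(np.nan_to_num(st.data), 0.0, None))
        out = lr_deconvolve(filled, psf, lr_iterations)
        out.origin_um = st.origin_um
        recon[ch] = out

    result: dict = {"pearson_r": {}}
    for ch in truth:
        sub = _crop_to_truth(recon[ch], truth[ch].shape, voxel)
        result["pearson_r"][ch] = float(
            np.corrcoef(np.nan_to_num(sub).ravel(), truth[ch].data.ravel())[0, 1]
        )

    # per-grain centroid error in the reconstructed particle channel
    sub = _crop_to_truth(recon["particle"], truth["particle"].shape, voxel)
    root = phantom.root_mask_at(25.0)
    errs = []
    for z, y, x, r in packing.particles:
        c_vox = np.array([z, y, x]) / voxel - 0.5
        r_vox = r / voxel
        lo = np.maximum(0, np.floor(c_vox - r_vox).astype(int))
        hi = np.minimum(truth["particle"].shape, np.ceil(c_vox + r_vox).astype(int) + 1)
        window = tuple(slice(a, b) for a, b in zip(lo, hi))
        if root[window].any():
            continue  # grains clipped by the root carry no fluorescence there
        zz, yy, xx = np.indices([b - a for a, b in zip(lo, hi)])
        ball = (
            (zz + lo[0] - c_vox[0]) ** 2
            + (yy + lo[1] - c_vox[1]) ** 2
            + (xx + lo[2] - c_vox[2]) ** 2
        ) <= r_vox**2
        vals = np.nan_to_num(sub[window]) * ball
        total = vals.sum()
        if total <= 0:
            continue
        idx = np.indices(vals.shape).reshape(3, -1)
        com = (idx * vals.ravel()).sum(axis=1) / total + lo
        errs.append(float(np.linalg.norm(com - c_vox)))
    result["centroid_errors_voxels"] = errs
    result["n_grains"] = len(errs)
    return result


def _crop_to_truth(volume, truth_shape, voxel):
    oz, oy, ox = [int(round(o / voxel)) for o in volume.origin_um]
    return volume.data[-oz:-oz + truth_shape[0], -oy:-oy + truth_shape[1], -ox:-ox + truth_shape[2]]


# --------------------------------------------------- indicator recovery

def recovery_phantom(seed: int = 21) -> MesocosmPhantom:
    """The standard 23-time-point recovery mesocosm (50 µm grid).

    Programmed conditions: bulk-density envelope peaking 26 h post
    inoculation, near-root envelope peaking at 32 h, hotspot pulses with
    period 4 h / duration 2 h, 3× occupancy bias in pores < 400 µm, root
    elongating at 120 µm·h⁻¹ from a 2 mm seedling.
    """
    chamber = ChamberGeometry(5.0, 8.0, 2.0)
    packing = make_particle_packing(chamber, (250.0, 1250.0), 0.6, seed=seed)
    spec = BacteriaFieldSpec(
        source_point=(1000.0, 1000.0, 2500.0),
        background_density=2e7,
        bulk_peak_h=26.0,
        bulk_envelope_sigma_h=2.5,
        root_density=2e8,
        root_peak_h=32.0,
        root_envelope_sigma_h=5.0,
        hotspot_density=4e8,
        hotspot_sigma_um=150.0,
        n_hotspots=4,
        hotspot_period_h=4.0,
        hotspot_duration_h=2.0,
        pore_bias_strength=3.0,
        pore_bias_threshold_um=400.0,
        root_accumulation_scale_um=300.0,
        hotspot_min_separation_um=1500.0,
    )
    return MesocosmPhantom(
        chamber=chamber,
        packing=packing,
        field_spec=spec,
        voxel_size_um=50.0,
        root_base=(1000.0, 0.0, 2500.0),
        root_radius_um=250.0,
        elongation_rate_um_h=120.0,
        hotspot_exclusion_um=1200.0,
        seed=seed,
    )


def run_recovery_series(phantom: MesocosmPhantom, timepoints=None) -> dict:
    """Run segmentation + quantification over the hourly series and
    recover the programmed parameters.

    Returns the recovered pore-bias ratio (median over time of the
    far-bulk density ratio below/above the 400 µm threshold), the pulse
    period from the maximum-temporal-variance voxel (hotspots are
    immobile, so the lab-frame voxel trace carries the schedule), the
    recovered rhizosphere/bulk peak times, and the same peak times
    measured on the ground-truth fields ("programmed").
    """
    if timepoints is None:
        timepoints = np.arange(20.0, 43.0)
    voxel = phantom.voxel_size_um
    calib = CalibrationModel(phantom.calib_a, phantom.calib_b, phantom.calib_c)

    densities, groups_rb, groups_ps = [], [], []
    truth_densities, truth_groups_rb = [], []
    for t in timepoints:
        truth = phantom.truth_volumes(t)
        root = segment_root(truth["scatter"], threshold=500.0)
        pores = segment_pores(truth["particle"], truth["gfp"], root, threshold=0.5)
        pore_size = local_thickness(pores, voxel, resolution_um=voxel / 2)
        dens = intensity_to_density(truth["gfp"], calib)
        dens[root.mask] = np.nan
        maps = centerline_and_tip(root.mask, voxel, base_hint=_base_voxel(phantom, voxel))
        soil = ~root.mask
        groups_rb.append(classify_pixels(maps, pore_size, "rhizosphere_bulk", analyzed_mask=soil))
        far_bulk = maps.from_root_surface_um > 1500.0
        groups_ps.append(
            classify_pixels(
                maps, pore_size, "by_pore_size",
                bin_edges=[0.0, 400.0, 1e9], analyzed_mask=soil & far_bulk,
            )
        )
        densities.append(dens)

        true_root = phantom.root_mask_at(t)
        true_d = phantom.density_at(t, true_root)
        gid = np.where(distance_from_root(true_root, voxel) < 200.0, 0, 1)
        gid[true_root] = -1
        truth_groups_rb.append(
            PixelGroups(gid.astype(np.int32), "rhizosphere_bulk", None, ["rhizosphere", "bulk"])
        )
        truth_densities.append(true_d)

    table = compute_indicators(densities, groups_ps, timepoints, voxel, per_root_volume=False)
    pivot = table.pivot_table(index="timepoint_h", columns="group_id", values="D")
    ratios = (pivot[0] / pivot[1]).values

    summary = timeseries_summary(densities, groups_rb, timepoints)
    truth_summary = timeseries_summary(truth_densities, truth_groups_rb, timepoints)

    stack = np.stack([np.nan_to_num(d) for d in densities])
    hot_voxel = np.unravel_index(np.argmax(stack.var(axis=0)), stack.shape[1:])
    pulse_series = stack[(slice(None),) + hot_voxel]
    dt = float(np.diff(timepoints).mean())
    period = dominant_period(pulse_series, dt, detrend_window=5)

    return {
        "pore_bias_ratio": float(np.median(ratios)),
        "pulse_period_h": period,
        "bulk_peak_h": summary.attrs["peak_time_bulk"],
        "rhizosphere_peak_h": summary.attrs["peak_time_rhizosphere"],
        "programmed_bulk_peak_h": truth_summary.attrs["peak_time_bulk"],
        "programmed_rhizosphere_peak_h": truth_summary.attrs["peak_time_rhizosphere"],
        "summary": summary,
        "indicator_table": table,
    }


def _base_voxel(phantom: MesocosmPhantom, voxel: float):
    base = np.asarray(phantom.root_base) / voxel
    return tuple(int(np.clip(b, 0, s - 1)) for b, s in zip(base, phantom.grid_shape))


# ------------------------------------------------------ kinematics stripe

def kinematics_stripe(seed: int = 31, elongation_rate_um_h: float = 200.0) -> dict:
    """A lab-frame-fixed, always-on hotspot beside a root elongating at
    the given rate: its distance from the tip grows at the elongation
    rate, so the space–time diagram shows a diagonal stripe of that slope.
    """
    chamber = ChamberGeometry(3.0, 8.0, 1.5)
    packing = make_particle_packing(chamber, (300.0, 700.0), 0.7, seed=seed)
    spec = BacteriaFieldSpec(
        source_point=(750.0, 1500.0, 800.0),
        background_density=0.0,
        root_density=0.0,
        hotspot_density=1e8,
        hotspot_sigma_um=200.0,
        n_hotspots=1,
        hotspot_period_h=1000.0,
        hotspot_duration_h=999.0,  # effectively always on
        pore_bias_strength=1.0,
    )
    phantom = MesocosmPhantom(
        chamber=chamber,
        packing=packing,
        field_spec=spec,
        voxel_size_um=50.0,
        root_base=(750.0, 0.0, 1500.0),
        root_radius_um=200.0,
        elongation_rate_um_h=elongation_rate_um_h,
        seed=seed,
    )
    calib = CalibrationModel(phantom.calib_a, phantom.calib_b, phantom.calib_c)
    times = np.arange(0.0, 11.0)
    densities, ftips, soils = [], [], []
    for t in times:
        truth = phantom.truth_volumes(t)
        root = segment_root(truth["scatter"], threshold=500.0)
        dens = intensity_to_density(truth["gfp"], calib)
        dens[root.mask] = np.nan
        maps = centerline_and_tip(root.mask, 50.0, base_hint=_base_voxel(phantom, 50.0))
        densities.append(dens)
        ftips.append(maps.from_tip_um)
        soils.append(~root.mask)
    matrix, centers, _, _ = kinematics_diagram(
        densities, ftips, times, bin_um=250.0, analyzed_masks=soils
    )
    slope = stripe_slope(matrix, centers, times)
    return {"stripe_slope_um_h": slope, "programmed_rate_um_h": elongation_rate_um_h}
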