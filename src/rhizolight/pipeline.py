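"""End-to-end orchestration: simulate → reconstruct → segment → quantify.

Each stage reads its inputs from the output directory, writes its outputs
there, and records file hashes in a run manifest; re-running with an
identical configuration and seed reproduces identical hashes for the
deterministic stages, and stages whose outputs already exist are skipped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .config import PipelineConfig
from .flatfield import apply_flatfield, estimate_flatfield
from .io import read_tiles, read_volume, write_tiles, write_volume
from .phantom import MesocosmPhantom, make_particle_packing, render_scan
from .quantify import (
    CalibrationModel,
    centerline_and_tip,
    classify_pixels,
    compute_indicators,
    intensity_to_density,
    kinematics_diagram,
    timeseries_summary,
)
from .reconstruct import lr_deconvolve, make_lightsheet_psf, shear_correct
from .segment import local_thickness, segment_pores, segment_root
from .stitching import apply_offsets, register_offsets, stitch_tiles
from .volume import CHANNELS, VolumeImage

logger = logging.getLogger("rhizolight")

__all__ = ["RunManifest", "StageError", "run_pipeline", "build_phantom"]


class StageError(RuntimeError):
    def __init__(self, stage: str, path, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {path}: {cause}")
        self.stage = stage
        self.path = path


@dataclass
class RunManifest:
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    stages: dict = field(default_factory=dict)  # stage → {file: sha256}

    def record(self, stage: str, files) -> None:
        self.stages.setdefault(stage, {})
        for f in files:
            f = Path(f)
            self.stages[stage][f.name] = _sha256(f)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


def _sha256(path: Path) -> str:
    """Content hash: TIFF voxel payloads are hashed as arrays so that
    embedded write timestamps/UUIDs do not break reproducibility."""
    h = hashlib.sha256()
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        h.update(np.ascontiguousarray(tifffile.imread(path)).tobytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def build_phantom(config: PipelineConfig) -> MesocosmPhantom:
    """Assemble the ground-truth mesocosm the simulate stage renders."""
    ph = config.phantom
    packing = make_particle_packing(
        config.chamber,
        size_range_um=ph.particle_size_range_um,
        target_porosity=ph.target_porosity,
        seed=config.rng_seed,
    )
    return MesocosmPhantom(
        chamber=config.chamber,
        packing=packing,
        field_spec=config.bacteria,
        voxel_size_um=ph.voxel_size_um,
        root_base=ph.root_base,
        root_direction=ph.root_direction,
        root_radius_um=ph.root_radius_um,
        elongation_rate_um_h=ph.elongation_rate_um_h,
        initial_root_length_um=ph.initial_root_length_um,
        calib_a=ph.calib_a,
        calib_b=ph.calib_b,
        calib_c=ph.calib_c,
        seed=config.rng_seed,
    )


def run_pipeline(config: PipelineConfig, out_dir=None, stages=None) -> RunManifest:
    """Run the configured stages end to end.

    ``stages`` defaults to the full chain (simulate skipped when
    ``config.simulate`` is false, in which case tiles must already sit in
    ``<out>/tiles``). A stage whose outputs already exist is skipped.
    """
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.rng_seed, started=_now())
    config.to_yaml(out / "resolved_config.yaml")

    all_stages = ["simulate", "reconstruct", "segment", "quantify"]
    if stages is None:
        stages = all_stages if config.simulate else all_stages[1:]

    for stage in stages:
        t0 = time.monotonic()
        try:
            files = _STAGE_FUNCS[stage](config, out)
        except Exception as exc:  # noqa: BLE001 — halt with stage context
            raise StageError(stage, out, exc) from exc
        manifest.record(stage, files)
        logger.info("stage %s: %d files in %.1f s", stage, len(files), time.monotonic() - t0)

    manifest.finished = _now()
    manifest.write(out / "run_manifest.json")
    return manifest


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


# ---------------------------------------------------------------- stages

def _stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    tiles_dir = out / "tiles"
    truth_dir = out / "truth"
    if (tiles_dir / "manifest.yaml").exists():
        logger.info("simulate: outputs exist, skipping")
        return sorted(tiles_dir.glob("*"))
    phantom = build_phantom(config)
    written: list[Path] = []
    all_tiles = []
    for t in config.timepoints_h:
        truth = phantom.truth_volumes(t)
        for ch, vol in truth.items():
            written.append(write_volume(vol, truth_dir / f"truth_{ch}_t{t:05.1f}.tif"))
        all_tiles.extend(render_scan(truth, config.scan, config.optics, config.noise))
    manifest_path = write_tiles(all_tiles, tiles_dir, seed=config.rng_seed)
    written.append(manifest_path)
    return written


def _stage_reconstruct(config: PipelineConfig, out: Path) -> list[Path]:
    tiles_dir = out / "tiles"
    rec_dir = out / "reconstructed"
    manifest_path = tiles_dir / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no tile manifest at {manifest_path}")
    existing = sorted(rec_dir.glob("*.tif"))
    expected = len(config.timepoints_h) * len(CHANNELS)
    if len(existing) == expected:
        logger.info("reconstruct: outputs exist, skipping")
        return existing

    written = []
    psf = None
    psf_grid = None
    for t in config.timepoints_h:
        tiles = read_tiles(manifest_path, timepoint_h=float(t))
        if not tiles:
            continue
        # flat-field per channel from all raw frames of this time point
        by_channel: dict[str, list] = {}
        for tile in tiles:
            by_channel.setdefault(tile.channel, []).append(tile)
        # vignetting is channel-independent; estimate the weight matrix on
        # the soil-texture (particle) channel, where the repeating grains
        # make the per-pixel mode track illumination, and apply everywhere
        ff_channel = "particle" if "particle" in by_channel else sorted(by_channel)[0]
        frames = np.concatenate([t_.frames for t_ in by_channel[ff_channel]], axis=0)
        try:
            ff = estimate_flatfield(frames)
        except ValueError:
            ff = None
        deskewed: dict[str, list] = {}
        for ch, ch_tiles in sorted(by_channel.items()):
            volumes = []
            for tile in ch_tiles:
                if ff is not None:
                    tile.frames = apply_flatfield(tile.frames, ff)
                volumes.append(shear_correct(tile))
            deskewed[ch] = volumes
        # register once on the texture-rich particle channel; all channels
        # come from one camera and must stay on a common grid
        ref_ch = "particle" if "particle" in deskewed else sorted(deskewed)[0]
        corrections = register_offsets(deskewed[ref_ch]) if len(deskewed[ref_ch]) > 1 else None
        for ch, volumes in sorted(deskewed.items()):
            if corrections is not None:
                volumes = apply_offsets(volumes, corrections)
            stitched = stitch_tiles(volumes, config.scan, register=False)
            if psf is None or psf_grid != stitched.voxel_size_um:
                psf = make_lightsheet_psf(config.optics, stitched.voxel_size_um)
                psf_grid = stitched.voxel_size_um
            # pyramid blending may undershoot slightly; RL needs ≥ 0
            filled = stitched.with_data(np.clip(np.nan_to_num(stitched.data), 0.0, None))
            decon = lr_deconvolve(filled, psf, iterations=config.lr_iterations)
            decon.data[~np.isfinite(stitched.data)] = np.nan
            written.append(write_volume(decon, rec_dir / f"rec_{ch}_t{t:05.1f}.tif"))
    return written


def _stage_segment(config: PipelineConfig, out: Path) -> list[Path]:
    rec_dir = out / "reconstructed"
    seg_dir = out / "segmented"
    existing = sorted(seg_dir.glob("*.tif"))
    if existing and len(existing) >= 3 * len(config.timepoints_h):
        logger.info("segment: outputs exist, skipping")
        return existing

    written = []
    seg = config.segmentation
    prev_seed = None
    for t in config.timepoints_h:
        scatter = read_volume(rec_dir / f"rec_scatter_t{t:05.1f}.tif")
        particle = read_volume(rec_dir / f"rec_particle_t{t:05.1f}.tif")
        gfp = read_volume(rec_dir / f"rec_gfp_t{t:05.1f}.tif")
        seeds = [prev_seed] if prev_seed is not None else None
        root = segment_root(
            scatter, seeds=seeds, threshold=seg.root_threshold,
            connectivity=seg.root_connectivity,
        )
        # propagate: next seed is this mask's centroid voxel (nearest in-mask)
        prev_seed = _mask_centroid_voxel(root.mask)
        pores = segment_pores(particle, gfp, root, threshold=seg.pore_threshold,
                              morph_radius=seg.morph_radius)
        pore_size = local_thickness(
            pores, scatter.voxel_size_um[0],
            resolution_um=scatter.voxel_size_um[0] / 2,
        )
        for name, data, dtype in (
            ("root", root.mask, np.uint8),
            ("pores", pores, np.uint8),
            ("poresize", pore_size, np.float32),
        ):
            vol = VolumeImage(
                data.astype(dtype), scatter.voxel_size_um, scatter.origin_um,
                channel=name, timepoint_h=float(t),
            )
            written.append(write_volume(vol, seg_dir / f"{name}_t{t:05.1f}.tif"))
    return written


def _mask_centroid_voxel(mask: np.ndarray):
    pts = np.argwhere(mask)
    centroid = pts.mean(axis=0)
    return tuple(int(i) for i in pts[np.argmin(np.sum((pts - centroid) ** 2, axis=1))])


def _stage_quantify(config: PipelineConfig, out: Path) -> list[Path]:
    rec_dir = out / "reconstructed"
    seg_dir = out / "segmented"
    q_dir = out / "quantified"
    q_dir.mkdir(parents=True, exist_ok=True)
    ph = config.phantom
    calib = CalibrationModel(ph.calib_a, ph.calib_b, ph.calib_c)

    qc = config.quantification
    densities, root_volumes = [], []
    groups_by_scheme: dict[str, list] = {s: [] for s in qc.schemes}
    from_tip_maps, soil_masks = [], []
    for t in config.timepoints_h:
        gfp = read_volume(rec_dir / f"rec_gfp_t{t:05.1f}.tif")
        root = read_volume(seg_dir / f"root_t{t:05.1f}.tif").data.astype(bool)
        pore_size = read_volume(seg_dir / f"poresize_t{t:05.1f}.tif").data
        density = intensity_to_density(gfp, calib)
        density[root] = np.nan
        maps = centerline_and_tip(root, gfp.voxel_size_um)
        soil = ~root
        for scheme in qc.schemes:
            groups_by_scheme[scheme].append(
                classify_pixels(maps, pore_size, scheme, analyzed_mask=soil)
            )
        densities.append(density)
        from_tip_maps.append(maps.from_tip_um)
        soil_masks.append(soil)
        root_volumes.append(float(root.sum()) * gfp.voxel_volume_mm3)

    written = []
    voxel = read_volume(rec_dir / f"rec_gfp_t{config.timepoints_h[0]:05.1f}.tif").voxel_size_um
    tables = []
    for scheme in qc.schemes:
        table = compute_indicators(
            densities, groups_by_scheme[scheme], config.timepoints_h, voxel,
            root_volumes_mm3=root_volumes, per_root_volume=qc.per_root_volume,
            discard_first=qc.discard_first_timepoints,
        )
        tables.append(table)
    indicators = _concat(tables)
    p = q_dir / "indicators.csv"
    _write_csv(indicators, p, config)
    written.append(p)

    matrix, centers, mean_prof, var_prof = kinematics_diagram(
        densities, from_tip_maps, config.timepoints_h,
        bin_um=qc.kinematics_bin_um, analyzed_masks=soil_masks,
    )
    import pandas as pd

    kin = pd.DataFrame(matrix, index=centers, columns=list(config.timepoints_h))
    kin.index.name = "from_tip_um"
    p = q_dir / "kinematics.csv"
    _write_csv(kin.reset_index(), p, config)
    written.append(p)
    prof = pd.DataFrame(
        {"from_tip_um": centers, "mean_density": mean_prof, "temporal_variance": var_prof}
    )
    p = q_dir / "kinematics_profiles.csv"
    _write_csv(prof, p, config)
    written.append(p)

    if "rhizosphere_bulk" in qc.schemes:
        summary = timeseries_summary(
            densities, groups_by_scheme["rhizosphere_bulk"], config.timepoints_h
        )
        p = q_dir / "timeseries_summary.csv"
        _write_csv(summary, p, config)
        written.append(p)
    return written


def _concat(tables):
    import pandas as pd

    return pd.concat(tables, ignore_index=True)


def _write_csv(df, path: Path, config: PipelineConfig) -> None:
    """CSV with a YAML metadata header in comment lines."""
    header = yaml.safe_dump(
        {"generator": f"rhizolight {__version__}", "seed": config.rng_seed,
         "units": {"length": "um", "time": "h", "density": "CFU/mL"}},
        sort_keys=False,
    )
    with open(path, "w") as fh:
        for line in header.strip().splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "reconstruct": _stage_reconstruct,
    "segment": _stage_segment,
    "quantify": _stage_quantify,
}
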