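"""Reading and writing volumes, tile stacks and manifests.

Volumes travel as OME-TIFF with voxel-size metadata plus a sidecar YAML
(origin, time point, channel — fields OME pixel sizes alone do not carry).
Raw tiles are one multi-page TIFF per tile per channel next to a single
YAML manifest recording the scan geometry, units and seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .geometry import ChamberGeometry, ScanGeometry
from .volume import TileStack, VolumeImage

__all__ = ["read_volume", "write_volume", "write_tiles", "read_tiles"]


def write_volume(volume: VolumeImage, path) -> Path:
    """Write one channel volume as OME-TIFF plus a sidecar YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dz, dy, dx = volume.voxel_size_um
    tifffile.imwrite(
        path,
        np.ascontiguousarray(volume.data)[None],  # singleton C axis carries the name
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": [volume.channel]},
        },
    )
    sidecar = {
        "voxel_size_um": [float(v) for v in volume.voxel_size_um],
        "origin_um": [float(v) for v in volume.origin_um],
        "channel": volume.channel,
        "timepoint_h": float(volume.timepoint_h),
        "units": {"length": "um", "time": "h"},
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))
    return path


def read_volume(path) -> VolumeImage:
    """Read a volume written by :func:`write_volume` (or any OME-TIFF with
    physical pixel sizes). Refuses files with no voxel-size metadata."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 4 and data.shape[0] == 1:
        data = data[0]
    sidecar_path = path.with_suffix(path.suffix + ".yaml")
    meta: dict = {}
    if sidecar_path.exists():
        meta = yaml.safe_load(sidecar_path.read_text()) or {}
    if "voxel_size_um" in meta:
        voxel = tuple(float(v) for v in meta["voxel_size_um"])
    else:
        voxel = _voxel_from_ome(path)
        if voxel is None:
            raise ValueError(
                f"{path}: no voxel-size metadata (OME PhysicalSize or sidecar YAML required)"
            )
    return VolumeImage(
        data=data,
        voxel_size_um=voxel,
        origin_um=tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
        channel=meta.get("channel", _channel_from_ome(path) or "gfp"),
        timepoint_h=float(meta.get("timepoint_h", 0.0)),
    )


def _voxel_from_ome(path: Path):
    with tifffile.TiffFile(path) as tif:
        if tif.ome_metadata is None:
            return None
        from xml.etree import ElementTree

        root = ElementTree.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is None:
            return None
        try:
            return (
                float(px.attrib["PhysicalSizeZ"]),
                float(px.attrib["PhysicalSizeY"]),
                float(px.attrib["PhysicalSizeX"]),
            )
        except KeyError:
            return None


def _channel_from_ome(path: Path):
    with tifffile.TiffFile(path) as tif:
        if tif.ome_metadata is None:
            return None
        from xml.etree import ElementTree

        root = ElementTree.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        ch = root.find(".//ome:Channel", ns)
        return ch.attrib.get("Name") if ch is not None else None


# -------------------------------------------------------------- tiles

def write_tiles(tiles: list[TileStack], out_dir, seed: int | None = None) -> Path:
    """Write tile stacks as multi-page TIFFs plus one YAML manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not tiles:
        raise ValueError("no tiles to write")
    scan = tiles[0].scan
    entries = []
    for tile in tiles:
        i, j = tile.tile_index
        name = f"tile_{i}_{j}_{tile.channel}_t{tile.timepoint_h:05.1f}.tif"
        tifffile.imwrite(out_dir / name, np.asarray(tile.frames, dtype=np.float32))
        entries.append(
            {
                "file": name,
                "channel": tile.channel,
                "tile_index": [int(i), int(j)],
                "origin_um": [float(v) for v in tile.origin_um],
                "pixel_size_um": [float(v) for v in tile.pixel_size_um],
                "timepoint_h": float(tile.timepoint_h),
            }
        )
    manifest = {
        "units": {"length": "um", "time": "h"},
        "seed": seed,
        "scan": {
            "scan_angle_deg": scan.scan_angle_deg,
            "slice_step_um": scan.slice_step_um,
            "slices_per_tile": scan.slices_per_tile,
            "tile_grid": list(scan.tile_grid),
            "tile_overlap_fraction": scan.tile_overlap_fraction,
            "vertical_step_mm": scan.vertical_step_mm,
            "footprint_mm": list(scan.footprint_mm),
            "chamber": dataclasses.asdict(scan.chamber),
        },
        "tiles": entries,
    }
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def read_tiles(manifest_path, timepoint_h: float | None = None) -> list[TileStack]:
    """Read tile stacks listed in a manifest, optionally one time point."""
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    sc = manifest["scan"]
    scan = ScanGeometry(
        scan_angle_deg=sc["scan_angle_deg"],
        slice_step_um=sc["slice_step_um"],
        slices_per_tile=sc["slices_per_tile"],
        tile_grid=tuple(sc["tile_grid"]),
        tile_overlap_fraction=sc["tile_overlap_fraction"],
        vertical_step_mm=sc.get("vertical_step_mm", 4.0),
        footprint_mm=tuple(sc.get("footprint_mm", (20.0, 60.0))),
        chamber=ChamberGeometry(**sc["chamber"]),
    )
    tiles = []
    for entry in manifest["tiles"]:
        if timepoint_h is not None and entry["timepoint_h"] != timepoint_h:
            continue
        frames = tifffile.imread(manifest_path.parent / entry["file"])
        tiles.append(
            TileStack(
                frames=frames,
                channel=entry["channel"],
                tile_index=tuple(entry["tile_index"]),
                scan=scan,
                pixel_size_um=tuple(entry["pixel_size_um"]),
                origin_um=tuple(entry["origin_um"]),
                timepoint_h=entry["timepoint_h"],
            )
        )
    return tiles
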