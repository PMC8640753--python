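"""Pipeline configuration: one YAML-serializable tree of parameter blocks.

Every run writes its resolved configuration beside its outputs so that a
run is reproducible from the output directory alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import ChamberGeometry, NoiseModel, OpticsModel, ScanGeometry
from .phantom import BacteriaFieldSpec

__all__ = ["PipelineConfig", "PhantomConfig", "SegmentationConfig", "QuantificationConfig"]


@dataclass
class PhantomConfig:
    voxel_size_um: float = 25.0
    particle_size_range_um: tuple[float, float] = (250.0, 1250.0)
    target_porosity: float = 0.55
    root_base: tuple[float, float, float] = (1500.0, 0.0, 1500.0)
    root_direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    root_radius_um: float = 250.0
    elongation_rate_um_h: float = 200.0
    initial_root_length_um: float = 2000.0
    calib_a: float = 1000.0
    calib_b: float = 50.0
    calib_c: float = 2.0e8


@dataclass
class SegmentationConfig:
    root_threshold: float | None = None  # None → Otsu
    root_connectivity: int = 26
    pore_threshold: float | None = None
    morph_radius: int = 1


@dataclass
class QuantificationConfig:
    schemes: tuple[str, ...] = ("rhizosphere_bulk", "tip_base", "by_pore_size", "by_root_distance")
    per_root_volume: bool = True
    kinematics_bin_um: float = 500.0
    discard_first_timepoints: int = 5


@dataclass
class PipelineConfig:
    chamber: ChamberGeometry = field(default_factory=ChamberGeometry)
    scan: ScanGeometry = field(default_factory=ScanGeometry)
    optics: OpticsModel = field(default_factory=OpticsModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    bacteria: BacteriaFieldSpec = field(default_factory=BacteriaFieldSpec)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    quantification: QuantificationConfig = field(default_factory=QuantificationConfig)
    timepoints_h: tuple[float, ...] = tuple(float(t) for t in range(20, 43))
    simulate: bool = True
    lr_iterations: int = 10
    rng_seed: int = 0
    output_dir: str = "rhizolight_out"

    # ---------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        chamber = ChamberGeometry(**d.pop("chamber", {}))
        scan_d = dict(d.pop("scan", {}))
        scan_d.pop("chamber", None)
        for key in ("tile_grid", "footprint_mm"):
            if key in scan_d:
                scan_d[key] = tuple(scan_d[key])
        kwargs = dict(
            chamber=chamber,
            scan=ScanGeometry(chamber=chamber, **scan_d),
            optics=OpticsModel(**d.pop("optics", {})),
            noise=NoiseModel(**d.pop("noise", {})),
            phantom=PhantomConfig(**_tuplify(d.pop("phantom", {}))),
            bacteria=BacteriaFieldSpec(**_tuplify(d.pop("bacteria", {}))),
            segmentation=SegmentationConfig(**d.pop("segmentation", {})),
            quantification=QuantificationConfig(**_tuplify(d.pop("quantification", {}))),
        )
        if "timepoints_h" in d:
            kwargs["timepoints_h"] = tuple(float(t) for t in d.pop("timepoints_h"))
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def small_demo(cls, seed: int = 0) -> "PipelineConfig":
        """Desk-scale phantom configuration: a few-mm chamber at reduced
        resolution, small enough to run the whole chain in seconds."""
        chamber = ChamberGeometry(width_mm=3.0, height_mm=5.0, depth_mm=1.5)
        voxel = 50.0
        scan = ScanGeometry(
            scan_angle_deg=45.0,
            slice_step_um=voxel * 2**0.5,
            slices_per_tile=40,
            tile_grid=(1, 2),
            tile_overlap_fraction=0.25,
            footprint_mm=(chamber.width_mm, chamber.height_mm),
            chamber=chamber,
        )
        return cls(
            chamber=chamber,
            scan=scan,
            optics=OpticsModel(sheet_fwhm_um=100.0, lateral_fwhm_um=60.0),
            phantom=PhantomConfig(
                voxel_size_um=voxel,
                particle_size_range_um=(300.0, 700.0),
                target_porosity=0.6,
                root_base=(750.0, 0.0, 1500.0),
            ),
            bacteria=BacteriaFieldSpec(
                source_point=(750.0, 500.0, 1500.0),
                bulk_peak_h=26.0,
                root_peak_h=32.0,
                n_hotspots=3,
            ),
            timepoints_h=tuple(float(t) for t in range(20, 43)),
            rng_seed=seed,
        )


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
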