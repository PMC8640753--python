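"""Shared fixtures: small phantoms every suite can afford to rebuild."""

import numpy as np
import pytest

from rhizolight.geometry import ChamberGeometry, NoiseModel, OpticsModel, ScanGeometry
from rhizolight.phantom import BacteriaFieldSpec, MesocosmPhantom, make_particle_packing


@pytest.fixture(scope="session")
def small_chamber():
    return ChamberGeometry(width_mm=3.0, height_mm=3.0, depth_mm=1.5)


@pytest.fixture(scope="session")
def small_packing(small_chamber):
    return make_particle_packing(small_chamber, (300.0, 700.0), 0.6, seed=1)


@pytest.fixture(scope="session")
def small_phantom(small_chamber, small_packing):
    return MesocosmPhantom(
        chamber=small_chamber,
        packing=small_packing,
        field_spec=BacteriaFieldSpec(
            source_point=(750.0, 500.0, 1500.0), n_hotspots=2
        ),
        voxel_size_um=25.0,
        root_base=(750.0, 0.0, 1500.0),
        root_direction=(0.0, 1.0, 0.0),
        root_radius_um=200.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_scan(small_chamber):
    voxel = 25.0
    return ScanGeometry(
        scan_angle_deg=45.0,
        slice_step_um=voxel * 2**0.5,
        slices_per_tile=80,
        tile_grid=(2, 2),
        tile_overlap_fraction=0.2,
        footprint_mm=(small_chamber.width_mm, small_chamber.height_mm),
        chamber=small_chamber,
    )


@pytest.fixture(scope="session")
def small_optics():
    return OpticsModel(sheet_fwhm_um=50.0, lateral_fwhm_um=30.0)


@pytest.fixture
def clean_noise():
    return NoiseModel()


def brute_force_edt(mask: np.ndarray, sampling) -> np.ndarray:
    """All-pairs minimum distance from each foreground voxel to the nearest
    background voxel centre; the independent distance-transform oracle."""
    sampling = np.broadcast_to(np.asarray(sampling, dtype=float), (3,))
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape, dtype=float)
    if len(bg) == 0 or len(fg) == 0:
        return out
    bgs = bg * sampling
    for chunk in np.array_split(fg, max(1, len(fg) // 512)):
        d2 = np.sum((chunk[:, None, :] * sampling - bgs[None, :, :]) ** 2, axis=2)
        out[tuple(chunk.T)] = np.sqrt(d2.min(axis=1))
    return out


def brute_force_local_thickness(pores: np.ndarray, voxel_size_um: float) -> np.ndarray:
    """Exhaustive inscribed-sphere search: thickness(v) = 2·max{dt(c) :
    ‖v−c‖ < dt(c)} over all pore voxels c, with dt itself brute-forced."""
    dt = brute_force_edt(pores, voxel_size_um)
    pv = np.argwhere(pores)
    out = np.zeros(pores.shape, dtype=float)
    if len(pv) == 0:
        return out
    centres = pv * voxel_size_um
    radii = dt[tuple(pv.T)]
    for chunk in np.array_split(pv, max(1, len(pv) // 256)):
        d = np.sqrt(
            np.sum((chunk[:, None, :] * voxel_size_um - centres[None, :, :]) ** 2, axis=2)
        )
        contained = d < radii[None, :]
        vals = np.where(contained, radii[None, :], 0.0)
        out[tuple(chunk.T)] = 2.0 * vals.max(axis=1)
    return out
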