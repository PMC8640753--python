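import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhizolight.geometry import ChamberGeometry, NoiseModel, OpticsModel, ScanGeometry
from rhizolight.phantom import (
    BacteriaFieldSpec,
    PackingError,
    bacteria_density_field,
    grow_root,
    make_particle_packing,
    rasterize_particles,
    render_scan,
)
from rhizolight.volume import VolumeImage


class TestParticlePacking:
    def test_sparse_packing_keeps_high_porosity(self):
        pk = make_particle_packing(
            ChamberGeometry(22.0, 65.0, 3.0), (250.0, 1250.0), 0.99, seed=1
        )
        assert pk.porosity >= 0.99
        assert pk.n_particles > 0

    def test_target_one_gives_empty_packing(self):
        pk = make_particle_packing(ChamberGeometry(), target_porosity=1.0, seed=0)
        assert pk.n_particles == 0
        assert pk.porosity == 1.0

    def test_voxelized_porosity_matches_analytic(self):
        # porosity from sphere volumes vs counting 10 µm voxels
        box = ChamberGeometry(2.0, 2.0, 2.0)
        pk = make_particle_packing(box, (300.0, 600.0), 0.6, seed=7)
        assert pk.porosity == pytest.approx(0.6, abs=0.02)
        mask = rasterize_particles(pk, 10.0)
        voxel_porosity = 1.0 - mask.mean()
        assert voxel_porosity == pytest.approx(pk.porosity, abs=0.02)

    def test_particles_inside_domain_and_size_range(self):
        box = ChamberGeometry(2.0, 2.0, 2.0)
        pk = make_particle_packing(box, (300.0, 600.0), 0.8, seed=2)
        c, r = pk.particles[:, :3], pk.particles[:, 3]
        assert np.all(2 * r >= 300.0) and np.all(2 * r <= 600.0)
        ext = np.array(box.extent_um)
        assert np.all(c - r[:, None] >= 0) and np.all(c + r[:, None] <= ext)

    def test_deterministic_given_seed(self):
        a = make_particle_packing(ChamberGeometry(2, 2, 2), (300, 600), 0.7, seed=5)
        b = make_particle_packing(ChamberGeometry(2, 2, 2), (300, 600), 0.7, seed=5)
        np.testing.assert_array_equal(a.particles, b.particles)

    def test_unreachable_porosity_raises_with_achieved_value(self):
        with pytest.raises(PackingError, match="achieved"):
            make_particle_packing(ChamberGeometry(2, 2, 2), (300, 600), 0.05, seed=0)


class TestRootGrowth:
    def test_zero_rate_leaves_length_unchanged(self):
        r = grow_root((0, 0, 0), (0, 1, 0), elongation_rate_um_h=0.0, timepoint_h=10.0)
        assert r.length_um == pytest.approx(2000.0, rel=1e-6)

    def test_closed_form_elongation(self):
        r = grow_root((0, 0, 0), (0, 1, 0), elongation_rate_um_h=200.0, timepoint_h=23.0)
        assert r.length_um == pytest.approx(2000.0 + 200.0 * 23.0, rel=1e-6)

    def test_seedling_starts_near_two_millimetres(self):
        r = grow_root((0, 0, 0), (0, 1, 0), timepoint_h=0.0)
        assert r.length_um == pytest.approx(2000.0, rel=1e-6)
        assert not r.truncated

    def test_tip_is_last_centerline_node(self):
        r = grow_root((0, 100, 0), (0, 1, 0), timepoint_h=5.0)
        np.testing.assert_allclose(r.tip_position, r.centerline[-1])
        assert r.tip_position[1] == pytest.approx(100 + r.length_um)

    def test_truncated_at_chamber_wall(self):
        box = ChamberGeometry(2.0, 2.0, 2.0)
        r = grow_root((1000, 0, 1000), (0, 1, 0), timepoint_h=10.0, chamber=box)
        assert r.truncated
        assert r.length_um <= 2000.0 + 1e-6


class TestBacteriaField:
    def _toy_maps(self):
        # two-pore toy: left half small pores (200 µm), right half large (600 µm)
        pore = np.full((4, 4, 8), 200.0)
        pore[:, :, 4:] = 600.0
        root = np.zeros_like(pore, dtype=bool)
        return root, pore

    def test_null_field_is_all_zero(self):
        root, pore = self._toy_maps()
        spec = BacteriaFieldSpec(
            background_density=0.0, root_density=0.0, hotspot_density=0.0,
            pore_bias_strength=1.0,
        )
        f = bacteria_density_field(spec, root, pore, 50.0, 3.0)
        assert np.all(f == 0)

    def test_grid_mismatch_raises(self):
        root, pore = self._toy_maps()
        with pytest.raises(ValueError, match="grid mismatch"):
            bacteria_density_field(BacteriaFieldSpec(), root[:2], pore, 50.0, 0.0)

    def test_pore_bias_ratio_on_two_pore_toy(self):
        root, pore = self._toy_maps()
        spec = BacteriaFieldSpec(
            background_density=1e7, root_density=0.0, hotspot_density=0.0,
            pore_bias_strength=3.0, pore_bias_threshold_um=400.0,
        )
        f = bacteria_density_field(spec, root, pore, 50.0, 0.0)
        small = f[pore < 400].mean()
        large = f[pore >= 400].mean()
        assert small / large == pytest.approx(3.0, rel=1e-9)

    def test_pulse_schedule_over_hourly_timepoints(self):
        spec = BacteriaFieldSpec(hotspot_period_h=4.0, hotspot_duration_h=2.0)
        states = [spec.hotspot_active(t) for t in range(23)]
        expected = [(t % 4.0) < 2.0 for t in range(23)]
        assert states == expected

    @given(
        period=st.floats(1.0, 12.0),
        frac=st.floats(0.1, 0.9),
        t=st.floats(0.0, 100.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pulse_rule_matches_modular_arithmetic(self, period, frac, t):
        spec = BacteriaFieldSpec(hotspot_period_h=period, hotspot_duration_h=frac * period)
        assert spec.hotspot_active(t) == ((t % period) < frac * period)

    def test_hotspots_toggle_with_schedule(self):
        # one hotspot, no other sources: active at t=1, silent at t=3
        root = np.zeros((6, 6, 6), dtype=bool)
        pore = np.full((6, 6, 6), 500.0)
        spec = BacteriaFieldSpec(
            background_density=0.0, root_density=0.0, pore_bias_strength=1.0,
            hotspot_period_h=4.0, hotspot_duration_h=2.0, n_hotspots=1,
            hotspot_density=1e8, hotspot_sigma_um=200.0,
        )
        on = bacteria_density_field(spec, root, pore, 50.0, 1.0, seed=4)
        off = bacteria_density_field(spec, root, pore, 50.0, 3.0, seed=4)
        assert on.max() > 0
        assert np.all(off == 0)

    def test_field_never_negative_and_zero_in_solid(self, small_phantom):
        f = small_phantom.density_at(26.0)
        assert np.all(f >= 0)
        assert np.all(f[small_phantom.particle_mask & (small_phantom.pore_size_map() == 0)] == 0)


def _point_truth(voxel=25.0, shape=(40, 48, 48), spots=((20, 24, 24),), value=1000.0):
    data = np.zeros(shape)
    for s in spots:
        data[s] = value
    return {
        "gfp": VolumeImage(data, (voxel, voxel, voxel), channel="gfp")
    }


class TestRenderScan:
    def test_identity_forward_model_crops_truth(self):
        # angle 0, delta PSF, no noise, single tile → frames equal truth
        truth = _point_truth()
        vol = truth["gfp"]
        rng = np.random.default_rng(0)
        vol.data[:] = rng.uniform(0, 100, vol.shape)
        scan = ScanGeometry(
            scan_angle_deg=0.0, slice_step_um=25.0, slices_per_tile=40,
            tile_grid=(1, 1), tile_overlap_fraction=0.0,
        )
        optics = OpticsModel(sheet_fwhm_um=1e-9, lateral_fwhm_um=1e-9)
        tiles = render_scan(truth, scan, optics, NoiseModel())
        assert len(tiles) == 1
        np.testing.assert_allclose(tiles[0].frames, vol.data, rtol=1e-9)

    def test_rendered_blob_axial_fwhm_matches_sheet(self):
        truth = _point_truth()
        scan = ScanGeometry(
            scan_angle_deg=0.0, slice_step_um=25.0, slices_per_tile=40,
            tile_grid=(1, 1), tile_overlap_fraction=0.0,
        )
        optics = OpticsModel(sheet_fwhm_um=50.0, lateral_fwhm_um=25.0)
        (tile,) = render_scan(truth, scan, optics, NoiseModel())
        profile = tile.frames[:, 24, 24]
        fwhm_um = _fwhm(profile) * 25.0
        assert fwhm_um == pytest.approx(50.0, abs=5.0)

    def test_shear_displaces_centroid_by_slice_arithmetic(self):
        # a blurred point at 45°: in-frame centroid drifts step·sinθ per slice
        truth = _point_truth()
        voxel = 25.0
        scan = ScanGeometry(
            scan_angle_deg=45.0, slice_step_um=voxel * np.sqrt(2), slices_per_tile=80,
            tile_grid=(1, 1), tile_overlap_fraction=0.0,
        )
        optics = OpticsModel(sheet_fwhm_um=75.0, lateral_fwhm_um=50.0)
        (tile,) = render_scan(truth, scan, optics, NoiseModel())
        ks, us = [], []
        for k in range(tile.frames.shape[0]):
            frame = tile.frames[k]
            if frame.sum() > 1e-3 * tile.frames.max():
                cols = np.arange(frame.shape[1])
                us.append((frame.sum(axis=0) * cols).sum() / frame.sum())
                ks.append(k)
        slope_px = np.polyfit(ks, us, 1)[0]
        expected = scan.shear_per_slice_um / voxel  # step·sinθ in pixels
        assert slope_px == pytest.approx(-expected, rel=0.05)

    def test_total_intensity_conserved_without_noise(self, small_phantom, small_scan, small_optics):
        from rhizolight.reconstruct import shear_correct
        from rhizolight.stitching import stitch_tiles
        from scipy import ndimage as ndi

        truth = small_phantom.truth_volumes(22.0)
        tiles = render_scan(truth, small_scan, small_optics, NoiseModel())
        gfp = [t for t in tiles if t.channel == "gfp"]
        stitched = stitch_tiles([shear_correct(t) for t in gfp], small_scan)
        voxel = truth["gfp"].voxel_size_um[0]
        sig = (
            np.array([small_optics.sheet_fwhm_um] + [small_optics.lateral_fwhm_um] * 2)
            / 2.355 / voxel
        )
        blurred = ndi.gaussian_filter(truth["gfp"].data, sig, mode="constant")
        total_rendered = np.nansum(stitched.data)
        assert total_rendered == pytest.approx(blurred.sum(), rel=0.01)

    def test_render_deterministic_given_seed(self, small_phantom, small_scan, small_optics):
        truth = small_phantom.truth_volumes(21.0)
        noise = NoiseModel(read_noise_sd=3.0, vignetting_min=0.7, rng_seed=11)
        a = render_scan(truth, small_scan, small_optics, noise)
        b = render_scan(truth, small_scan, small_optics, noise)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.frames, tb.frames)

    def test_insufficient_slices_raise_coverage_error(self):
        from rhizolight.phantom import CoverageError

        truth = _point_truth()
        scan = ScanGeometry(
            scan_angle_deg=0.0, slice_step_um=25.0, slices_per_tile=10,
            tile_grid=(1, 1), tile_overlap_fraction=0.0,
        )
        with pytest.raises(CoverageError):
            render_scan(truth, scan, OpticsModel(), NoiseModel())


def _fwhm(profile: np.ndarray) -> float:
    """Interpolated full width at half maximum, in samples."""
    p = profile - profile.min()
    half = p.max() / 2.0
    above = np.where(p >= half)[0]
    lo, hi = above[0], above[-1]
    left = lo - (p[lo] - half) / (p[lo] - p[lo - 1]) if lo > 0 else lo
    right = hi + (p[hi] - half) / (p[hi] - p[hi + 1]) if hi + 1 < len(p) else hi
    return right - left
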