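import numpy as np
import pandas as pd
import pytest

from rhizolight.quantify import (
    CalibrationError,
    CalibrationModel,
    DistanceMaps,
    centerline_and_tip,
    classify_pixels,
    compute_indicators,
    distance_from_root,
    dominant_period,
    fit_calibration,
    intensity_to_density,
    kinematics_diagram,
    peak_time,
    stripe_slope,
    timeseries_summary,
)
from rhizolight.volume import VolumeImage

from conftest import brute_force_edt


class TestDistanceFromRoot:
    def test_unit_step_next_to_root_face(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2, 2, 2] = True
        d = distance_from_root(mask, 50.0)
        assert d[2, 2, 3] == pytest.approx(50.0)
        assert d[2, 2, 2] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_exactly(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(6, 14, 3))
        mask = rng.random(shape) > 0.9
        if not mask.any():
            mask[0, 0, 0] = True
        sampling = (60.0, 50.0, 40.0)  # anisotropic voxels
        d = distance_from_root(mask, sampling)
        brute = brute_force_edt(~mask, sampling)
        np.testing.assert_allclose(d, brute, atol=1e-9)

    def test_ball_root_analytic_distance(self):
        voxel = 50.0
        shape = (24, 24, 24)
        zz, yy, xx = np.indices(shape)
        r_vox = 4
        mask = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= r_vox**2
        d = distance_from_root(mask, voxel)
        probe = (12, 12, 22)
        expected = (22 - 12) * voxel - r_vox * voxel
        assert d[probe] == pytest.approx(expected, abs=voxel)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            distance_from_root(np.zeros((4, 4, 4), dtype=bool), 50.0)


class TestCenterline:
    def test_straight_cylinder_length_and_tip(self):
        voxel = 50.0
        shape = (16, 50, 16)
        zz, yy, xx = np.indices(shape)
        mask = ((zz - 8) ** 2 + (xx - 8) ** 2 <= 9) & (yy >= 5) & (yy < 45)
        maps = centerline_and_tip(mask, voxel, base_hint=(8, 5, 8))
        true_len = (45 - 5 - 1) * voxel
        assert maps.arclength_from_tip_um.max() == pytest.approx(true_len, abs=2 * voxel)
        # tip (last node) sits at the far (high-y) end
        assert maps.centerline_um[-1][1] > maps.centerline_um[0][1]

    def test_from_tip_vanishes_beside_tip(self):
        voxel = 50.0
        shape = (12, 40, 12)
        zz, yy, xx = np.indices(shape)
        mask = ((zz - 6) ** 2 + (xx - 6) ** 2 <= 4) & (yy < 30)
        maps = centerline_and_tip(mask, voxel, base_hint=(6, 0, 6))
        tip = maps.centerline_um[-1]
        tip_vox = tuple(int(c / voxel) for c in tip)
        probe = (tip_vox[0], min(tip_vox[1] + 1, 39), tip_vox[2])
        assert maps.from_tip_um[probe] <= 2 * voxel

    def test_curved_tube_arc_length(self):
        # capsule-shaped quarter-circle tube, axis radius 1 mm: centerline
        # runs tip-of-cap to tip-of-cap, π/2 mm plus one tube radius per end
        voxel = 25.0
        shape = (12, 50, 50)
        R = 1000.0
        t = np.linspace(0, np.pi / 2, 200)
        pts = np.stack(
            [np.full_like(t, 6 * voxel), R * np.sin(t) + 100, R * np.cos(t) + 100], axis=1
        )
        mask = np.zeros(shape, dtype=bool)
        for p in pts:
            zi, yi, xi = (p / voxel).astype(int)
            zz, yy, xx = np.ogrid[:12, :50, :50]
            mask |= (
                (zz * voxel - p[0]) ** 2 + (yy * voxel - p[1]) ** 2 + (xx * voxel - p[2]) ** 2
            ) <= 150.0**2
        maps = centerline_and_tip(mask, voxel)
        expected = R * np.pi / 2 + 2 * 150.0
        assert maps.arclength_from_tip_um.max() == pytest.approx(expected, rel=0.05)

    def test_degenerate_blob_raises(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[3, 3, 3] = True
        with pytest.raises(ValueError, match="degenerate|skeleton"):
            centerline_and_tip(mask, 50.0)


class TestCalibration:
    def test_exact_lines_recovered(self):
        a, b, c = 1000.0, 50.0, 2.0e8
        od = np.geomspace(1.2e-3, 3.0, 12)
        standards = [(a * x + b, x) for x in od]
        cfu = [(x, c * x) for x in od]
        model = fit_calibration(standards, cfu)
        assert model.intensity_per_od == pytest.approx(a, rel=1e-6)
        assert model.intensity_offset == pytest.approx(b, rel=1e-6)
        assert model.cfu_per_od == pytest.approx(c, rel=1e-6)
        assert model.r2_intensity_od == pytest.approx(1.0, abs=1e-9)

    def test_constant_intensity_rejected(self):
        od = np.geomspace(1.2e-3, 3.0, 12)
        standards = [(500.0, x) for x in od]
        cfu = [(x, 2e8 * x) for x in od]
        with pytest.raises(CalibrationError):
            fit_calibration(standards, cfu)

    def test_noisy_dilution_series_recovery(self):
        # the instrument's design: 12 ODs spanning [1.2e-3, 3.0], 1% noise
        rng = np.random.default_rng(12)
        a, b, c = 1000.0, 50.0, 2.0e8
        od = np.geomspace(1.2e-3, 3.0, 12)
        for _ in range(20):
            standards = [(float((a * x + b) * (1 + rng.normal(0, 0.01))), x) for x in od]
            cfu = [(x, float(c * x * (1 + rng.normal(0, 0.01)))) for x in od]
            model = fit_calibration(standards, cfu)
            assert model.intensity_per_od == pytest.approx(a, rel=0.05)
            assert model.cfu_per_od == pytest.approx(c, rel=0.05)

    def test_narrow_od_span_rejected(self):
        standards = [(100.0 + i, 1.0 + 0.01 * i) for i in range(5)]
        cfu = [(1.0 + 0.01 * i, 2e8) for i in range(5)]
        with pytest.raises(CalibrationError, match="decade"):
            fit_calibration(standards, cfu)

    def test_intensity_to_density_plug_in(self):
        model = CalibrationModel(1000.0, 50.0, 2.0e8)
        vol = VolumeImage(np.array([[[50.0, 1050.0, 0.0]]]), (50.0,) * 3)
        d = intensity_to_density(vol, model)
        assert d[0, 0, 0] == 0.0  # intensity = offset
        assert d[0, 0, 1] == pytest.approx(2.0e8)  # intensity = a + b
        assert d[0, 0, 2] == 0.0  # clipped below offset

    def test_phantom_round_trip(self, small_phantom):
        density = small_phantom.density_at(24.0)
        gfp = small_phantom.density_to_intensity(density)
        model = CalibrationModel(
            small_phantom.calib_a, small_phantom.calib_b, small_phantom.calib_c
        )
        recovered = model.density(gfp)
        rms = np.sqrt(np.mean((recovered - density) ** 2))
        assert rms <= 0.02 * density.max()


def _maps(shape, voxel, root_mask=None, tip_at_high_y=True):
    from rhizolight.quantify import distance_from_root

    if root_mask is None:
        root_mask = np.zeros(shape, dtype=bool)
        root_mask[:, :, shape[2] // 2] = True
    d_root = distance_from_root(root_mask, voxel)
    yy = np.indices(shape)[1].astype(float) * voxel
    from_tip = yy.max() - yy if tip_at_high_y else yy
    return DistanceMaps(d_root, from_tip, np.zeros((2, 3)), np.zeros(2)), root_mask


class TestClassifyPixels:
    def test_rhizosphere_cut_at_200_um(self):
        shape = (4, 4, 12)
        voxel = 50.0
        maps, root = _maps(shape, voxel)
        groups = classify_pixels(maps, None, "rhizosphere_bulk")
        d = maps.from_root_surface_um
        assert np.all(groups.group_id[(d > 0) & (d < 200.0)] == 0)
        assert np.all(groups.group_id[d >= 200.0] == 1)
        assert np.all(groups.group_id[root] == -1)

    def test_tip_base_cut_at_2_mm(self):
        shape = (4, 60, 4)
        voxel = 50.0
        maps, _ = _maps(shape, voxel)
        groups = classify_pixels(maps, None, "tip_base")
        sel = groups.group_id >= 0
        base = maps.from_tip_um > 2000.0
        assert np.all(groups.group_id[sel & base] == 1)
        assert np.all(groups.group_id[sel & ~base] == 0)

    def test_pore_bins_half_open_boundary_falls_upward(self):
        shape = (2, 2, 4)
        voxel = 50.0
        maps, _ = _maps(shape, voxel)
        pores = np.full(shape, 100.0)
        pores[0, 0, 0] = 400.0  # exactly on an edge
        groups = classify_pixels(maps, pores, "by_pore_size", bin_edges=[0.0, 400.0, 800.0])
        assert groups.group_id[0, 0, 0] == 1
        assert groups.labels[1] == "[400,800)"

    def test_partition_covers_analyzed_region(self):
        shape = (6, 20, 10)
        voxel = 50.0
        maps, root = _maps(shape, voxel)
        for scheme in ("rhizosphere_bulk", "tip_base", "by_tip_distance"):
            groups = classify_pixels(maps, None, scheme, analyzed_mask=~root)
            counts = [(groups.group_id == k).sum() for k in range(groups.n_groups)]
            assert sum(counts) == groups.analyzed().sum()

    def test_unsorted_bin_edges_rejected(self):
        maps, _ = _maps((2, 2, 4), 50.0)
        with pytest.raises(ValueError, match="increasing"):
            classify_pixels(maps, None, "by_tip_distance", bin_edges=[0, 500, 300])


class TestIndicators:
    def _uniform_setup(self, value=1e8, nt=8):
        shape = (4, 12, 8)
        voxel = 50.0
        maps, root = _maps(shape, voxel)
        groups = classify_pixels(maps, None, "rhizosphere_bulk", analyzed_mask=~root)
        fields = [np.full(shape, value) for _ in range(nt)]
        return fields, [groups] * nt, list(range(20, 20 + nt)), voxel

    def test_uniform_field_normalizes_to_one_with_zero_variance(self):
        fields, groups, times, voxel = self._uniform_setup()
        table = compute_indicators(fields, groups, times, voxel, per_root_volume=False)
        assert np.allclose(table["D_norm"], 1.0, atol=1e-12)
        assert np.allclose(table["variance"].dropna(), 0.0, atol=1e-15)

    def test_two_to_one_density_ratio_normalization(self):
        # groups of equal volume with densities 2x and x → D/⟨D⟩ = 4/3, 2/3
        shape = (2, 2, 8)
        voxel = 50.0
        gid = np.zeros(shape, dtype=np.int32)
        gid[:, :, 4:] = 1
        from rhizolight.quantify import PixelGroups

        groups = PixelGroups(gid, "by_pore_size", None, ["small", "large"])
        field = np.where(gid == 0, 2.0e8, 1.0e8)
        table = compute_indicators([field], [groups], [20.0], voxel, per_root_volume=False)
        by = table.set_index("group_label")["D_norm"]
        assert by["small"] == pytest.approx(4.0 / 3.0)
        assert by["large"] == pytest.approx(2.0 / 3.0)

    def test_mean_over_groups_is_unity(self):
        rng = np.random.default_rng(5)
        fields, groups, times, voxel = self._uniform_setup()
        fields = [f * rng.uniform(0.5, 2.0) + rng.uniform(0, 1e7, f.shape) for f in fields]
        table = compute_indicators(fields, groups, times, voxel, per_root_volume=False)
        means = table.groupby("timepoint_h")["D_norm"].mean()
        assert np.allclose(means, 1.0, atol=1e-9)

    def test_empty_group_flagged_not_fatal(self):
        shape = (2, 2, 4)
        gid = np.zeros(shape, dtype=np.int32)
        from rhizolight.quantify import PixelGroups

        groups = PixelGroups(gid, "by_pore_size", None, ["a", "b"])  # b never occurs
        field = np.full(shape, 1e8)
        table = compute_indicators([field], [groups], [20.0], 50.0, per_root_volume=False)
        row_b = table[table["group_label"] == "b"].iloc[0]
        assert row_b["empty"]
        assert row_b["voxel_count"] == 0

    def test_variance_discards_first_five_timepoints(self):
        fields, groups, times, voxel = self._uniform_setup(nt=8)
        # wild values in the first five time points must not matter
        for k in range(5):
            fields[k] = fields[k] * (10 + k)
        table = compute_indicators(fields, groups, times, voxel, per_root_volume=False)
        assert np.allclose(table["variance"].dropna(), 0.0, atol=1e-12)


class TestKinematics:
    def test_static_hotspot_static_root_gives_horizontal_stripe(self):
        shape = (2, 40, 2)
        voxel = 50.0
        nt = 6
        from_tip = (np.indices(shape)[1].astype(float)) * voxel
        fields = []
        for _ in range(nt):
            f = np.zeros(shape)
            f[:, 20, :] = 1e8
            fields.append(f)
        matrix, centers, _, _ = kinematics_diagram(
            fields, [from_tip] * nt, list(range(nt)), bin_um=100.0
        )
        rows = [int(np.nanargmax(matrix[:, t])) for t in range(nt)]
        assert len(set(rows)) == 1

    def test_fixed_hotspot_under_growth_appears_as_diagonal_stripe(self):
        # root elongates at v: a lab-frame-fixed hotspot recedes from the
        # tip at v, so the stripe slope equals the elongation rate
        shape = (2, 120, 2)
        voxel = 50.0
        v_um_h = 200.0
        times = np.arange(0.0, 10.0)
        hotspot_y = 10  # lab frame voxel row
        fields, ftips = [], []
        yy = np.indices(shape)[1].astype(float) * voxel
        for t in times:
            tip_pos = 1000.0 + v_um_h * t
            from_tip = np.abs(tip_pos - yy)
            f = np.zeros(shape)
            f[:, hotspot_y - 1 : hotspot_y + 2, :] = 1e8
            fields.append(f)
            ftips.append(from_tip)
        matrix, centers, _, _ = kinematics_diagram(fields, ftips, times, bin_um=100.0)
        slope = stripe_slope(matrix, centers, times)
        assert slope == pytest.approx(v_um_h, rel=0.10)

    def test_pulse_period_from_autocorrelation(self):
        times = np.arange(0, 24.0)
        series = np.array([(t % 4.0) < 2.0 for t in times], dtype=float) * 1e8
        assert dominant_period(series, 1.0) == pytest.approx(4.0, abs=1.0)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            kinematics_diagram([np.zeros((2, 2, 2))] * 2, [np.zeros((2, 2, 2))] * 2, [3.0, 2.0])


class TestTimeseriesSummary:
    def _groups(self, shape, voxel):
        maps, root = _maps(shape, voxel)
        return classify_pixels(maps, None, "rhizosphere_bulk", analyzed_mask=~root), root

    def test_constant_field_gives_flat_curves_and_volume_weighting(self):
        shape = (4, 10, 10)
        voxel = 50.0
        groups, root = self._groups(shape, voxel)
        fields = [np.full(shape, 2.0e8) for _ in range(6)]
        df = timeseries_summary(fields, [groups] * 6, list(range(6)))
        for col in ("rhizosphere", "bulk", "total"):
            assert np.allclose(df[col], 2.0e8)
        nr, nb = df["rhizosphere_voxels"][0], df["bulk_voxels"][0]
        weighted = (df["rhizosphere"][0] * nr + df["bulk"][0] * nb) / (nr + nb)
        assert df["total"][0] == pytest.approx(weighted)

    def test_partition_counts_cover_soil(self):
        shape = (4, 10, 10)
        voxel = 50.0
        groups, root = self._groups(shape, voxel)
        fields = [np.full(shape, 1e8)] * 3
        df = timeseries_summary(fields, [groups] * 3, list(range(3)))
        assert (df["rhizosphere_voxels"] + df["bulk_voxels"]).iloc[0] == (~root).sum()

    def test_programmed_peaks_detected(self):
        # bulk envelope peaking at 26 h, rhizosphere at 32 h
        shape = (2, 8, 12)
        voxel = 50.0
        groups, _ = self._groups(shape, voxel)
        times = np.arange(20.0, 43.0)
        d = groups.group_id
        fields = []
        for t in times:
            f = np.zeros(shape)
            f[d == 1] = 1e8 * np.exp(-0.5 * ((t - 26.0) / 4.0) ** 2)
            f[d == 0] = 1e8 * np.exp(-0.5 * ((t - 32.0) / 8.0) ** 2)
            fields.append(f)
        df = timeseries_summary(fields, [groups] * len(times), times)
        assert df.attrs["peak_time_bulk"] == pytest.approx(26.0, abs=1.0)
        assert df.attrs["peak_time_rhizosphere"] == pytest.approx(32.0, abs=1.0)

    def test_peak_time_with_plateau_tolerance(self):
        times = np.arange(5)
        values = np.array([0.0, 9.8, 10.0, 9.9, 1.0])
        assert peak_time(times, values) == 2
        assert peak_time(times, values, plateau_tolerance=0.05) == 1
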