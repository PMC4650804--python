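"""Thickness, CSA, pore and surface-map measurements plus group statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from vesselseg import (
    PhantomSpec,
    PressureEffectSpec,
    Tomogram,
    axial_length_um,
    cross_sectional_area,
    luminal_surface_map,
    make_pressurised_pair,
    make_vessel_phantom,
    ray_thickness,
    segment_pores,
    summarize_groups,
    thickness_from_columns,
)


class TestThickness:
    def test_uniform_annulus_scales_exactly_to_microns(self):
        """12-voxel media at 0.75 um/vox is 9.0 um on every slice."""
        inner = np.full((3, 64), 8.0)
        boundary = inner + 12.0
        outer = boundary + 20.0
        df = thickness_from_columns(inner, boundary, outer, 0.75)
        assert np.allclose(df.media_thickness_um, 9.0)
        assert np.allclose(df.adventitia_thickness_um, 15.0)

    def test_missing_rows_excluded_not_zeroed(self):
        inner = np.full((1, 8), 2.0)
        boundary = inner + 10.0
        boundary[0, :4] = np.nan
        outer = boundary + 5.0
        df = thickness_from_columns(inner, boundary, outer, 1.0)
        assert df.media_thickness_um.iloc[0] == pytest.approx(10.0)

    def test_entirely_missing_slice_is_nan(self):
        inner = np.full((1, 4), 2.0)
        nanrow = np.full((1, 4), np.nan)
        df = thickness_from_columns(inner, nanrow, nanrow, 1.0)
        assert np.isnan(df.media_thickness_um.iloc[0])

    def test_ray_cast_thickness_recovers_eccentric_phantom(self):
        """Ray-cast measurement on ground-truth labels matches the known
        radial layer widths even when the centre drifts across slices."""
        spec = PhantomSpec(image_shape=(4, 256, 256), centre_offset=(0.6, 0.4),
                           ripple_amplitude_vox=0.0, waviness_amplitude_vox=0.0,
                           pore_count=0, noise_sd=0.0, seed=4)
        _, gt = make_vessel_phantom(spec)
        for z in range(4):
            df = ray_thickness(gt.labels[z], tuple(gt.centres[z]))
            assert df.media_thickness_vox.mean() == pytest.approx(
                spec.media_thickness_vox, abs=0.5
            )
            assert df.adventitia_thickness_vox.mean() == pytest.approx(
                spec.adventitia_thickness_vox, abs=0.5
            )


class TestCSA:
    def test_disk_lumen_area_matches_analytic(self, clean_circular_phantom):
        spec, (_, gt) = clean_circular_phantom
        df, meta = cross_sectional_area(gt.labels, spec.voxel_size_um)
        analytic = math.pi * spec.lumen_radius_vox**2 * spec.voxel_size_um**2
        band = 2 * math.pi * spec.lumen_radius_vox * spec.voxel_size_um**2
        assert abs(df.lumen_csa_um2.iloc[0] - analytic) <= band

    def test_conservation_of_slice_area(self, small_phantom):
        _, gt = small_phantom
        df, meta = cross_sectional_area(gt.labels, 0.75)
        total = (df.lumen_csa_um2 + df.media_csa_um2 + df.adventitia_csa_um2
                 + df.pore_csa_um2 + df.background_csa_um2)
        expected = gt.labels.shape[1] * gt.labels.shape[2] * 0.75**2
        assert np.allclose(total, expected)

    def test_empty_class_reports_zero(self):
        labels = np.zeros((2, 8, 8), dtype=np.uint8)
        df, _ = cross_sectional_area(labels, 1.0)
        assert (df.lumen_csa_um2 == 0).all()

    def test_axial_length_rounds_to_nearest_micron(self):
        assert axial_length_um(450, 0.75) == 338
        assert axial_length_um(100, 0.75) == 75


class TestPores:
    def test_noiseless_counts_and_volume(self):
        spec = PhantomSpec(image_shape=(32, 256, 256), noise_sd=0.0,
                           pore_count=10, seed=5)
        tom, gt = make_vessel_phantom(spec)
        ps = segment_pores(tom, gt.labels)
        assert ps.count == 10
        true_vol = gt.total_pore_volume_um3
        assert ps.total_volume_um3 == pytest.approx(true_vol, rel=0.15)

    def test_no_sub_paraffin_voxels_gives_zero_pores(self):
        spec = PhantomSpec(image_shape=(8, 256, 256), noise_sd=0.0,
                           pore_count=0, seed=5)
        tom, gt = make_vessel_phantom(spec)
        ps = segment_pores(tom, gt.labels)
        assert ps.count == 0 and ps.total_volume_um3 == 0.0

    def test_background_estimate_requires_background(self):
        spec = PhantomSpec(image_shape=(4, 256, 256), pore_count=0, seed=1)
        tom, gt = make_vessel_phantom(spec)
        labels = np.full_like(gt.labels, 2)  # no background voxels anywhere
        with pytest.raises(ValueError, match="background"):
            segment_pores(tom, labels)

    def test_pressurised_pore_volume_smaller(self):
        base = PhantomSpec(image_shape=(12, 256, 256), pore_count=10,
                           noise_sd=0.0, seed=6)
        (tu, gu), (tp, gp) = make_pressurised_pair(base, PressureEffectSpec())
        pu = segment_pores(tu, gu.labels)
        pp = segment_pores(tp, gp.labels)
        assert pp.total_volume_um3 < pu.total_volume_um3


class TestSurfaceMap:
    def test_perfect_cylinder_has_zero_roughness(self):
        sm = luminal_surface_map(np.full((4, 360), 40.0), voxel_size_um=0.75)
        assert sm.rms_roughness_um == pytest.approx(0.0, abs=1e-6)

    def test_sinusoidal_ripple_rms_is_amplitude_over_sqrt2(self):
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        a_vox = 3.0
        radius = 40.0 + a_vox * np.sin(4 * th)
        sm = luminal_surface_map(np.tile(radius, (6, 1)), voxel_size_um=0.75)
        assert sm.rms_roughness_um == pytest.approx(a_vox * 0.75 / math.sqrt(2), rel=0.02)

    def test_axial_ripple_orientation_shows_in_directional_variance(self):
        """A ripple oriented along the vessel axis varies around the
        circumference but not along the axis."""
        th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        radius = np.tile(40.0 + 2.0 * np.sin(5 * th), (8, 1))
        sm = luminal_surface_map(radius, voxel_size_um=1.0)
        assert sm.circumferential_variance > 100 * max(sm.axial_variance, 1e-12)

    def test_missing_slice_interpolated_but_long_gaps_rejected(self):
        radius = np.full((6, 90), 40.0)
        radius[2] = np.nan
        sm = luminal_surface_map(radius, voxel_size_um=1.0)
        assert np.isfinite(sm.radius_um).all()
        radius[2:6] = np.nan
        with pytest.raises(ValueError):
            luminal_surface_map(radius, voxel_size_um=1.0)

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError):
            luminal_surface_map(np.full((1, 90), 40.0), voxel_size_um=1.0)


class TestGroupSummary:
    def _table(self, rng, mean, sd, n=40):
        return pd.DataFrame({"slice": np.arange(n),
                             "media_thickness_um": rng.normal(mean, sd, n)})

    def test_null_groups_rarely_significant(self):
        """Same-distribution groups should give p > 0.05 in >= 90% of repeats."""
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            gs = summarize_groups(
                {"a": self._table(rng, 30.0, 1.0), "b": self._table(rng, 30.0, 1.0)}
            )
            if gs.tests.p.iloc[0] > 0.05:
                hits += 1
        assert hits >= 90

    def test_constant_shift_detected_exactly(self):
        rng = np.random.default_rng(0)
        a = self._table(rng, 30.0, 1e-9)
        b = a.copy()
        b["media_thickness_um"] += 5.0
        gs = summarize_groups({"a": a, "b": b})
        means = gs.per_group.set_index("group")["mean"]
        assert means["b"] - means["a"] == pytest.approx(5.0)
        assert gs.tests.p.iloc[0] < 1e-10

    def test_sem_is_sd_over_sqrt_n(self):
        rng = np.random.default_rng(1)
        a, b = self._table(rng, 30, 1.0), self._table(rng, 31, 1.0)
        gs = summarize_groups({"a": a, "b": b})
        row = gs.per_group.iloc[0]
        assert row["sem"] == pytest.approx(row["sd"] / math.sqrt(row["n"]))

    def test_single_slice_group_rejected(self):
        rng = np.random.default_rng(2)
        a = self._table(rng, 30, 1.0, n=1)
        b = self._table(rng, 30, 1.0, n=10)
        with pytest.raises(ValueError):
            summarize_groups({"a": a, "b": b})

    def test_autocorrelation_caveat_recorded(self):
        rng = np.random.default_rng(3)
        gs = summarize_groups({"a": self._table(rng, 30, 1), "b": self._table(rng, 30, 1)})
        assert "anti-conservative" in gs.notes
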