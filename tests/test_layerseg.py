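"""Texture filtering, edge modelling and geodesic boundary extraction."""

import itertools

import numpy as np
import pytest

from vesselseg import (
    EdgeProfile,
    SegmentConfig,
    WeightImage,
    WeightParams,
    build_weight_image,
    edge_profile,
    fit_edge_model,
    open_vertical,
    remove_islands,
    segment_volume,
    smooth_boundary_surface,
    threshold_wall,
    trace_geodesic_boundary,
)
from vesselseg.layerseg import WallMask


def otsu_oracle(img):
    """Exhaustive intra-class-variance minimiser over all candidate cuts."""
    vals = np.sort(np.unique(img.ravel()))
    best_t, best_v = None, np.inf
    for t in (vals[:-1] + vals[1:]) / 2.0:
        lo, hi = img[img < t], img[img >= t]
        v = len(lo) * lo.var() + len(hi) * hi.var()
        if v < best_v:
            best_v, best_t = v, t
    return best_t


class TestThresholdWall:
    def test_otsu_separates_two_level_image_like_oracle(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((64, 64)) < 0.5, 40.0, 200.0)
        wm = threshold_wall(img, "otsu")
        assert 40.0 < wm.threshold <= 200.0
        oracle_mask = img >= otsu_oracle(img)
        np.testing.assert_array_equal(wm.mask, oracle_mask)

    def test_fixed_threshold_matches_otsu_decision_on_two_levels(self):
        img = np.tile([40.0, 200.0], (8, 8))
        np.testing.assert_array_equal(
            threshold_wall(img, "fixed", 100.0).mask, threshold_wall(img, "otsu").mask
        )

    def test_constant_image_has_no_bimodality(self):
        with pytest.raises(ValueError, match="bimodality"):
            threshold_wall(np.full((8, 8), 7.0), "otsu")

    def test_fixed_without_value_rejected(self):
        with pytest.raises(ValueError):
            threshold_wall(np.zeros((4, 4)), "fixed")


def roll_opening_oracle(mask, length):
    """Erosion/dilation as min/max over circularly shifted copies."""
    h = length // 2
    shifts = [np.roll(mask, k, axis=0) for k in range(-h, h + 1)]
    eroded = np.logical_and.reduce(shifts)
    shifts = [np.roll(eroded, k, axis=0) for k in range(-h, h + 1)]
    return np.logical_or.reduce(shifts)


class TestOpening:
    def test_full_height_vertical_bar_is_preserved(self):
        m = np.zeros((32, 16), dtype=bool)
        m[:, 5] = True
        out = open_vertical(m, 9)
        np.testing.assert_array_equal(out.mask, m)

    def test_thin_horizontal_bar_is_removed(self):
        m = np.zeros((32, 16), dtype=bool)
        m[10, 2:14] = True
        assert not open_vertical(m, 9).mask.any()

    def test_matches_shift_composition_oracle_bitwise(self):
        rng = np.random.default_rng(3)
        m = rng.random((40, 24)) < 0.45
        out = open_vertical(m, 7)
        np.testing.assert_array_equal(out.mask, roll_opening_oracle(m, 7))

    def test_anti_extensive(self):
        rng = np.random.default_rng(4)
        m = rng.random((30, 20)) < 0.6
        assert not (open_vertical(m, 5).mask & ~m).any()

    def test_even_length_rejected(self):
        with pytest.raises(ValueError):
            open_vertical(np.zeros((8, 8), dtype=bool), 4)


def flood_fill_oracle(mask, min_size):
    """Naive BFS 8-connected component filter."""
    out = np.zeros_like(mask)
    seen = np.zeros_like(mask)
    for i, j in zip(*np.nonzero(mask)):
        if seen[i, j]:
            continue
        stack, comp = [(i, j)], []
        seen[i, j] = True
        while stack:
            a, b = stack.pop()
            comp.append((a, b))
            for da in (-1, 0, 1):
                for db in (-1, 0, 1):
                    x, y = a + da, b + db
                    if (0 <= x < mask.shape[0] and 0 <= y < mask.shape[1]
                            and mask[x, y] and not seen[x, y]):
                        seen[x, y] = True
                        stack.append((x, y))
        if len(comp) >= min_size:
            for a, b in comp:
                out[a, b] = True
    return out


class TestIslandRemoval:
    def test_blob_below_minimum_removed(self):
        m = np.zeros((16, 16), dtype=bool)
        m[3, 3:6] = True
        assert not remove_islands(m, 5).mask.any()

    def test_blob_of_exactly_minimum_size_kept(self):
        m = np.zeros((16, 16), dtype=bool)
        m[3, 3:8] = True
        np.testing.assert_array_equal(remove_islands(m, 5).mask, m)

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(8)
        m = rng.random((48, 32)) < 0.35
        out = remove_islands(m, 6)
        np.testing.assert_array_equal(out.mask, flood_fill_oracle(m, 6))

    def test_anti_extensive(self):
        rng = np.random.default_rng(9)
        m = rng.random((30, 20)) < 0.5
        assert not (remove_islands(m, 4).mask & ~m).any()


class TestEdgeProfile:
    def test_full_width_rows_give_last_column(self):
        m = np.ones((10, 12), dtype=bool)
        prof = edge_profile(m)
        assert (prof.xe == 11).all() and not prof.missing.any()

    def test_staircase_matches_naive_scan(self):
        rng = np.random.default_rng(11)
        m = rng.random((20, 15)) < 0.4
        m[:, 0] = True  # avoid empty rows
        prof = edge_profile(m)
        for r in range(20):
            expect = max(c for c in range(15) if m[r, c])
            assert prof.xe[r] == expect

    def test_empty_row_is_flagged_others_unaffected(self):
        m = np.ones((5, 8), dtype=bool)
        m[2] = False
        prof = edge_profile(m)
        assert prof.missing[2] and not prof.missing[[0, 1, 3, 4]].any()
        assert (prof.xe[[0, 1, 3, 4]] == 7).all()

    def test_all_rows_empty_is_an_error(self):
        with pytest.raises(ValueError, match="wall lost"):
            edge_profile(np.zeros((4, 4), dtype=bool))


class TestEdgeModel:
    def test_point_mass_gives_exact_dominant_mean(self):
        prof = EdgeProfile(xe=np.full(20, 30), missing=np.zeros(20, dtype=bool))
        model = fit_edge_model(prof, 2)
        assert model.dominant_mean == pytest.approx(31.0, abs=1e-6)

    def test_two_cluster_mixture_identifies_majority_cluster(self):
        rng = np.random.default_rng(12)
        xe = np.concatenate([
            np.round(rng.normal(30, 0.8, 90)), np.round(rng.normal(60, 0.8, 10))
        ]).astype(int)
        prof = EdgeProfile(xe=xe, missing=np.zeros(100, dtype=bool))
        model = fit_edge_model(prof, 2)
        assert model.dominant_mean == pytest.approx(31.0, abs=1.0)

    def test_single_component_is_sample_mean(self):
        rng = np.random.default_rng(13)
        xe = rng.integers(20, 40, 50)
        prof = EdgeProfile(xe=xe, missing=np.zeros(50, dtype=bool))
        model = fit_edge_model(prof, 1)
        assert model.dominant_mean == pytest.approx(np.mean(xe + 1.0), abs=1e-9)

    def test_too_few_rows_rejected(self):
        prof = EdgeProfile(xe=np.arange(5), missing=np.zeros(5, dtype=bool))
        with pytest.raises(ValueError):
            fit_edge_model(prof, 2)


class TestWeightImage:
    def _profile(self, xe):
        xe = np.asarray(xe)
        return EdgeProfile(xe=xe, missing=xe < 0)

    def test_empty_mask_no_edges_gives_uniform_base(self):
        mask = WallMask(np.zeros((4, 10), dtype=bool), 0.0)
        prof = self._profile([-1, -1, -1, -1])
        model = fit_edge_model(self._profile(np.full(20, 5)), 1)
        wi = build_weight_image(mask, model, prof)
        np.testing.assert_allclose(wi.values, 1.0)

    def test_single_qualifying_row_gets_single_bonus(self):
        mask = WallMask(np.zeros((12, 10), dtype=bool), 0.0)
        xe = np.full(12, -1)
        xe[4] = 5
        prof = self._profile(xe)
        model = fit_edge_model(self._profile(np.full(20, 5)), 1)  # mean 6
        wi = build_weight_image(mask, model, prof)
        assert wi.values[4, 6] == pytest.approx(3.0)
        assert (wi.values == 3.0).sum() == 1

    def test_penalty_then_bonus_precedence(self):
        m = np.zeros((12, 10), dtype=bool)
        m[4, 6] = True  # candidate pixel also inside the initial mask
        xe = np.full(12, -1)
        xe[4] = 5
        prof = self._profile(xe)
        model = fit_edge_model(self._profile(np.full(20, 5)), 1)
        wi = build_weight_image(WallMask(m, 0.0), model, prof)
        assert wi.values[4, 6] == pytest.approx(1.0 - 0.5 + 2.0)


def enumerate_paths_cost(W, lam, dmax):
    """Brute-force minimum over all feasible column sequences."""
    n_rows, n_cols = W.shape
    cost = W.max() - W
    best = np.inf
    for start in range(n_cols):
        for deltas in itertools.product(range(-dmax, dmax + 1), repeat=n_rows - 1):
            c = start
            total = cost[0, c]
            ok = True
            for r, d in enumerate(deltas, start=1):
                c += d
                if not 0 <= c < n_cols:
                    ok = False
                    break
                total += cost[r, c] + lam * abs(d)
            if ok:
                total += lam * abs(c - start)
                if total < best:
                    best = total
    return best


class TestGeodesic:
    def test_uniform_weights_return_leftmost_vertical_path(self):
        wi = WeightImage(np.ones((8, 6)), WeightParams())
        path = trace_geodesic_boundary(wi)
        assert (path.columns == 0).all()

    def test_path_follows_high_weight_ridge(self):
        W = np.ones((10, 12))
        W[:, 7] = 5.0
        wi = WeightImage(W, WeightParams(deviation_penalty=0.01))
        path = trace_geodesic_boundary(wi)
        assert (path.columns == 7).all()

    def test_cost_matches_exhaustive_enumeration_on_small_instances(self):
        rng = np.random.default_rng(17)
        params = WeightParams(deviation_penalty=0.25, max_step=1)
        for _ in range(20):
            W = rng.random((6, 5)) * 3.0
            wi = WeightImage(W, params)
            path = trace_geodesic_boundary(wi)
            assert path.cost == pytest.approx(
                enumerate_paths_cost(W, 0.25, 1), abs=1e-9
            )

    def test_larger_deviation_penalty_never_increases_total_deviation(self):
        rng = np.random.default_rng(18)
        for _ in range(10):
            W = rng.random((12, 8)) * 4.0
            devs = []
            for lam in (0.05, 0.5, 2.0):
                wi = WeightImage(W, WeightParams(deviation_penalty=lam, max_step=2))
                p = trace_geodesic_boundary(wi).columns
                devs.append(np.abs(np.diff(p)).sum())
            assert devs[0] >= devs[1] >= devs[2]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            trace_geodesic_boundary(WeightImage(np.ones((1, 5)), WeightParams()))


class TestSurfaceSmoothing:
    def test_constant_surface_unchanged(self):
        surf = np.full((5, 64), 12.0)
        np.testing.assert_allclose(smooth_boundary_surface(surf), surf, atol=1e-9)

    def test_spike_is_contracted(self):
        surf = np.full((5, 64), 10.0)
        surf[2, 30] += 10.0
        out = smooth_boundary_surface(surf)
        assert 0 < out[2, 30] - 10.0 < 10.0

    def test_sinusoid_attenuation_matches_kernel_frequency_response(self):
        """Attenuation of a pure row-frequency mode equals the DFT of the
        discrete Gaussian kernel at that frequency (separable smoothing)."""
        n, k, sigma = 256, 8, 3.0
        rows = np.arange(n)
        surf = np.tile(np.sin(2 * np.pi * k * rows / n), (3, 1))
        out = smooth_boundary_surface(surf, sigma_rows=sigma, sigma_slices=0.0)
        gain = np.ptp(out[1]) / np.ptp(surf[1])
        # oracle: frequency response of the same discrete truncated kernel
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        kern = np.exp(-x**2 / (2 * sigma**2))
        kern /= kern.sum()
        expected = np.abs(np.sum(kern * np.exp(-2j * np.pi * k * x / n)))
        assert gain == pytest.approx(expected, rel=0.05)


class TestSegmentVolume:
    def test_noiseless_phantom_recovers_layers(self, clean_circular_phantom):
        """Media and adventitia Dice vs ground truth on a clean phantom."""
        _, (tom, gt) = clean_circular_phantom
        seg = segment_volume(tom)
        assert len(seg.records) == tom.values.shape[0]
        assert not seg.flagged_slices
        pred, true = seg.labels, gt.labels
        true_adv = (true == 3) | (true == 4)
        dice_media = 2 * ((pred == 2) & (true == 2)).sum() / ((pred == 2).sum() + (true == 2).sum())
        dice_adv = 2 * ((pred == 3) & true_adv).sum() / ((pred == 3).sum() + true_adv.sum())
        assert dice_media >= 0.98
        assert dice_adv >= 0.98

    def test_one_contour_record_per_slice(self, small_phantom):
        tom, _ = small_phantom
        seg = segment_volume(tom)
        assert len(seg.records) == tom.values.shape[0]
        assert seg.boundary_cols.shape[0] == tom.values.shape[0]

    def test_invalid_config_rejected(self):
        cfg = SegmentConfig(deviation_penalty=-1.0)
        with pytest.raises(ValueError):
            cfg.validate()
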