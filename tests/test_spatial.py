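import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xyspot import (
    EmptyFieldError,
    GeometryError,
    KernelSpec,
    ParameterError,
    SceneConfig,
    density_map,
    dorsoventral_partition,
    flag_pixels,
    generate_scene,
    permutation_null,
    purity_field,
    purity_histogram,
    region_ratio,
    welch_one_tailed,
)


def spot_frame(points, gene="X"):
    return pd.DataFrame(
        [{"row": r, "col": c, "gene": gene, "cell_id": -1} for r, c in points],
        columns=["row", "col", "gene", "cell_id"],
    )


class TestKernel:
    def test_even_window_made_odd(self):
        assert KernelSpec(window=150, sd=25.0).window == 151

    def test_unit_mass_when_normalized(self):
        k = KernelSpec(window=31, sd=5.0, normalized=True).array()
        assert k.sum() == pytest.approx(1.0, abs=1e-12)
        assert k[15, 15] == k.max()

    def test_invalid_sd_rejected(self):
        with pytest.raises(ParameterError):
            KernelSpec(window=31, sd=0.0)


class TestDensityMap:
    def test_single_interior_spot_mass_and_peak(self):
        spots = spot_frame([(100, 120)])
        field = density_map(spots, (256, 256), KernelSpec(window=51, sd=8.0))
        d = field["X"]
        assert np.unravel_index(np.argmax(d), d.shape) == (100, 120)
        assert d.sum() == pytest.approx(1.0, abs=1e-9)

    def test_linearity_in_the_spot_set(self):
        rng = np.random.default_rng(3)
        pts_a = list(zip(rng.integers(20, 100, 30), rng.integers(20, 100, 30)))
        pts_b = list(zip(rng.integers(20, 100, 20), rng.integers(20, 100, 20)))
        kernel = KernelSpec(window=31, sd=6.0)
        da = density_map(spot_frame(pts_a), (128, 128), kernel)["X"]
        db = density_map(spot_frame(pts_b), (128, 128), kernel)["X"]
        dab = density_map(spot_frame(pts_a + pts_b), (128, 128), kernel)["X"]
        assert np.allclose(dab, da + db, atol=1e-12)

    def test_empty_spot_set_gives_zero_map(self):
        field = density_map(spot_frame([]), (64, 64), KernelSpec(window=31, sd=6.0),
                            genes=["X"])
        assert np.all(field["X"] == 0)

    def test_out_of_shape_spot_rejected(self):
        with pytest.raises(ParameterError):
            density_map(spot_frame([(70, 10)]), (64, 64), KernelSpec(window=31, sd=6.0))


class TestPurity:
    def test_balanced_densities_give_half(self):
        x = np.full((16, 16), 2.0)
        field = purity_field(x, x, eps=1e-6)
        assert np.allclose(field.purity, 0.5)

    def test_pure_y_gives_one(self):
        x = np.zeros((8, 8))
        y = np.full((8, 8), 1.0)
        assert np.allclose(purity_field(x, y, eps=1e-3).purity, 1.0)

    def test_four_to_one_ratio_is_y_dominant_at_cutoff(self):
        x = np.full((10, 10), 1.0)
        field = purity_field(x, 4.0 * x, eps=1e-6)
        assert np.allclose(field.purity, 0.8)
        hist = purity_histogram(field, n_bins=50, cutoff=0.8)
        assert hist.proportions["y_dominant"] == 1.0

    def test_negative_density_rejected(self):
        with pytest.raises(ParameterError):
            purity_field(np.full((4, 4), -1.0), np.ones((4, 4)))

    def test_low_total_pixels_masked(self):
        x = np.zeros((4, 4))
        x[0, 0] = 1.0
        field = purity_field(x, np.zeros((4, 4)), eps=0.5)
        assert np.isfinite(field.purity).sum() == 1


class TestPurityHistogram:
    def make_field(self, values):
        return purity_field(1.0 - np.asarray(values), np.asarray(values), eps=1e-9)

    def test_uniform_half_field_all_in_central_bin(self):
        field = self.make_field(np.full((20, 20), 0.5))
        hist = purity_histogram(field, n_bins=50)
        assert hist.frequencies[25] == 400
        assert hist.frequencies.sum() == 400
        assert hist.proportions == {"x_dominant": 0.0, "mixed": 1.0, "y_dominant": 0.0}

    def test_constructed_mixture_proportions(self):
        vals = np.full(1000, 0.5)
        vals[:300] = 0.9
        field = self.make_field(vals.reshape(25, 40))
        hist = purity_histogram(field, n_bins=50, cutoff=0.8)
        assert hist.proportions["y_dominant"] == pytest.approx(0.30)
        assert sum(hist.proportions.values()) == pytest.approx(1.0)

    def test_raising_cutoff_never_increases_dominance(self):
        rng = np.random.default_rng(5)
        field = self.make_field(rng.random((30, 30)))
        last_x, last_y = 1.0, 1.0
        for cutoff in (0.6, 0.7, 0.8, 0.9, 0.99):
            hist = purity_histogram(field, cutoff=cutoff)
            assert hist.proportions["x_dominant"] <= last_x + 1e-12
            assert hist.proportions["y_dominant"] <= last_y + 1e-12
            last_x = hist.proportions["x_dominant"]
            last_y = hist.proportions["y_dominant"]

    def test_fully_masked_field_raises(self):
        field = purity_field(np.zeros((4, 4)), np.zeros((4, 4)), eps=1.0)
        with pytest.raises(EmptyFieldError):
            purity_histogram(field)


class TestPermutationNull:
    def make_spots(self, n=120, seed=0, p_y=0.5):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "row": rng.integers(10, 118, n),
            "col": rng.integers(10, 118, n),
            "gene": np.where(rng.random(n) < p_y, "Y", "X"),
            "cell_id": -1,
        })

    KERNEL = KernelSpec(window=41, sd=8.0)

    def test_single_label_degenerates_to_zero_sd_no_flags(self):
        spots = self.make_spots(p_y=0.0)
        summary = permutation_null(spots, (128, 128), self.KERNEL, n_rand=10, seed=1)
        assert np.all(summary.rand_sd == 0)
        assert np.all(summary.flags == 0)
        assert summary.observed_props["x_dominant"] == 1.0

    def test_seeded_determinism(self):
        spots = self.make_spots(seed=2)
        a = permutation_null(spots, (128, 128), self.KERNEL, n_rand=20, seed=7)
        b = permutation_null(spots, (128, 128), self.KERNEL, n_rand=20, seed=7)
        assert np.array_equal(a.rand_mean, b.rand_mean)
        assert np.array_equal(a.flags, b.flags)
        assert a.observed_props == b.observed_props
        assert a.ci_low == b.ci_low and a.ci_high == b.ci_high

    def test_label_counts_preserved(self):
        spots = self.make_spots(seed=3, p_y=0.3)
        summary = permutation_null(spots, (128, 128), self.KERNEL, n_rand=5, seed=1)
        assert summary.label_counts["X"] + summary.label_counts["Y"] == len(spots)
        assert summary.label_counts["Y"] == int((spots["gene"] == "Y").sum())

    def test_too_few_randomizations_rejected(self):
        with pytest.raises(ParameterError):
            permutation_null(self.make_spots(), (128, 128), self.KERNEL, n_rand=1)

    def test_empty_spot_set_rejected(self):
        with pytest.raises(ParameterError):
            permutation_null(self.make_spots(0), (128, 128), self.KERNEL, n_rand=10)


class TestFlagPixels:
    def test_no_flags_gives_empty_map(self):
        field = purity_field(np.ones((8, 8)), np.ones((8, 8)), eps=1e-6)
        edges = np.linspace(0, 1, 51)
        assert not flag_pixels(field, edges, np.zeros(50, dtype=np.int8)).any()

    def test_single_flagged_bin_selects_exact_pixels(self):
        vals = np.linspace(0.0, 1.0, 100).reshape(10, 10)
        field = purity_field(1 - vals, vals, eps=1e-9)
        edges = np.linspace(0, 1, 21)
        flags = np.zeros(20, dtype=np.int8)
        flags[18] = 1  # bin [0.90, 0.95)
        marked = flag_pixels(field, edges, flags)
        expected = (field.purity >= 0.90) & (field.purity < 0.95)
        assert np.array_equal(marked, expected)

    def test_flagged_pixel_count_equals_flagged_bin_frequencies(self):
        rng = np.random.default_rng(8)
        vals = rng.random((40, 40))
        field = purity_field(1 - vals, vals, eps=1e-9)
        hist = purity_histogram(field, n_bins=25)
        flags = np.zeros(25, dtype=np.int8)
        flags[[3, 11, 24]] = 1
        marked = flag_pixels(field, hist.bin_edges, flags)
        assert marked.sum() == hist.frequencies[[3, 11, 24]].sum()


class TestDorsoventralPartition:
    def test_symmetric_landmarks_split_rectangle_evenly(self):
        mask = np.ones((100, 60), dtype=bool)
        part = dorsoventral_partition(mask, [(20, 10), (80, 10)], [(20, 50), (80, 50)])
        dorsal = (part.region == 1).sum()
        ventral = (part.region == 2).sum()
        assert abs(dorsal - ventral) <= mask.shape[1]  # at most the border row
        assert dorsal + ventral == mask.size

    def test_pixel_above_border_is_dorsal_on_border_ventral(self):
        mask = np.ones((40, 40), dtype=bool)
        part = dorsoventral_partition(mask, [(10, 5), (30, 5)], [(10, 35), (30, 35)])
        assert part.region[19, 20] == 1
        assert part.region[20, 20] == 2

    def test_matches_per_pixel_line_side_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            mask = rng.random((30, 30)) > 0.3
            mask[10:20, 4:26] = True  # ensure landmarks are inside
            part = dorsoventral_partition(mask, [(11, 5), (19, 5)], [(12, 25), (18, 25)])
            ml = np.array([15.0, 5.0])
            mr = np.array([15.0, 25.0])
            slope = (mr[0] - ml[0]) / (mr[1] - ml[1])
            for r in range(30):
                for c in range(30):
                    if not mask[r, c]:
                        assert part.region[r, c] == 0
                    else:
                        border = ml[0] + slope * (c - ml[1])
                        assert part.region[r, c] == (1 if r < border else 2)

    def test_degenerate_landmarks_rejected(self):
        mask = np.ones((20, 20), dtype=bool)
        with pytest.raises(GeometryError):
            dorsoventral_partition(mask, [(5, 5), (5, 5)], [(5, 15), (15, 15)])
        with pytest.raises(GeometryError):
            dorsoventral_partition(mask, [(25, 5), (15, 5)], [(5, 15), (15, 15)])


class TestRegionRatio:
    def make_partition(self):
        mask = np.ones((100, 100), dtype=bool)
        return dorsoventral_partition(mask, [(10, 10), (90, 10)], [(10, 90), (90, 90)])

    def test_counts_and_ratios(self):
        part = self.make_partition()
        spots = pd.concat([
            spot_frame([(10, 50)] * 10, "X"), spot_frame([(10, 50)] * 5, "Y"),
            spot_frame([(90, 50)] * 20, "X"), spot_frame([(90, 50)] * 5, "Y"),
        ], ignore_index=True)
        ratios = region_ratio(spots, part, "X", "Y")
        assert ratios["dorsal"]["ratio"] == pytest.approx(2.0)
        assert ratios["ventral"]["ratio"] == pytest.approx(4.0)

    def test_zero_y_flagged_as_nan(self):
        part = self.make_partition()
        spots = spot_frame([(10, 50), (90, 50)], "X")
        spots = pd.concat([spots, spot_frame([(90, 51)], "Y")], ignore_index=True)
        ratios = region_ratio(spots, part, "X", "Y")
        assert np.isnan(ratios["dorsal"]["ratio"])
        assert ratios["ventral"]["ratio"] == pytest.approx(1.0)

    def test_enriched_scenes_have_higher_ventral_ratio(self):
        diffs = []
        for seed in range(20):
            cfg = SceneConfig(image_height=256, image_width=256, n_cells=400,
                              min_nucleus_separation=6.0, ventral_x_enrichment=3.0,
                              seed=600 + seed)
            scene = generate_scene(cfg)
            border = scene.ventral_border_row()
            mask = scene.tissue_mask
            rows = np.nonzero(mask.any(axis=1))[0]
            mid = int(border)
            cols = np.nonzero(mask[mid])[0]
            part = dorsoventral_partition(
                mask,
                [(mid - 20, cols[5]), (mid + 20, cols[5])],
                [(mid - 20, cols[-6]), (mid + 20, cols[-6])],
            )
            ratios = region_ratio(scene.true_spots, part, "X", "Y")
            if np.isnan(ratios["dorsal"]["ratio"]) or np.isnan(ratios["ventral"]["ratio"]):
                continue
            diffs.append(ratios["ventral"]["ratio"] - ratios["dorsal"]["ratio"])
        assert len(diffs) >= 15
        assert np.mean(diffs) > 0


class TestWelch:
    def test_identical_groups_give_half_p(self):
        res = welch_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "a_greater")
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(0.5)

    def test_zero_variance_is_degenerate(self):
        res = welch_one_tailed([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], "a_greater")
        assert res.degenerate
        assert res.p == 0.5
        res2 = welch_one_tailed([3.0, 3.0], [2.0, 2.0], "a_greater")
        assert res2.degenerate and res2.p == 0.0

    def test_matches_scipy_oracle(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        res = welch_one_tailed(a, b, "b_greater")
        ref = stats.ttest_ind(b, a, equal_var=False, alternative="greater")
        assert res.p == pytest.approx(ref.pvalue, abs=1e-6)
        assert res.t == pytest.approx(ref.statistic, abs=1e-9)
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.5, 2, rng.integers(3, 12))
            res = welch_one_tailed(a, b, "a_greater")
            ref = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
            assert res.p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            welch_one_tailed([1.0], [1.0, 2.0], "a_greater")
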