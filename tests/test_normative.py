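"""KDE normative percentiles, ROI censoring and deviation-map logic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import gaussian_kde, norm

from smas.normative import (Category, DeviationMap, NormativeModel, censor_roi,
                            classify_cell, classify_cells, combine_maps,
                            fit_kde_percentiles, fit_normative_model,
                            median_onh_distance, proportion_abnormal,
                            surrogate_fp_rate)


class TestKdePercentiles:
    def test_constant_data(self):
        p = fit_kde_percentiles(np.full(10, 0.42))
        assert np.allclose(p, 0.42)

    def test_standard_normal_calibration(self):
        draws = np.random.default_rng(42).standard_normal(10_000)
        p = fit_kde_percentiles(draws, levels=(1, 5, 10), bounds=None)
        for got, expected in zip(p, (-2.326, -1.645, -1.282)):
            assert got == pytest.approx(expected, abs=0.1)

    @given(st.integers(0, 5000))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_level(self, seed):
        x = np.random.default_rng(seed).random(15)
        p1, p5, p10, p50 = fit_kde_percentiles(x)
        assert p1 <= p5 <= p10 <= p50

    def test_matches_scipy_kde_cdf(self, rng):
        # independent oracle: scipy's Gaussian KDE with the Silverman rule
        # must assign CDF ~= level/100 at our estimated percentile
        x = rng.normal(0.5, 0.1, 40)
        kde = gaussian_kde(x, bw_method="silverman")
        p = fit_kde_percentiles(x, levels=(1, 5, 10, 50), bounds=None)
        for level, q in zip((1, 5, 10, 50), p):
            cdf = kde.integrate_box_1d(-np.inf, q)
            assert cdf == pytest.approx(level / 100.0, abs=0.01)

    def test_truncation_keeps_percentiles_in_bounds(self, rng):
        x = np.clip(rng.normal(0.05, 0.1, 50), 0, 1)
        p = fit_kde_percentiles(x, bounds=(0.0, 1.0))
        assert np.all(p >= 0.0) and np.all(p <= 1.0)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            fit_kde_percentiles(np.array([0.1, 0.2, np.nan, np.nan, 0.3]))


class TestCensorRoi:
    def test_hand_computed_threshold(self):
        means = np.array([0.9] * 9 + [0.05])
        roi, t = censor_roi(means)
        assert t == pytest.approx(0.143, abs=0.001)
        assert roi.sum() == 9 and not roi[-1]

    def test_all_equal_keeps_all(self):
        roi, t = censor_roi(np.full(12, 0.7))
        assert roi.all()

    @given(st.floats(0.5, 5.0), st.floats(0.0, 3.0))
    @settings(max_examples=30, deadline=None)
    def test_larger_cutoff_never_excludes_more(self, cutoff, extra):
        means = np.random.default_rng(7).random(30)
        roi_small, _ = censor_roi(means, cutoff=cutoff)
        roi_large, _ = censor_roi(means, cutoff=cutoff + extra)
        assert np.all(roi_large >= roi_small)


class TestClassification:
    PCT = np.array([0.2, 0.3, 0.4, 0.6])  # p1, p5, p10, p50

    @pytest.mark.parametrize("value, in_roi, expected", [
        (0.1, True, Category.BELOW1),
        (0.25, True, Category.BELOW5),
        (0.35, True, Category.BELOW10),
        (0.6, True, Category.WNL),      # exactly the median
        (0.9, True, Category.WNL),
        (0.05, False, Category.UNTESTED),
        (np.nan, True, Category.UNTESTED),
    ])
    def test_categories(self, value, in_roi, expected):
        assert classify_cell(value, self.PCT, in_roi) == expected

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_lowering_never_moves_toward_wnl(self, seed):
        r = np.random.default_rng(seed)
        value = r.random()
        lower = value - r.random() * 0.5
        order = [Category.WNL, Category.BELOW10, Category.BELOW5, Category.BELOW1]
        a = classify_cell(value, self.PCT, True)
        b = classify_cell(lower, self.PCT, True)
        assert order.index(b) >= order.index(a)


def make_map(categories, slab=1, onh=(2, 5)):
    return DeviationMap(categories=np.asarray(categories, dtype=np.int8),
                        slab_index=slab, onh_cell=onh)


class TestCombineAndMetrics:
    def test_abnormal_at_any_depth(self):
        base = np.full((3, 4), int(Category.WNL), dtype=np.int8)
        m1 = make_map(base.copy())
        m2 = make_map(base.copy(), slab=2)
        m2.categories[1, 1] = int(Category.BELOW1)
        combined = combine_maps([m1, m2])
        assert combined.abnormal[1, 1]
        assert combined.abnormal.sum() == 1
        assert combined.tested.all()

    def test_untested_everywhere(self):
        maps = [make_map(np.zeros((2, 2)), slab=k) for k in (1, 2)]
        combined = combine_maps(maps)
        assert not combined.tested.any() and not combined.abnormal.any()

    def test_grid_mismatch(self):
        with pytest.raises(ValueError):
            combine_maps([make_map(np.zeros((2, 2))), make_map(np.zeros((3, 3)))])

    def test_combined_count_dominates_single_slabs(self, rng):
        maps = [make_map(rng.integers(0, 5, (6, 6)), slab=k) for k in range(1, 8)]
        combined = combine_maps(maps)
        for m in maps:
            assert combined.abnormal.sum() >= (m.categories == 4).sum()

    def test_proportion(self):
        cats = np.full((20, 30), int(Category.WNL), dtype=np.int8)
        cats[0, :15] = int(Category.BELOW1)
        assert proportion_abnormal(make_map(cats)) == pytest.approx(15 / 600)

    def test_proportion_matches_recount_oracle(self, rng):
        cats = rng.integers(0, 5, (10, 12)).astype(np.int8)
        abnormal = sum(1 for v in cats.ravel() if v == int(Category.BELOW1))
        tested = sum(1 for v in cats.ravel() if v != int(Category.UNTESTED))
        if tested == 0:
            return
        assert proportion_abnormal(make_map(cats)) == pytest.approx(abnormal / tested)

    def test_no_tested_cells_rejected(self):
        with pytest.raises(ValueError):
            proportion_abnormal(make_map(np.zeros((2, 2))))

    def test_median_distance(self):
        cats = np.full((10, 10), int(Category.WNL), dtype=np.int8)
        onh = (0, 0)
        for c in (3, 5, 9):
            cats[0, c] = int(Category.BELOW1)
        assert median_onh_distance(make_map(cats, onh=onh)) == 5.0

    def test_median_distance_matches_sorted_oracle(self, rng):
        cats = rng.integers(0, 5, (8, 9)).astype(np.int8)
        onh = (4, 4)
        dm = make_map(cats, onh=onh)
        dists = sorted(np.hypot(r - 4, c - 4)
                       for r, c in zip(*np.nonzero(cats == 4)))
        if not dists:
            assert np.isnan(median_onh_distance(dm))
        else:
            assert median_onh_distance(dm) == pytest.approx(np.median(dists))

    def test_no_abnormal_is_nan(self):
        cats = np.full((3, 3), int(Category.WNL), dtype=np.int8)
        assert np.isnan(median_onh_distance(make_map(cats)))


class TestNormativeModelFit:
    def _fit(self, rng, n_controls=8):
        vals = rng.normal(0.8, 0.05, size=(n_controls, 2, 5, 6))
        return fit_normative_model(vals, "Hood", onh_cell=(2, 4)), vals

    def test_percentiles_monotone_in_roi(self, rng):
        model, _ = self._fit(rng)
        p = model.percentiles[model.roi]
        assert np.all(np.diff(p, axis=-1) >= 0)

    def test_training_values_not_below_p1(self, rng):
        model, vals = self._fit(rng)
        fp = surrogate_fp_rate(vals, model)
        assert fp == 0.0

    def test_sentinel_limits_give_zero_rate(self, rng):
        model, vals = self._fit(rng)
        model.percentiles[..., 0] = -np.inf
        assert surrogate_fp_rate(vals, model) == 0.0

    def test_save_load_round_trip(self, rng, tmp_path):
        model, vals = self._fit(rng)
        path = tmp_path / "model.zip"
        model.save(path)
        loaded = NormativeModel.load(path)
        assert loaded.scheme == model.scheme
        assert np.array_equal(loaded.roi, model.roi)
        assert np.allclose(loaded.percentiles, model.percentiles, equal_nan=True)
        a = model.classify(vals[0])
        b = loaded.classify(vals[0])
        assert all(np.array_equal(x.categories, y.categories) for x, y in zip(a, b))

    def test_sparse_cells_left_untested(self, rng):
        vals = rng.normal(0.8, 0.05, size=(8, 1, 4, 4))
        vals[2:, 0, 0, 0] = np.nan      # only 2 observations at this cell
        model = fit_normative_model(vals, "Hood", onh_cell=(0, 3))
        assert not model.roi[0, 0, 0]
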