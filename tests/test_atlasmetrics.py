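"""Normalization/thresholding, atlas metrics, maximal maps, Welch tests."""

import math

import numpy as np
import pytest
from scipy import stats

from netdisrupt import atlasmetrics as am
from netdisrupt.decompose import SpatialMapSet


def _mapset(rows, method="sdl"):
    return SpatialMapSet(maps=np.asarray(rows, dtype=float), method=method)


class TestNormalizeAndThreshold:
    def test_positive_tail_survives_unit_z(self):
        out = am.normalize_and_threshold(_mapset([[1, 2, 3, 4, 5]]),
                                         group_max=1.0, z_cut=1.0)
        # population sd sqrt(2): z(5) = 2/sqrt(2) ~ 1.414 survives,
        # z(4) = 1/sqrt(2) ~ 0.707 does not
        assert np.array_equal(out.maps[0], [0, 0, 0, 0, 5])
        assert out.state == "thresholded"
        z5 = (5 - 3) / np.std([1, 2, 3, 4, 5])
        assert z5 == pytest.approx(math.sqrt(2))

    def test_constant_map_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = am.normalize_and_threshold(_mapset([[2, 2, 2]]), 1.0)
        assert not out.maps.any()

    def test_group_max_rescales_but_does_not_change_survivors(self):
        a = am.normalize_and_threshold(_mapset([[1, 2, 3, 4, 5]]), 1.0)
        b = am.normalize_and_threshold(_mapset([[1, 2, 3, 4, 5]]), 2.0)
        assert np.array_equal(a.maps != 0, b.maps != 0)
        nz = a.maps != 0
        assert np.allclose(b.maps[nz], a.maps[nz] / 2.0)

    def test_nonpositive_group_max_rejected(self):
        with pytest.raises(ValueError):
            am.normalize_and_threshold(_mapset([[1, 2]]), 0.0)


class TestPearson:
    def test_indicator_extremes(self):
        ind = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        assert am.pearson_to_atlas(ind.astype(float), ind) == pytest.approx(1)
        assert am.pearson_to_atlas(1.0 - ind, ind) == pytest.approx(-1)
        assert am.pearson_to_atlas(np.array([2., 2, 2, 0, 0, 0]), ind) == \
            pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        ind = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        x = np.array([2.0, 1, 3, 0, 0, 1])
        expected = stats.pearsonr(x, ind.astype(float)).statistic
        assert am.pearson_to_atlas(x, ind) == pytest.approx(expected,
                                                            abs=1e-12)
        assert am.pearson_to_atlas(x, ind) == pytest.approx(0.780869,
                                                            abs=1e-6)

    def test_zero_variance_undefined(self):
        ind = np.array([1, 0], dtype=bool)
        assert math.isnan(am.pearson_to_atlas(np.array([3.0, 3.0]), ind))


class TestMeanRatio:
    def test_inside_over_outside(self):
        ind = np.array([1, 1, 0, 0], dtype=bool)
        ratio, defined = am.mean_ratio(np.array([2.0, 2, 1, 1]), ind)
        assert defined and ratio == pytest.approx(2.0)

    def test_uniform_map_is_one(self):
        ind = np.array([1, 0, 0], dtype=bool)
        ratio, defined = am.mean_ratio(np.array([3.0, 3, 3]), ind)
        assert defined and ratio == pytest.approx(1.0)

    def test_zero_outside_flagged_undefined(self):
        ind = np.array([1, 0], dtype=bool)
        ratio, defined = am.mean_ratio(np.array([1.0, 0.0]), ind)
        assert not defined and math.isnan(ratio)


class TestMaximalMap:
    def _maps(self):
        ind = np.zeros(30, dtype=bool)
        ind[:10] = True
        rng = np.random.default_rng(0)
        noise = rng.normal(size=(4, 30))
        rows = np.array([
            noise[0],
            ind + 0.5 * noise[1],
            ind + 0.2 * noise[2],
            ind + 0.1 * noise[3],
        ])
        return _mapset(rows), ind

    def test_ica_argmax_selection(self):
        maps, ind = self._maps()
        fmap, sel = am.select_maximal_map(maps, ind, "ica")
        rs = [am.pearson_to_atlas(r, ind) for r in maps.maps]
        assert sel == [int(np.argmax(rs))]
        assert np.array_equal(fmap, maps.maps[sel[0]])

    def test_sdl_averages_three_distinct_top_maps(self):
        maps, ind = self._maps()
        fmap, sel = am.select_maximal_map(maps, ind, "sdl")
        assert len(set(sel)) == 3 and 0 not in sel  # noise map excluded
        assert np.allclose(fmap, maps.maps[sel].mean(axis=0))
        # recomputed metric on the average matches a brute-force recompute
        assert am.pearson_to_atlas(fmap, ind) == pytest.approx(
            stats.pearsonr(maps.maps[sel].mean(axis=0),
                           ind.astype(float)).statistic)

    def test_identical_maps_average_unchanged(self):
        ind = np.zeros(10, dtype=bool)
        ind[:3] = True
        row = ind + 0.1
        maps = _mapset([row, row, row])
        fmap, _ = am.select_maximal_map(maps, ind, "sdl")
        assert np.allclose(fmap, row)

    def test_sdl_needs_three_maps(self):
        ind = np.array([1, 0, 0], dtype=bool)
        with pytest.raises(ValueError):
            am.select_maximal_map(_mapset([[1.0, 0, 0]] * 2), ind, "sdl")

    def test_ties_break_to_lowest_component_index(self):
        ind = np.array([1, 1, 0, 0], dtype=bool)
        row = np.array([1.0, 1.0, 0.0, 0.0])
        maps = _mapset([row, row.copy()])
        _, sel = am.select_maximal_map(maps, ind, "ica")
        assert sel == [0]


class TestStructureMetrics:
    def test_ex_network_yields_eight_records(self, atlas, masks):
        rng = np.random.default_rng(0)
        fmap = np.abs(rng.normal(size=masks["EX"].size))
        recs = am.structure_metrics(fmap, atlas, "EX", masks, "C01", "sdl",
                                    "rest")
        assert len(recs) == 8  # network + 7 structures
        assert recs[0].region_name == "EX"

    def test_cerebellum_reported_network_level_only(self, atlas, masks):
        rng = np.random.default_rng(0)
        fmap = np.abs(rng.normal(size=masks["CERE"].size))
        recs = am.structure_metrics(fmap, atlas, "CERE", masks, "C01", "sdl",
                                    "rest")
        assert len(recs) == 1

    def test_single_structure_network_metrics_match(self, atlas, masks):
        # DMN's one structure mask equals the network mask
        rng = np.random.default_rng(1)
        fmap = np.abs(rng.normal(size=masks["DMN"].size))
        recs = am.structure_metrics(fmap, atlas, "DMN", masks, "C01", "sdl",
                                    "rest")
        assert len(recs) == 2
        assert recs[0].pearson_r == pytest.approx(recs[1].pearson_r)
        assert recs[0].mean_ratio == pytest.approx(recs[1].mean_ratio)


class TestWelch:
    def test_identical_groups(self):
        res = am.welch_test([1.0, 2, 3], [1.0, 2, 3])
        assert res.t == pytest.approx(0.0) and res.p_value == pytest.approx(1)

    def test_textbook_example(self):
        res = am.welch_test([1.0, 2, 3], [2.0, 3, 4])
        assert res.t == pytest.approx(-1.224744871391589, abs=1e-8)
        assert res.p_value == pytest.approx(0.28786413472669053, abs=1e-8)
        assert res.direction == "increase"
        ref = stats.ttest_ind([1.0, 2, 3], [2.0, 3, 4], equal_var=False)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_degenerate_zero_variance_distinct_means(self):
        res = am.welch_test([1.0, 1.0], [2.0, 2.0])
        assert res.p_value < 1e-6
        assert res.direction == "increase"

    def test_nan_values_dropped_and_counted(self):
        res = am.welch_test([1.0, 2, float("nan"), 3], [2.0, 3, 4])
        assert res.n_dropped == 1

    def test_skipped_when_too_few_defined(self):
        assert am.welch_test([1.0, float("nan")], [2.0, 3]) is None


class TestDualMetricRule:
    def _records(self, pearson_shift, ratio_shift):
        recs = []
        for i, sid in enumerate(["C1", "C2", "C3", "T1", "T2", "T3"]):
            injured = sid.startswith("T")
            recs.append(am.MetricRecord(
                subject_id=sid, method="sdl", paradigm="rest",
                region_name="VIS",
                pearson_r=0.8 - (pearson_shift if injured else 0) + 0.01 * i,
                mean_ratio=2.0 - (ratio_shift if injured else 0) + 0.01 * i))
        return recs

    def test_fires_only_when_both_metrics_significant(self):
        ctrl, inj = {"C1", "C2", "C3"}, {"T1", "T2", "T3"}
        both = am.group_comparison(self._records(0.5, 1.5), ctrl, inj)[0]
        assert both["significant"] and both["direction"] == "decrease"
        one = am.group_comparison(self._records(0.5, 0.0), ctrl, inj)[0]
        assert one["pearson_p"] < 0.05 and not one["significant"]
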