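"""Group overlay, score summation, scenarios, enumeration and area stats."""

import numpy as np
import pytest

from ecozone import (
    GridLayer,
    GridSpec,
    SCENARIOS,
    ScenarioSpec,
    apply_scenario,
    combine_scores,
    comprehensive_group_map,
    enumerate_combinations,
    weighted_overlay,
    zone_statistics,
)
from ecozone.zoning import FMCA, NMCA, SMCA, ZONE_CODE, compare_zone_stats


def _layer(vals, cell=30.0):
    vals = np.asarray(vals, dtype=float)
    return GridLayer(GridSpec(*vals.shape, cell), vals)


class TestWeightedOverlay:
    def test_single_map_identity(self, rng):
        m = _layer(rng.integers(1, 6, (5, 5)))
        out = weighted_overlay([m], [1.0])
        np.testing.assert_allclose(out.values, m.values)

    def test_two_constant_maps_midpoint(self):
        out = weighted_overlay([_layer(np.full((3, 3), 5)), _layer(np.full((3, 3), 1))], [0.5, 0.5])
        np.testing.assert_allclose(out.values, 3.0)

    def test_matches_cellwise_oracle(self, rng):
        maps = [_layer(rng.integers(1, 6, (4, 4))) for _ in range(3)]
        w = [0.5, 0.3, 0.2]
        out = weighted_overlay(maps, w)
        expect = sum(wi * m.values for wi, m in zip(w, maps))
        np.testing.assert_allclose(out.values, expect, atol=1e-12)

    def test_weight_sum_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            weighted_overlay([_layer(np.ones((2, 2)))], [0.9])

    def test_nodata_propagates(self):
        a = _layer(np.ones((2, 2)))
        b = _layer(np.ones((2, 2)))
        b.values[0, 0] = b.nodata
        out = weighted_overlay([a, b], [0.5, 0.5])
        assert out.mask[0, 0] and not out.mask[1, 1]


class TestComprehensiveGroupMap:
    def test_three_plateaus_coded_1_2_3(self):
        vals = np.concatenate([np.full(20, 1.2), np.full(20, 2.9), np.full(20, 4.8)])
        layer = _layer(vals.reshape(6, 10))
        out = comprehensive_group_map(layer)
        assert set(out.values[layer.values == 1.2]) == {1}
        assert set(out.values[layer.values == 2.9]) == {2}
        assert set(out.values[layer.values == 4.8]) == {3}

    def test_constant_overlay_degenerates(self):
        with pytest.warns(UserWarning):
            out = comprehensive_group_map(_layer(np.full((4, 4), 2.0)))
        assert np.all(out.values == 1)

    def test_agrees_with_breaks_classifier(self, rng):
        from ecozone import classify_with_breaks, compute_breaks

        vals = rng.uniform(1, 5, (8, 8))
        layer = _layer(vals)
        out = comprehensive_group_map(layer)
        bs = compute_breaks(vals.ravel(), 3)
        np.testing.assert_array_equal(out.values, classify_with_breaks(layer, bs).values)


class TestCombineScores:
    @pytest.mark.parametrize("codes, total", [((1, 1, 1), 3), ((3, 3, 3), 9), ((2, 3, 1), 6)])
    def test_sums(self, codes, total):
        gs = [_layer(np.full((2, 2), c)) for c in codes]
        out = combine_scores(*gs)
        assert np.all(out.values == total)

    def test_score_range_invariant(self, rng):
        gs = [_layer(rng.integers(1, 4, (6, 6))) for _ in range(3)]
        out = combine_scores(*gs)
        assert out.values.min() >= 3 and out.values.max() <= 9

    def test_bad_codes_rejected(self):
        gs = [_layer(np.full((2, 2), 4))] + [_layer(np.ones((2, 2)))] * 2
        with pytest.raises(ValueError, match="1/2/3"):
            combine_scores(*gs)


class TestScenarios:
    def test_builtin_score_tables_exactly(self):
        expected = {
            "priority_ecological": {FMCA: {7, 8, 9}, SMCA: {5, 6}, NMCA: {3, 4}},
            "balanced": {FMCA: {8, 9}, SMCA: {5, 6, 7}, NMCA: {3, 4}},
            "development": {FMCA: {8, 9}, SMCA: {6, 7}, NMCA: {3, 4, 5}},
        }
        for name, zones in expected.items():
            spec = SCENARIOS[name]
            for zone, scores in zones.items():
                assert spec.scores_of(zone) == scores, (name, zone)

    @pytest.mark.parametrize(
        "scenario, score, zone",
        [("balanced", 8, FMCA), ("priority_ecological", 7, FMCA), ("development", 5, NMCA)],
    )
    def test_apply_scenario_lookup(self, scenario, score, zone):
        out = apply_scenario(_layer(np.full((2, 2), score)), scenario)
        assert np.all(out.values == ZONE_CODE[zone])

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_scenario(_layer(np.full((2, 2), 10)), "balanced")

    def test_interleaved_custom_scenario_rejected(self):
        mapping = {3: "FMCA", 4: "NMCA", 5: "NMCA", 6: "SMCA", 7: "SMCA", 8: "FMCA", 9: "FMCA"}
        with pytest.raises(ValueError, match="interleav"):
            ScenarioSpec("bad", mapping)

    def test_partial_mapping_rejected(self):
        with pytest.raises(ValueError, match="every score"):
            ScenarioSpec("partial", {3: "NMCA"})

    def test_scenario_nesting_on_random_scores(self, rng):
        scores = _layer(rng.integers(3, 10, (10, 10)))
        z = {name: apply_scenario(scores, name) for name in SCENARIOS}
        prio_f = z["priority_ecological"].values == ZONE_CODE[FMCA]
        bal_f = z["balanced"].values == ZONE_CODE[FMCA]
        dev_n = z["development"].values == ZONE_CODE[NMCA]
        bal_n = z["balanced"].values == ZONE_CODE[NMCA]
        assert np.all(prio_f >= bal_f)  # priority FMCA contains balanced FMCA
        assert np.all(dev_n >= bal_n)


class TestEnumeration:
    def test_counts(self):
        combo = enumerate_combinations()
        assert combo["total"] == 27
        assert combo["per_sum"] == {3: 1, 4: 3, 5: 6, 6: 7, 7: 6, 8: 3, 9: 1}
        assert combo["per_sum"][3] + combo["per_sum"][4] == 4

    def test_sum_symmetry(self):
        per_sum = enumerate_combinations()["per_sum"]
        for s in range(3, 10):
            assert per_sum[s] == per_sum[12 - s]

    def test_per_scenario_triple_counts(self):
        per = enumerate_combinations()["per_scenario"]
        assert per["priority_ecological"] == {FMCA: 10, SMCA: 13, NMCA: 4}
        assert per["balanced"] == {FMCA: 4, SMCA: 19, NMCA: 4}
        assert per["development"] == {FMCA: 4, SMCA: 13, NMCA: 10}
        for counts in per.values():
            assert sum(counts.values()) == 27


class TestZoneStatistics:
    def test_all_nmca_area(self):
        zones = GridLayer(GridSpec(100, 100, 30.0), np.ones((100, 100)))
        st = zone_statistics(zones)
        assert st.area_km2[NMCA] == pytest.approx(9.0)
        assert st.proportion[NMCA] == 1.0
        assert st.counts[FMCA] == 0

    def test_random_map_matches_hand_counts(self, rng):
        vals = rng.integers(1, 4, (20, 20))
        zones = GridLayer(GridSpec(20, 20, 30.0), vals)
        st = zone_statistics(zones)
        for zone, code in ZONE_CODE.items():
            assert st.counts[zone] == int((vals == code).sum())
        assert sum(st.proportion.values()) == pytest.approx(1.0)

    def test_nodata_excluded(self):
        vals = np.ones((4, 4))
        vals[0, :] = -9999.0
        zones = GridLayer(GridSpec(4, 4, 30.0), vals)
        st = zone_statistics(zones)
        assert st.counts[NMCA] == 12
        assert st.proportion[NMCA] == 1.0

    def test_all_nodata_rejected(self):
        zones = GridLayer(GridSpec(2, 2, 30.0), np.full((2, 2), -9999.0))
        with pytest.raises(ValueError):
            zone_statistics(zones)

    def test_compare_differences_sum_to_zero(self, rng):
        a = zone_statistics(GridLayer(GridSpec(10, 10, 30.0), rng.integers(1, 4, (10, 10))))
        b = zone_statistics(GridLayer(GridSpec(10, 10, 30.0), rng.integers(1, 4, (10, 10))))
        diff = compare_zone_stats(a, b)
        assert sum(diff.values()) == pytest.approx(0.0, abs=1e-9)
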