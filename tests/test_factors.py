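"""Single-factor classifiers and the heavy-metal risk index."""

import numpy as np
import pytest

from ecozone import (
    GridLayer,
    GridSpec,
    HakansonConstants,
    classify_aspect,
    classify_categorical,
    classify_continuous,
    classify_distance,
    classify_range,
    contamination_factor,
    integrated_risk,
    reference_factors,
    risk_grid,
    single_metal_risk,
)
from ecozone.factors import LANDUSE_LEVELS, PH_INTERVALS, WATER_BUFFERS, ROAD_BUFFERS


def _layer(vals, nodata=-9999.0):
    vals = np.asarray(vals, dtype=float)
    return GridLayer(GridSpec(*vals.shape, 30.0), vals, nodata=nodata)


class TestHakansonScalars:
    @pytest.mark.parametrize(
        "conc, metal, expected",
        [(0.119, "Cd", 1.0), (0.238, "Cd", 2.0), (18.0, "Cr", 1.0), (35.7, "Cd", 300.0)],
    )
    def test_contamination_factor(self, conc, metal, expected):
        assert contamination_factor(conc, metal) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "cf, metal, expected", [(1.0, "Cd", 30.0), (0.0, "Zn", 0.0), (2.0, "As", 20.0)]
    )
    def test_single_metal_risk(self, cf, metal, expected):
        assert single_metal_risk(cf, metal) == pytest.approx(expected)

    def test_unknown_metal_and_negative_concentration(self):
        with pytest.raises(KeyError):
            contamination_factor(1.0, "Hg")
        with pytest.raises(ValueError):
            contamination_factor(-0.1, "Cd")

    def test_all_background_ri_is_53(self):
        consts = HakansonConstants()
        res = integrated_risk(dict(consts.background), consts)
        assert res.ri == pytest.approx(53.0)
        assert all(cf == pytest.approx(1.0) for cf in res.contamination.values())

    def test_zero_concentrations_give_zero_ri(self):
        res = integrated_risk({m: 0.0 for m in HakansonConstants().background})
        assert res.ri == 0.0

    def test_single_metal_subset(self):
        res = integrated_risk({"Cd": 0.119})
        assert res.ri == pytest.approx(30.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            integrated_risk({})

    def test_monotone_in_concentration(self):
        consts = HakansonConstants()
        base = integrated_risk(dict(consts.background), consts).ri
        bumped = dict(consts.background)
        bumped["Pb"] *= 1.5
        assert integrated_risk(bumped, consts).ri > base


class TestRiskGrid:
    def test_constant_background_grid_is_53(self):
        consts = HakansonConstants()
        layers = {m: _layer(np.full((4, 4), bg)) for m, bg in consts.background.items()}
        ri = risk_grid(layers, consts)
        np.testing.assert_allclose(ri.values, 53.0)

    def test_matches_scalar_oracle_cell_by_cell(self, rng):
        consts = HakansonConstants()
        layers = {
            m: _layer(rng.uniform(0.5, 2.0, (2, 2)) * bg)
            for m, bg in consts.background.items()
        }
        ri = risk_grid(layers, consts)
        for r in range(2):
            for c in range(2):
                conc = {m: float(layers[m].values[r, c]) for m in layers}
                assert ri.values[r, c] == pytest.approx(integrated_risk(conc, consts).ri)

    def test_nodata_propagates(self):
        consts = HakansonConstants()
        layers = {m: _layer(np.full((3, 3), bg)) for m, bg in consts.background.items()}
        layers["Cd"].values[1, 1] = -9999.0
        ri = risk_grid(layers, consts)
        assert ri.mask[1, 1] and not ri.mask[0, 0]

    def test_misaligned_layers_rejected(self):
        consts = HakansonConstants()
        a = _layer(np.full((3, 3), 1.0))
        b = GridLayer(GridSpec(3, 3, 60.0), np.full((3, 3), 1.0))
        with pytest.raises(Exception):
            risk_grid({"Cd": a, "Cr": b}, consts)


class TestContinuous:
    def test_constant_layer_degenerates_with_warning(self):
        with pytest.warns(UserWarning):
            out = classify_continuous(_layer(np.full((5, 5), 2.0)))
        assert np.all(out.values == 1)

    def test_high_values_code_five_when_ascending(self, rng):
        vals = rng.uniform(0, 1, (10, 10))
        out = classify_continuous(_layer(vals), k=5, ascending=True)
        assert out.values[np.unravel_index(vals.argmax(), vals.shape)] == 5
        assert out.values[np.unravel_index(vals.argmin(), vals.shape)] == 1

    def test_descending_flips_coding(self, rng):
        vals = rng.uniform(0, 1, (8, 8))
        up = classify_continuous(_layer(vals), ascending=True)
        dn = classify_continuous(_layer(vals), ascending=False)
        np.testing.assert_array_equal(up.values + dn.values, 6)


class TestDistance:
    def test_river_buffer_levels(self):
        d = _layer([[15.0, 45.0, 75.0, 105.0, 5000.0]])
        out = classify_distance(d, WATER_BUFFERS, near_is_sensitive=True)
        np.testing.assert_array_equal(out.values, [[5, 4, 3, 2, 1]])

    def test_boundary_inclusive(self):
        d = _layer([[30.0, 30.0001]])
        out = classify_distance(d, WATER_BUFFERS)
        assert out.values[0, 0] == 5  # exactly 30 m is still "within 30 m"
        assert out.values[0, 1] == 4

    def test_road_coding_is_mirrored(self):
        d = _layer([[15.0, 75.0, 125.0, 175.0, 5000.0]])
        out = classify_distance(d, ROAD_BUFFERS, near_is_sensitive=False)
        np.testing.assert_array_equal(out.values, [[1, 2, 3, 4, 5]])

    def test_mirror_codes_sum_to_six(self, rng):
        d = _layer(rng.uniform(0, 300, (6, 6)))
        near = classify_distance(d, ROAD_BUFFERS, near_is_sensitive=True)
        far = classify_distance(d, ROAD_BUFFERS, near_is_sensitive=False)
        np.testing.assert_array_equal(near.values + far.values, 6)

    def test_malformed_thresholds(self):
        with pytest.raises(ValueError):
            classify_distance(_layer([[1.0]]), [30, 60, 60, 120])
        with pytest.raises(ValueError):
            classify_distance(_layer([[1.0]]), [30, 60, 90])


class TestCategorical:
    def test_landuse_mapping(self):
        lu = _layer([[1, 2], [5, 4]])
        out = classify_categorical(lu, LANDUSE_LEVELS)
        np.testing.assert_array_equal(out.values, [[5, 4], [1, 2]])

    def test_unmapped_code_becomes_nodata_with_warning(self):
        lu = _layer([[1, 99]])
        with pytest.warns(UserWarning, match="unmapped"):
            out = classify_categorical(lu, LANDUSE_LEVELS)
        assert out.values[0, 0] == 5 and out.mask[0, 1]

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            classify_categorical(_layer([[1]]), {})


class TestRange:
    @pytest.mark.parametrize("ph, level", [(7.0, 1), (4.5, 5), (6.0, 3), (8.0, 3), (9.0, 5)])
    def test_ph_scheme(self, ph, level):
        out = classify_range(_layer([[ph]]), PH_INTERVALS)
        assert out.values[0, 0] == level

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            classify_range(_layer([[1.0]]), [(0, 5, 1), (4, 9, 2)])

    def test_gap_becomes_nodata_with_warning(self):
        with pytest.warns(UserWarning, match="outside"):
            out = classify_range(_layer([[3.0]]), [(0, 1, 1), (5, 9, 2)])
        assert out.mask[0, 0]


class TestAspect:
    @pytest.mark.parametrize(
        "deg, level",
        [(180.0, 5), (135.0, 5), (90.0, 4), (45.0, 3), (225.0, 3), (0.0, 2), (270.0, 1), (315.0, 1)],
    )
    def test_compass_sectors(self, deg, level):
        out = classify_aspect(_layer([[deg]]))
        assert out.values[0, 0] == level

    def test_flat_sentinel_is_non_sensitive(self):
        out = classify_aspect(_layer([[-1.0]]))
        assert out.values[0, 0] == 1

    def test_wraparound_near_north(self):
        out = classify_aspect(_layer([[359.0, 1.0]]))
        np.testing.assert_array_equal(out.values, [[2, 2]])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_aspect(_layer([[400.0]]))


class TestReferenceConfiguration:
    def test_eighteen_factors_partition_6_8_4(self):
        factors = reference_factors()
        assert len(factors) == 18
        by_group = {}
        for f in factors:
            by_group.setdefault(f.group, []).append(f.name)
        assert len(by_group["topographic"]) == 6
        assert len(by_group["ecological"]) == 8
        assert len(by_group["human"]) == 4
        assert len({f.name for f in factors}) == 18
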