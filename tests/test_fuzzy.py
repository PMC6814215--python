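import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fuzzyrisk import (
    ConversionSpec,
    FuzzyLayer,
    GridSpec,
    RasterLayer,
    TIE_NONE,
    convert_linear,
    fuzzy_and,
    fuzzy_or,
    fuzzy_union,
)
from fuzzyrisk.fuzzy import convert_linear_scalar

from conftest import fuzzy_from, raster_from

BURNED_SPEC = ConversionSpec(0.0, 110.0)


def convert_scalar_via_layer(value: float, spec: ConversionSpec) -> float:
    grid = GridSpec(1, 1)
    return float(convert_linear(raster_from(grid, [[value]]), spec).values[0, 0])


class TestConversionSpec:
    def test_equal_thresholds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ConversionSpec(5.0, 5.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ConversionSpec(0.0, np.inf)


class TestConvertLinear:
    def test_midpoint_of_burned_thresholds(self):
        # worked value: halfway between the burned-biomass thresholds
        assert convert_scalar_via_layer(55.0, BURNED_SPEC) == 0.5

    def test_below_false_threshold(self):
        assert convert_scalar_via_layer(-5.0, BURNED_SPEC) == 0.0

    def test_above_true_threshold(self):
        assert convert_scalar_via_layer(200.0, BURNED_SPEC) == 1.0

    def test_boundaries_map_exactly(self):
        assert convert_scalar_via_layer(0.0, BURNED_SPEC) == 0.0
        assert convert_scalar_via_layer(110.0, BURNED_SPEC) == 1.0

    def test_reversed_thresholds_decreasing(self):
        spec = ConversionSpec(10.0, 0.0)
        assert convert_scalar_via_layer(12.0, spec) == 0.0
        assert convert_scalar_via_layer(-1.0, spec) == 1.0
        assert convert_scalar_via_layer(5.0, spec) == 0.5

    @given(
        value=st.floats(-1e6, 1e6),
        lo=st.floats(-1e3, 1e3),
        width=st.floats(1e-3, 1e3),
    )
    def test_output_in_unit_interval(self, value, lo, width):
        spec = ConversionSpec(lo, lo + width)
        out = convert_linear_scalar(value, spec)
        assert 0.0 <= out <= 1.0

    @given(
        values=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=20),
        lo=st.floats(-100, 100),
        width=st.floats(0.1, 100),
    )
    def test_monotone_nondecreasing(self, values, lo, width):
        spec = ConversionSpec(lo, lo + width)
        ordered = sorted(values)
        outs = [convert_linear_scalar(v, spec) for v in ordered]
        assert all(a <= b for a, b in zip(outs, outs[1:]))

    def test_scalar_matches_vectorized(self, rng):
        spec = ConversionSpec(-3.0, 7.0)
        grid = GridSpec(5, 5)
        values = rng.uniform(-10, 15, (5, 5))
        layer = convert_linear(raster_from(grid, values), spec)
        expected = np.array(
            [[convert_linear_scalar(v, spec) for v in row] for row in values]
        )
        np.testing.assert_array_equal(layer.values, expected)


class TestFuzzyLayerValidation:
    def test_rejects_out_of_range(self, grid2x2):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            FuzzyLayer(grid2x2, np.full((2, 2), 1.5))


class TestAnd:
    def test_worked_example(self, single_cell):
        a = fuzzy_from(single_cell, [[0.3]], "A")
        b = fuzzy_from(single_cell, [[0.5]], "B")
        result, attribution = fuzzy_and([a, b])
        assert result.values[0, 0] == 0.3
        assert attribution.indices[0, 0] == 0
        assert not attribution.tie[0, 0]
        assert attribution.input_names[attribution.indices[0, 0]] == "A"

    def test_identical_inputs_tie(self, grid2x2):
        a = fuzzy_from(grid2x2, np.full((2, 2), 0.4))
        result, attribution = fuzzy_and([a, a])
        np.testing.assert_array_equal(result.values, a.values)
        assert attribution.tie.all()
        assert (attribution.indices == 0).all()

    def test_minimum_of_three(self, single_cell):
        layers = [fuzzy_from(single_cell, [[v]]) for v in (1.0, 1.0, 0.0)]
        result, attribution = fuzzy_and(layers)
        assert result.values[0, 0] == 0.0
        assert attribution.indices[0, 0] == 2

    def test_fewer_than_two_inputs(self, single_cell):
        with pytest.raises(ValueError, match="at least 2"):
            fuzzy_and([fuzzy_from(single_cell, [[0.5]])])

    def test_grid_mismatch(self, single_cell, grid2x2):
        with pytest.raises(ValueError, match="grid mismatch"):
            fuzzy_and(
                [fuzzy_from(single_cell, [[0.5]]), fuzzy_from(grid2x2, np.zeros((2, 2)))]
            )


class TestOr:
    def test_maximum(self, single_cell):
        a = fuzzy_from(single_cell, [[0.3]])
        b = fuzzy_from(single_cell, [[0.5]])
        result, attribution = fuzzy_or([a, b])
        assert result.values[0, 0] == 0.5
        assert attribution.indices[0, 0] == 1

    def test_all_zero_tie(self, single_cell):
        layers = [fuzzy_from(single_cell, [[0.0]]) for _ in range(2)]
        result, attribution = fuzzy_or(layers)
        assert result.values[0, 0] == 0.0
        assert attribution.tie[0, 0]

    def test_tie_resolved_to_lowest_index(self, single_cell):
        layers = [fuzzy_from(single_cell, [[v]]) for v in (0.2, 0.9, 0.9)]
        result, attribution = fuzzy_or(layers)
        assert result.values[0, 0] == 0.9
        assert attribution.indices[0, 0] == 1
        assert attribution.tie[0, 0]


class TestUnion:
    def test_mean_of_two(self, single_cell):
        result = fuzzy_union(
            [fuzzy_from(single_cell, [[0.0]]), fuzzy_from(single_cell, [[1.0]])]
        )
        assert result.values[0, 0] == 0.5

    def test_identity_on_equal_inputs(self, grid2x2):
        x = fuzzy_from(grid2x2, np.full((2, 2), 0.37))
        result = fuzzy_union([x, x, x])
        np.testing.assert_allclose(result.values, 0.37, rtol=1e-15)

    def test_mean_of_three(self, single_cell):
        result = fuzzy_union(
            [fuzzy_from(single_cell, [[v]]) for v in (0.2, 0.4, 0.9)]
        )
        # oracle: arithmetic mean computed directly
        assert result.values[0, 0] == pytest.approx((0.2 + 0.4 + 0.9) / 3, abs=1e-12)
        assert result.values[0, 0] == pytest.approx(0.5, abs=1e-9)


unit_arrays = hnp.arrays(
    dtype=float,
    shape=st.tuples(st.integers(1, 4), st.integers(1, 4)),
    elements=st.floats(0.0, 1.0),
)


@st.composite
def fuzzy_layer_lists(draw, min_size=2, max_size=4):
    shape = draw(st.tuples(st.integers(1, 4), st.integers(1, 4)))
    grid = GridSpec(*shape)
    n = draw(st.integers(min_size, max_size))
    layers = [
        fuzzy_from(
            grid,
            draw(hnp.arrays(dtype=float, shape=shape, elements=st.floats(0.0, 1.0))),
            f"in{i}",
        )
        for i in range(n)
    ]
    return layers


class TestOperatorProperties:
    @given(layers=fuzzy_layer_lists())
    @settings(max_examples=50, deadline=None)
    def test_and_le_union_le_or(self, layers):
        low, _ = fuzzy_and(layers)
        mid = fuzzy_union(layers)
        high, _ = fuzzy_or(layers)
        assert (low.values <= mid.values + 1e-12).all()
        assert (mid.values <= high.values + 1e-12).all()

    @given(layers=fuzzy_layer_lists(min_size=2, max_size=2))
    @settings(max_examples=50, deadline=None)
    def test_commutativity(self, layers):
        a, b = layers
        np.testing.assert_array_equal(
            fuzzy_and([a, b])[0].values, fuzzy_and([b, a])[0].values
        )
        np.testing.assert_array_equal(
            fuzzy_or([a, b])[0].values, fuzzy_or([b, a])[0].values
        )
        np.testing.assert_array_equal(
            fuzzy_union([a, b]).values, fuzzy_union([b, a]).values
        )

    @given(layers=fuzzy_layer_lists(min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_and_or_associative_idempotent(self, layers):
        a, b, c = layers
        left, _ = fuzzy_and([fuzzy_and([a, b])[0], c])
        right, _ = fuzzy_and([a, fuzzy_and([b, c])[0]])
        np.testing.assert_array_equal(left.values, right.values)
        left, _ = fuzzy_or([fuzzy_or([a, b])[0], c])
        right, _ = fuzzy_or([a, fuzzy_or([b, c])[0]])
        np.testing.assert_array_equal(left.values, right.values)
        np.testing.assert_array_equal(fuzzy_and([a, a])[0].values, a.values)
        np.testing.assert_array_equal(fuzzy_or([a, a])[0].values, a.values)

    @given(layers=fuzzy_layer_lists())
    @settings(max_examples=50, deadline=None)
    def test_attribution_consistency(self, layers):
        # result value at a cell equals the attributed input's value, exactly
        for op in (fuzzy_and, fuzzy_or):
            result, attribution = op(layers)
            stacked = np.stack([lyr.values for lyr in layers])
            rows, cols = np.nonzero(result.grid.valid_mask)
            for r, c in zip(rows, cols):
                idx = attribution.indices[r, c]
                assert result.values[r, c] == stacked[idx, r, c]

    @given(layers=fuzzy_layer_lists())
    @settings(max_examples=50, deadline=None)
    def test_outputs_stay_in_unit_interval(self, layers):
        for values in (
            fuzzy_and(layers)[0].values,
            fuzzy_or(layers)[0].values,
            fuzzy_union(layers).values,
        ):
            assert np.nanmin(values) >= 0.0
            assert np.nanmax(values) <= 1.0


class TestMaskPropagation:
    def test_masked_cells_stay_masked(self, masked_grid):
        a = FuzzyLayer(masked_grid, np.where(masked_grid.valid_mask, 0.2, np.nan))
        b = FuzzyLayer(masked_grid, np.where(masked_grid.valid_mask, 0.8, np.nan))
        result, attribution = fuzzy_and([a, b])
        assert np.isnan(result.values[~masked_grid.valid_mask]).all()
        assert (attribution.indices[~masked_grid.valid_mask] == TIE_NONE).all()
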