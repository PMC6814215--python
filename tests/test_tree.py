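import numpy as np
import pytest

from fuzzyrisk import ConversionSpec, GridSpec, LogicTree, NodeSpec, load_tree
from fuzzyrisk.grid_io import EnsembleStack
from fuzzyrisk.tree import default_tree_path, tree_from_config

from conftest import raster_from
from oracles import random_tree, scalar_tree_eval

#: Raw single-cell inputs that sit exactly at every fully-true threshold of
#: the default (frozen-profile) tree.
ALL_TRUE_INPUTS = {
    "mc2_biomass_burned": 110.0,
    "mc2_fire_frequency": 1.0,
    "mc2_biomass": 73148.0,
    "mc2_live_biomass": 29387.0,
    "mc2_vegetation_stress": 3.0,
    "observed_biomass": 21844.0,
}


@pytest.fixture(scope="module")
def default_tree() -> LogicTree:
    return load_tree(default_tree_path())


def single_cell_inputs(values: dict) -> dict:
    grid = GridSpec(1, 1)
    return {var: raster_from(grid, [[v]], var) for var, v in values.items()}


class TestLoadTree:
    def test_default_tree_shape(self, default_tree):
        assert len(default_tree.nodes) == 11
        inputs = [n for n in default_tree.nodes.values() if n.kind == "input"]
        assert len(inputs) == 6
        assert default_tree.root == "biomass_loss_risk"

    def test_cycle_detected(self):
        config = {
            "nodes": [
                {"name": "a", "kind": "and", "children": ["b", "a"]},
                {"name": "b", "kind": "input", "variable": "x"},
            ]
        }
        with pytest.raises(ValueError, match="cycle"):
            tree_from_config(config)

    def test_convert_arity_violation(self):
        with pytest.raises(ValueError, match="arity"):
            NodeSpec(
                "c",
                "convert",
                children=("a", "b"),
                conversion=ConversionSpec(0, 1),
            )

    def test_operator_arity_violation(self):
        with pytest.raises(ValueError, match="arity"):
            NodeSpec("c", "and", children=("a",))

    def test_dangling_child(self):
        config = {
            "nodes": [
                {"name": "a", "kind": "input", "variable": "x"},
                {"name": "root", "kind": "and", "children": ["a", "ghost"]},
            ]
        }
        with pytest.raises(ValueError, match="dangling"):
            tree_from_config(config)

    def test_multiple_roots_rejected(self):
        config = {
            "nodes": [
                {"name": "a", "kind": "input", "variable": "x"},
                {"name": "b", "kind": "input", "variable": "y"},
            ]
        }
        with pytest.raises(ValueError, match="exactly one root"):
            tree_from_config(config)


class TestEvaluateSingleCell:
    def test_all_true_inputs_give_root_one(self, default_tree):
        result = default_tree.evaluate(single_cell_inputs(ALL_TRUE_INPUTS))
        assert result.root_layer.values[0, 0] == 1.0

    def test_zero_observed_biomass_forces_root_zero(self, default_tree):
        inputs = dict(ALL_TRUE_INPUTS)
        inputs["observed_biomass"] = 0.0  # below its fully-false threshold
        result = default_tree.evaluate(single_cell_inputs(inputs))
        assert result.root_layer.values[0, 0] == 0.0

    def test_random_cell_matches_scalar_oracle(self, default_tree, rng):
        scalars = {
            "mc2_biomass_burned": float(rng.uniform(0, 200)),
            "mc2_fire_frequency": float(rng.uniform(0, 1)),
            "mc2_biomass": float(rng.uniform(0, 100000)),
            "mc2_live_biomass": float(rng.uniform(0, 40000)),
            "mc2_vegetation_stress": float(rng.uniform(0, 3)),
            "observed_biomass": float(rng.uniform(0, 30000)),
        }
        result = default_tree.evaluate(single_cell_inputs(scalars))
        oracle = scalar_tree_eval(default_tree, scalars)
        for node, value in oracle.items():
            assert result.layers[node].values[0, 0] == value

    def test_missing_input_variable(self, default_tree):
        inputs = single_cell_inputs(ALL_TRUE_INPUTS)
        del inputs["mc2_biomass"]
        with pytest.raises(KeyError, match="missing input"):
            default_tree.evaluate(inputs)

    def test_all_node_layers_present(self, default_tree):
        result = default_tree.evaluate(single_cell_inputs(ALL_TRUE_INPUTS))
        assert set(result.layers) == set(default_tree.nodes)
        # attributions exactly on and/or nodes
        and_or = {
            n for n, s in default_tree.nodes.items() if s.kind in ("and", "or")
        }
        assert set(result.attributions) == and_or


class TestEngineVsOracle:
    def test_random_trees_match_scalar_evaluator(self):
        rng = np.random.default_rng(1234)
        for _ in range(25):
            tree, variables = random_tree(rng)
            shape = (int(rng.integers(1, 8)), int(rng.integers(1, 8)))
            grid = GridSpec(*shape)
            raw = {
                var: rng.uniform(0, 1, shape) if needs_unit else rng.uniform(-8, 8, shape)
                for var, needs_unit in variables
            }
            inputs = {var: raster_from(grid, vals, var) for var, vals in raw.items()}
            result = tree.evaluate(inputs)
            for r in range(shape[0]):
                for c in range(shape[1]):
                    scalars = {var: raw[var][r, c] for var, _ in variables}
                    oracle = scalar_tree_eval(tree, scalars)
                    for node, value in oracle.items():
                        assert result.layers[node].values[r, c] == value


class TestInvariants:
    def test_cell_independence_under_permutation(self, default_tree, rng):
        shape = (6, 7)
        grid = GridSpec(*shape)
        raw = {
            "mc2_biomass_burned": rng.uniform(0, 200, shape),
            "mc2_fire_frequency": rng.uniform(0, 1, shape),
            "mc2_biomass": rng.uniform(0, 100000, shape),
            "mc2_live_biomass": rng.uniform(0, 40000, shape),
            "mc2_vegetation_stress": rng.uniform(0, 3, shape),
            "observed_biomass": rng.uniform(0, 30000, shape),
        }
        perm = rng.permutation(shape[0] * shape[1])
        base = default_tree.evaluate(
            {var: raster_from(grid, vals, var) for var, vals in raw.items()}
        )
        permuted = default_tree.evaluate(
            {
                var: raster_from(grid, vals.ravel()[perm].reshape(shape), var)
                for var, vals in raw.items()
            }
        )
        for node in default_tree.nodes:
            np.testing.assert_array_equal(
                base.layers[node].values.ravel()[perm],
                permuted.layers[node].values.ravel(),
            )

    def test_monotone_in_each_raw_input(self, default_tree, rng):
        # bumping one raw input never decreases the root under the default
        # tree (all conversions increasing, all operators monotone)
        base_raw = {
            "mc2_biomass_burned": 60.0,
            "mc2_fire_frequency": 0.4,
            "mc2_biomass": 50000.0,
            "mc2_live_biomass": 15000.0,
            "mc2_vegetation_stress": 1.2,
            "observed_biomass": 12000.0,
        }
        base = default_tree.evaluate(single_cell_inputs(base_raw)).root_layer.values[0, 0]
        for var in base_raw:
            for bump in (1.1, 2.0, 10.0):
                raw = dict(base_raw)
                raw[var] *= bump
                bumped = default_tree.evaluate(
                    single_cell_inputs(raw)
                ).root_layer.values[0, 0]
                assert bumped >= base


class TestEvaluateEnsemble:
    def small_stacks(self, tree, grid, member_ids, rng):
        shape = (len(member_ids),) + grid.shape
        return {
            "mc2_biomass_burned": EnsembleStack(grid, member_ids, rng.uniform(0, 200, shape)),
            "mc2_fire_frequency": EnsembleStack(grid, member_ids, rng.uniform(0, 1, shape)),
            "mc2_biomass": EnsembleStack(grid, member_ids, rng.uniform(0, 1e5, shape)),
            "mc2_live_biomass": EnsembleStack(grid, member_ids, rng.uniform(0, 4e4, shape)),
            "mc2_vegetation_stress": EnsembleStack(grid, member_ids, rng.uniform(0, 3, shape)),
        }

    def shared(self, grid, rng):
        return {"observed_biomass": raster_from(grid, rng.uniform(0, 3e4, grid.shape))}

    def test_member_count_preserved(self, default_tree, rng):
        grid = GridSpec(3, 3)
        ids = tuple(f"cf{i}" for i in range(20))
        results = default_tree.evaluate_ensemble(
            self.small_stacks(default_tree, grid, ids, rng), self.shared(grid, rng)
        )
        assert tuple(results) == ids

    def test_single_member_equals_plain_evaluate(self, default_tree, rng):
        grid = GridSpec(4, 4)
        stacks = self.small_stacks(default_tree, grid, ("only",), rng)
        shared = self.shared(grid, rng)
        ens = default_tree.evaluate_ensemble(stacks, shared)["only"]
        inputs = {var: stack.member("only") for var, stack in stacks.items()}
        inputs.update(shared)
        direct = default_tree.evaluate(inputs)
        for node in default_tree.nodes:
            np.testing.assert_array_equal(
                ens.layers[node].values, direct.layers[node].values
            )

    def test_permuted_member_order_rejected(self, default_tree, rng):
        grid = GridSpec(2, 2)
        stacks = self.small_stacks(default_tree, grid, ("a", "b"), rng)
        flipped = stacks["mc2_biomass"]
        stacks["mc2_biomass"] = EnsembleStack(
            grid, ("b", "a"), flipped.values[::-1], flipped.variable_name
        )
        with pytest.raises(ValueError, match="member-id mismatch"):
            default_tree.evaluate_ensemble(stacks, self.shared(grid, rng))
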