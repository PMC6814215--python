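"""Declarative logic tree and its cell-independent evaluation engine.

A tree is a DAG of named nodes: *input* nodes bind raw variables (optionally
fused with a linear conversion to fuzzy truth), *convert* nodes normalize a
single child, and *and*/*or*/*union* nodes combine two or more children
per cell.  Evaluation is bottom-up, topological and memoized; every node
yields a displayable fuzzy layer, and And/Or nodes additionally yield an
attribution layer naming the input that supplied each cell's value.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from fuzzyrisk.fuzzy import (
    AttributionLayer,
    ConversionSpec,
    FuzzyLayer,
    convert_linear,
    fuzzy_and,
    fuzzy_or,
    fuzzy_union,
)
from fuzzyrisk.grid_io import EnsembleStack, GridSpec, RasterLayer

__all__ = ["NodeSpec", "LogicTree", "TreeResult", "load_tree", "default_tree_path"]

OPERATOR_KINDS = ("and", "or", "union")
KINDS = ("input", "convert") + OPERATOR_KINDS

#: Default logic-tree configuration shipped with the package.
_DATA_DIR = os.path.join(os.path.dirname(__file__), "data")


def default_tree_path() -> str:
    """Path of the packaged default biomass-loss-risk tree config."""
    return os.path.join(_DATA_DIR, "biomass_loss_risk.yaml")


@dataclass(frozen=True)
class NodeSpec:
    """One node of the logic tree.

    ``kind`` is one of ``input``, ``convert``, ``and``, ``or``, ``union``.
    Input nodes carry ``input_variable`` and may fuse a conversion; convert
    nodes have exactly one child plus a conversion; operator nodes have two
    or more children.
    """

    name: str
    kind: str
    statement: str = ""
    children: tuple[str, ...] = ()
    conversion: ConversionSpec | None = None
    input_variable: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        object.__setattr__(self, "children", tuple(self.children))
        if self.kind == "input":
            if self.children:
                raise ValueError(f"input node {self.name!r} must have no children")
            if not self.input_variable:
                raise ValueError(f"input node {self.name!r} needs input_variable")
        elif self.kind == "convert":
            if len(self.children) != 1:
                raise ValueError(
                    f"arity violation: convert node {self.name!r} must have exactly "
                    f"1 child, got {len(self.children)}"
                )
            if self.conversion is None:
                raise ValueError(f"convert node {self.name!r} needs a conversion")
        else:
            if len(self.children) < 2:
                raise ValueError(
                    f"arity violation: operator node {self.name!r} needs >= 2 "
                    f"children, got {len(self.children)}"
                )


@dataclass(frozen=True)
class TreeResult:
    """All node layers (and And/Or attributions) from one tree evaluation."""

    root: str
    layers: dict = field(repr=False)  # node name -> FuzzyLayer
    attributions: dict = field(repr=False)  # node name -> AttributionLayer

    @property
    def root_layer(self) -> FuzzyLayer:
        return self.layers[self.root]


@dataclass(frozen=True)
class LogicTree:
    """A validated, single-rooted, acyclic logic tree."""

    name: str
    nodes: dict  # node name -> NodeSpec

    def __post_init__(self) -> None:
        nodes = dict(self.nodes)
        referenced: set[str] = set()
        for spec in nodes.values():
            for child in spec.children:
                if child not in nodes:
                    raise ValueError(
                        f"dangling child {child!r} referenced by {spec.name!r}"
                    )
                referenced.add(child)
        object.__setattr__(self, "nodes", nodes)
        order = self._toposort()
        roots = [n for n in nodes if n not in referenced]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {sorted(roots)}")
        object.__setattr__(self, "_root", roots[0])
        # keep only nodes the root actually depends on, in evaluation order
        reachable: set[str] = set()
        pending = [roots[0]]
        while pending:
            name = pending.pop()
            if name in reachable:
                continue
            reachable.add(name)
            pending.extend(nodes[name].children)
        unreachable = set(nodes) - reachable
        if unreachable:
            raise ValueError(f"nodes unreachable from root: {sorted(unreachable)}")
        object.__setattr__(self, "_order", tuple(n for n in order if n in reachable))

    def _toposort(self) -> tuple[str, ...]:
        """Order all nodes children-first; raises on any cycle."""
        order: list[str] = []
        state: dict[str, int] = {}  # 1 = visiting, 2 = done

        def visit(name: str, path: tuple[str, ...]) -> None:
            if state.get(name) == 2:
                return
            if state.get(name) == 1:
                start = path.index(name)
                cycle = " -> ".join(path[start:] + (name,))
                raise ValueError(f"cycle in logic tree: {cycle}")
            state[name] = 1
            for child in self.nodes[name].children:
                visit(child, path + (name,))
            state[name] = 2
            order.append(name)

        for name in self.nodes:
            visit(name, ())
        return tuple(order)

    @property
    def root(self) -> str:
        return self._root

    @property
    def input_variables(self) -> tuple[str, ...]:
        return tuple(
            spec.input_variable
            for spec in self.nodes.values()
            if spec.kind == "input"
        )

    def with_thresholds(self, thresholds: dict) -> "LogicTree":
        """Return a copy with conversions replaced per input variable name.

        ``thresholds`` maps input variable names to :class:`ConversionSpec`;
        nodes whose variable is absent keep their configured conversion.
        """
        new_nodes = {}
        for name, spec in self.nodes.items():
            if spec.kind == "input" and spec.input_variable in thresholds:
                spec = NodeSpec(
                    spec.name,
                    spec.kind,
                    spec.statement,
                    spec.children,
                    thresholds[spec.input_variable],
                    spec.input_variable,
                )
            new_nodes[name] = spec
        return LogicTree(self.name, new_nodes)

    # ------------------------------------------------------------------
    # evaluation

    def evaluate(self, inputs: dict) -> TreeResult:
        """Evaluate every node bottom-up on one set of input layers.

        ``inputs`` maps input variable names to :class:`RasterLayer`.  All
        layers must share one grid; each cell is computed independently of
        all other cells.
        """
        grid = self._common_grid(inputs)
        layers: dict[str, FuzzyLayer] = {}
        attributions: dict[str, AttributionLayer] = {}
        for name in self._order:
            spec = self.nodes[name]
            if spec.kind == "input":
                raw = inputs[spec.input_variable]
                grid.require_same(raw.grid, f"input {name!r}")
                if spec.conversion is not None:
                    layers[name] = convert_linear(raw, spec.conversion)
                else:
                    layers[name] = FuzzyLayer(
                        raw.grid, raw.values, raw.variable_name, "fuzzy truth"
                    )
            elif spec.kind == "convert":
                child = layers[spec.children[0]]
                raw_layer = RasterLayer(child.grid, child.values, name)
                layers[name] = convert_linear(raw_layer, spec.conversion)
            else:
                children = [layers[c] for c in spec.children]
                if spec.kind == "and":
                    layers[name], attributions[name] = fuzzy_and(children, name)
                elif spec.kind == "or":
                    layers[name], attributions[name] = fuzzy_or(children, name)
                else:
                    layers[name] = fuzzy_union(children, name)
        return TreeResult(self._root, layers, attributions)

    def evaluate_ensemble(
        self,
        stacks: dict,
        shared_inputs: dict | None = None,
    ) -> dict:
        """Evaluate the tree independently for each ensemble member.

        ``stacks`` maps input variable names to :class:`EnsembleStack`;
        ``shared_inputs`` maps names to single layers broadcast to every
        member (e.g. the observed-biomass layer).  Returns an ordered dict
        ``member_id -> TreeResult`` with no cross-member mixing.
        """
        shared_inputs = shared_inputs or {}
        missing = [
            v
            for v in self.input_variables
            if v not in stacks and v not in shared_inputs
        ]
        if missing:
            raise KeyError(f"missing input variable(s): {missing}")
        stack_list = list(stacks.values())
        if not stack_list:
            raise ValueError("evaluate_ensemble requires at least one stack")
        member_ids = stack_list[0].member_ids
        for stack in stack_list[1:]:
            if stack.member_ids != member_ids:
                raise ValueError(
                    f"member-id mismatch between stacks: {stack.member_ids} "
                    f"vs {member_ids}"
                )
        results: dict[str, TreeResult] = {}
        for i, member_id in enumerate(member_ids):
            inputs = {
                var: RasterLayer(stack.grid, stack.values[i], var, stack.units)
                for var, stack in stacks.items()
            }
            inputs.update(shared_inputs)
            results[member_id] = self.evaluate(inputs)
        return results

    def _common_grid(self, inputs: dict) -> GridSpec:
        missing = [v for v in self.input_variables if v not in inputs]
        if missing:
            raise KeyError(f"missing input variable(s): {missing}")
        grids = [inputs[v].grid for v in self.input_variables]
        grid = grids[0]
        for other in grids[1:]:
            grid.require_same(other, "tree evaluation")
        return grid


def _parse_thresholds(raw: dict) -> ConversionSpec:
    # YAML parses bare false/true keys as booleans; accept both spellings
    mapping = {str(k).lower(): v for k, v in raw.items()}
    if "false" not in mapping or "true" not in mapping:
        raise ValueError(f"thresholds must have 'false' and 'true' keys, got {raw}")
    return ConversionSpec(float(mapping["false"]), float(mapping["true"]))


def load_tree(path: str) -> LogicTree:
    """Load and validate a logic tree from a YAML or JSON config file."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        if path.endswith(".json"):
            config = json.load(fh)
        else:
            config = yaml.safe_load(fh)
    return tree_from_config(config)


def tree_from_config(config: dict) -> LogicTree:
    """Build a :class:`LogicTree` from an already-parsed config mapping."""
    if "nodes" not in config:
        raise ValueError("tree config must have a 'nodes' list")
    nodes: dict[str, NodeSpec] = {}
    for entry in config["nodes"]:
        name = entry["name"]
        if name in nodes:
            raise ValueError(f"duplicate node name {name!r}")
        conversion = None
        if "thresholds" in entry:
            conversion = _parse_thresholds(entry["thresholds"])
        nodes[name] = NodeSpec(
            name=name,
            kind=entry["kind"],
            statement=entry.get("statement", ""),
            children=tuple(entry.get("children", ())),
            conversion=conversion,
            input_variable=entry.get("variable", ""),
        )
    return LogicTree(config.get("name", "logic_tree"), nodes)
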