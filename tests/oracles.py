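"""Independent brute-force oracles kept deliberately separate from the
vectorized implementations they check."""

import numpy as np

from fuzzyrisk.fuzzy import ConversionSpec, convert_linear_scalar
from fuzzyrisk.tree import LogicTree, NodeSpec


def scalar_tree_eval(tree: LogicTree, scalar_inputs: dict) -> dict:
    """Recursive per-cell (scalar) evaluation of every tree node."""
    memo: dict[str, float] = {}

    def visit(name: str) -> float:
        if name in memo:
            return memo[name]
        spec = tree.nodes[name]
        if spec.kind == "input":
            value = scalar_inputs[spec.input_variable]
            if spec.conversion is not None:
                value = convert_linear_scalar(value, spec.conversion)
        elif spec.kind == "convert":
            value = convert_linear_scalar(visit(spec.children[0]), spec.conversion)
        else:
            children = [visit(c) for c in spec.children]
            if spec.kind == "and":
                value = min(children)
            elif spec.kind == "or":
                value = max(children)
            else:  # union: accumulate in child order, like the engine
                acc = children[0]
                for c in children[1:]:
                    acc = acc + c
                value = acc / len(children)
        memo[name] = value
        return value

    visit(tree.root)
    return memo


def percentile_oracle(values: np.ndarray, p: float) -> float:
    """Sort-and-interpolate percentile, written independently of numpy's."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    pos = (p / 100.0) * (n - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    if lo == hi:
        return float(x[lo])
    frac = pos - lo
    return float(x[lo] + frac * (x[hi] - x[lo]))


def random_tree(rng: np.random.Generator, max_depth: int = 4) -> tuple[LogicTree, list]:
    """Random logic tree of depth <= max_depth; returns (tree, input variables)."""
    nodes: dict[str, NodeSpec] = {}
    variables: list[str] = []
    counter = [0]

    def fresh(prefix: str) -> str:
        counter[0] += 1
        return f"{prefix}{counter[0]}"

    def make_input() -> str:
        name = fresh("in")
        var = fresh("v")
        conversion = None
        if rng.random() < 0.7:
            lo = float(rng.uniform(-5, 5))
            hi = lo + float(rng.uniform(0.5, 5))
            if rng.random() < 0.2:
                lo, hi = hi, lo  # reversed ramp
            conversion = ConversionSpec(lo, hi)
        # variables feeding unconverted inputs must already be fuzzy in [0, 1]
        variables.append((var, conversion is None))
        nodes[name] = NodeSpec(name, "input", conversion=conversion, input_variable=var)
        return name

    def make_node(depth: int) -> str:
        if depth <= 0 or rng.random() < 0.3:
            return make_input()
        kind = rng.choice(["and", "or", "union", "convert"])
        if kind == "convert":
            child = make_node(depth - 1)
            name = fresh("cv")
            lo = float(rng.uniform(-1, 1))
            nodes[name] = NodeSpec(
                name, "convert", children=(child,),
                conversion=ConversionSpec(lo, lo + float(rng.uniform(0.2, 2))),
            )
            return name
        n_children = int(rng.integers(2, 4))
        children = tuple(make_node(depth - 1) for _ in range(n_children))
        name = fresh(kind)
        nodes[name] = NodeSpec(name, str(kind), children=children)
        return name

    root_kind = rng.choice(["and", "or", "union"])
    children = tuple(make_node(max_depth - 1) for _ in range(int(rng.integers(2, 4))))
    root = fresh(root_kind)
    nodes[root] = NodeSpec(root, str(root_kind), children=children)
    return LogicTree("random", nodes), variables
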