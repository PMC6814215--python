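"""Cross-member ensemble reducers, the variability (uncertainty) layer, and
area-weighted scenario summaries.

An ensemble is the set of results for one scenario and time period across N
climate futures.  Reduction happens only after the logic tree has been
evaluated independently per member: min/mean/max layers bracket the spread,
and the *high variability* layer maps the per-cell population standard
deviation into fuzzy space with thresholds 0 (the minimum possible standard
deviation) and 0.5 (the maximum possible for values confined to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fuzzyrisk.fuzzy import ConversionSpec, FuzzyLayer, convert_linear
from fuzzyrisk.grid_io import EnsembleStack, GridSpec, RasterLayer

__all__ = [
    "VARIABILITY_SPEC",
    "ScenarioSummary",
    "reduce_stack",
    "high_variability",
    "area_weighted_mean",
    "scenario_summary",
    "scenario_pair_uncertainty",
    "stack_from_layers",
]

#: Standard deviation -> fuzzy truth: 0 is fully false, 0.5 (the maximum a
#: [0, 1]-valued ensemble can attain) is fully true.
VARIABILITY_SPEC = ConversionSpec(0.0, 0.5)

_REDUCERS = {
    "min": lambda v: v.min(axis=0),
    "mean": lambda v: v.mean(axis=0),
    "max": lambda v: v.max(axis=0),
}


@dataclass(frozen=True)
class ScenarioSummary:
    """Area-weighted scalar summaries of one scenario/period ensemble."""

    mean: float
    min: float
    max: float
    uncertainty: float
    member_means: dict  # member_id -> area-weighted mean

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError("summary must satisfy min <= mean <= max")


def stack_from_layers(layers, member_ids, variable_name: str = "") -> EnsembleStack:
    """Assemble an :class:`EnsembleStack` from per-member fuzzy layers."""
    layers = list(layers)
    grid = layers[0].grid
    for layer in layers[1:]:
        grid.require_same(layer.grid, "stack_from_layers")
    values = np.stack([layer.values for layer in layers])
    return EnsembleStack(grid, tuple(member_ids), values, variable_name)


def reduce_stack(stack: EnsembleStack, stat: str) -> FuzzyLayer:
    """Per-cell min, mean, or max across ensemble members."""
    if stat not in _REDUCERS:
        raise ValueError(f"stat must be one of {sorted(_REDUCERS)}, got {stat!r}")
    if stack.n_members < 1:
        raise ValueError("empty stack")
    values = _REDUCERS[stat](stack.values)
    name = f"{stack.variable_name or 'stack'}_{stat}"
    return FuzzyLayer(stack.grid, values, name, "fuzzy truth")


def high_variability(stack: EnsembleStack, ddof: int = 0) -> FuzzyLayer:
    """Fuzzified cross-member standard deviation (the uncertainty layer).

    Population standard deviation (``ddof=0``) is the default: it is the
    only variant whose maximum over [0, 1]-valued members is exactly 0.5
    (half the members at 0, half at 1), matching the fully-true threshold.
    ``ddof=1`` is accepted for sensitivity analyses.
    """
    if stack.n_members < 2:
        raise ValueError("high_variability requires at least 2 members")
    sd = np.std(stack.values, axis=0, ddof=ddof)
    raw = RasterLayer(stack.grid, sd, "ensemble_sd", "fuzzy-truth sd")
    out = convert_linear(raw, VARIABILITY_SPEC)
    return FuzzyLayer(out.grid, out.values, "high_variability", "fuzzy truth")


def area_weighted_mean(layer: RasterLayer, grid: GridSpec | None = None) -> float:
    """Weighted spatial mean over valid cells: sum(w*v) / sum(w)."""
    grid = grid or layer.grid
    grid.require_same(layer.grid, "area_weighted_mean")
    mask = grid.valid_mask
    weights = grid.cell_area_weights[mask]
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total weight over valid cells")
    return float((weights * layer.values[mask]).sum() / total)


def scenario_summary(root_stack: EnsembleStack, grid: GridSpec | None = None) -> ScenarioSummary:
    """Regional summary of a root-node ensemble.

    Area-weighted means of the mean/min/max reductions and of the
    high-variability layer, plus the per-member area-weighted means.
    """
    grid = grid or root_stack.grid
    member_means = {
        member_id: area_weighted_mean(layer, grid)
        for member_id, layer in root_stack.layers()
    }
    return ScenarioSummary(
        mean=area_weighted_mean(reduce_stack(root_stack, "mean"), grid),
        min=area_weighted_mean(reduce_stack(root_stack, "min"), grid),
        max=area_weighted_mean(reduce_stack(root_stack, "max"), grid),
        uncertainty=area_weighted_mean(high_variability(root_stack), grid),
        member_means=member_means,
    )


def scenario_pair_uncertainty(
    stack_a: EnsembleStack,
    stack_b: EnsembleStack,
    method: str = "paired",
) -> float:
    """Uncertainty attributable to the choice between two scenarios.

    ``paired`` (default): members are matched one-to-one by id (the same
    climate futures drive both scenarios); per pair and cell the population
    standard deviation of the two values is ``|a - b| / 2``, which fuzzified
    with thresholds (0, 0.5) is ``min(|a - b|, 1)``; pair means are averaged
    across members and then area-weighted over cells.

    ``pooled``: the two stacks are concatenated into one 2N-member ensemble
    and its high-variability layer is area-weighted.
    """
    stack_a.grid.require_same(stack_b.grid, "scenario_pair_uncertainty")
    if set(stack_a.member_ids) != set(stack_b.member_ids):
        raise ValueError("unmatched member ids between scenarios")
    order = [stack_b.member_ids.index(m) for m in stack_a.member_ids]
    b_values = stack_b.values[order]
    if method == "paired":
        diff = np.clip(np.abs(stack_a.values - b_values), 0.0, 1.0)
        layer = FuzzyLayer(
            stack_a.grid, diff.mean(axis=0), "pair_uncertainty", "fuzzy truth"
        )
        return area_weighted_mean(layer)
    if method == "pooled":
        pooled = EnsembleStack(
            stack_a.grid,
            tuple(f"a:{m}" for m in stack_a.member_ids)
            + tuple(f"b:{m}" for m in stack_a.member_ids),
            np.concatenate([stack_a.values, b_values]),
            stack_a.variable_name,
        )
        return area_weighted_mean(high_variability(pooled))
    raise ValueError(f"unknown method {method!r}")
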