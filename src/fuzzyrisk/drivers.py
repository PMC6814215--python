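"""Fire-vs-mortality driver attribution for the biomass-loss-risk model.

The model-only risk node is an Or of a fire branch and a mortality branch,
so each cell's risk can be attributed to whichever branch supplies the
larger value.  This module produces the difference maps, the zero-risk /
fire-dominated / mortality-dominated area fractions, per-ensemble dominance
counts, each member's share of the ensemble extremes, and the per-member
climate deltas those extremes are compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from fuzzyrisk.ensemble import area_weighted_mean
from fuzzyrisk.fuzzy import FuzzyLayer
from fuzzyrisk.grid_io import EnsembleStack, GridSpec, RasterLayer

__all__ = [
    "DominanceSummary",
    "MemberExtremes",
    "driver_difference",
    "dominance_summary",
    "ensemble_dominance_counts",
    "member_extremes",
    "climate_deltas",
]


@dataclass(frozen=True)
class DominanceSummary:
    """Area fractions: zero risk / fire-dominated / mortality-dominated.

    Computed over the total valid area, so the three fractions sum to 1.
    """

    zero_fraction: float
    fire_fraction: float
    mortality_fraction: float

    def __post_init__(self) -> None:
        total = self.zero_fraction + self.fire_fraction + self.mortality_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"dominance fractions must sum to 1, got {total}")
        for f in (self.zero_fraction, self.fire_fraction, self.mortality_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class MemberExtremes:
    """Fractions of valid area where one member attains the ensemble extremes."""

    member_id: str
    frac_at_max: float
    frac_at_min: float

    def __post_init__(self) -> None:
        for f in (self.frac_at_max, self.frac_at_min):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")


def driver_difference(fire: FuzzyLayer, mortality: FuzzyLayer) -> RasterLayer:
    """Per-cell fire risk minus mortality risk, in [-1, 1].

    For ensembles, take the ensemble mean of each branch before differencing.
    Positive cells are fire-driven, negative cells mortality-driven;
    magnitudes are largest where one branch is high and the other low.
    """
    fire.grid.require_same(mortality.grid, "driver_difference")
    return RasterLayer(
        fire.grid,
        fire.values - mortality.values,
        "fire_minus_mortality",
        "fuzzy-truth difference",
    )


def dominance_summary(
    fire: FuzzyLayer,
    mortality: FuzzyLayer,
    risk: FuzzyLayer,
    grid: GridSpec | None = None,
    weighted: bool = False,
) -> DominanceSummary:
    """Classify the study area by risk driver.

    Cells where the model-only risk node is exactly 0 count as zero-risk
    (the final And makes exact zeros common); among the rest, a cell is
    fire-dominated where fire > mortality and mortality-dominated where
    mortality > fire, with exact ties split half-and-half so the three
    fractions always sum to 1.  Plain cell counts by default; area weights
    optional.
    """
    grid = grid or risk.grid
    grid.require_same(fire.grid, "dominance_summary")
    grid.require_same(mortality.grid, "dominance_summary")
    grid.require_same(risk.grid, "dominance_summary")
    mask = grid.valid_mask
    weights = grid.cell_area_weights[mask] if weighted else np.ones(mask.sum())
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total weight over valid cells")
    r = risk.values[mask]
    f = fire.values[mask]
    m = mortality.values[mask]
    zero = r == 0.0
    fire_dom = ~zero & (f > m)
    mort_dom = ~zero & (m > f)
    tie = ~zero & (f == m)
    return DominanceSummary(
        zero_fraction=float(weights[zero].sum() / total),
        fire_fraction=float((weights[fire_dom].sum() + 0.5 * weights[tie].sum()) / total),
        mortality_fraction=float(
            (weights[mort_dom].sum() + 0.5 * weights[tie].sum()) / total
        ),
    )


def ensemble_dominance_counts(summaries) -> tuple[int, int]:
    """Count ensemble members dominated by fire vs by mortality.

    A member is fire-dominated when its fire-dominated area fraction exceeds
    its mortality-dominated fraction, and vice versa.  Exact member-level
    ties count to the fire side with a warning (they are measure-zero on
    continuous data).
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("at least one member summary required")
    fire_count = 0
    mortality_count = 0
    for s in summaries:
        if s.fire_fraction > s.mortality_fraction:
            fire_count += 1
        elif s.mortality_fraction > s.fire_fraction:
            mortality_count += 1
        else:
            warnings.warn("member tied between fire and mortality; counted as fire")
            fire_count += 1
    return fire_count, mortality_count


def member_extremes(stack: EnsembleStack, grid: GridSpec | None = None) -> list:
    """Each member's share of the per-cell ensemble maximum and minimum.

    For every member, the weighted fraction of valid cells where its value
    equals the cross-member max (resp. min).  Ties credit every attaining
    member, so each extremum is covered by at least one member everywhere
    and fractions can exceed 1/N (identical members all score 1).
    """
    if stack.n_members < 2:
        raise ValueError("member_extremes requires at least 2 members")
    grid = grid or stack.grid
    grid.require_same(stack.grid, "member_extremes")
    mask = grid.valid_mask
    weights = grid.cell_area_weights[mask]
    total = weights.sum()
    values = stack.values[:, mask]
    vmax = values.max(axis=0)
    vmin = values.min(axis=0)
    out = []
    for i, member_id in enumerate(stack.member_ids):
        at_max = values[i] == vmax
        at_min = values[i] == vmin
        out.append(
            MemberExtremes(
                member_id,
                frac_at_max=float(weights[at_max].sum() / total),
                frac_at_min=float(weights[at_min].sum() / total),
            )
        )
    return out


def climate_deltas(
    temp_future: dict,
    temp_baseline: RasterLayer,
    precip_future: dict,
    precip_baseline: RasterLayer,
    grid: GridSpec | None = None,
) -> dict:
    """Per-member area-weighted mean change in temperature and precipitation.

    ``temp_future``/``precip_future`` map member ids to future-period layers;
    the baseline layers are shared.  Returns ``member_id -> (dT, dP)``.
    """
    grid = grid or temp_baseline.grid
    grid.require_same(temp_baseline.grid, "climate_deltas")
    grid.require_same(precip_baseline.grid, "climate_deltas")
    if set(temp_future) != set(precip_future):
        raise ValueError("temperature and precipitation member ids differ")
    deltas = {}
    for member_id, t_layer in temp_future.items():
        p_layer = precip_future[member_id]
        grid.require_same(t_layer.grid, "climate_deltas")
        grid.require_same(p_layer.grid, "climate_deltas")
        dt = area_weighted_mean(
            RasterLayer(grid, t_layer.values - temp_baseline.values, "dT"), grid
        )
        dp = area_weighted_mean(
            RasterLayer(grid, p_layer.values - precip_baseline.values, "dP"), grid
        )
        deltas[member_id] = (dt, dp)
    return deltas
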