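"""End-to-end orchestration: thresholds, ensemble evaluation, reductions,
uncertainty, driver attribution, and cross-scenario comparison tables.

``run_scenario`` evaluates the logic tree independently for every ensemble
member of one scenario/period, reduces the root node to mean/min/max and
uncertainty layers, and computes the driver products.  ``compare_scenarios``
assembles the regional summary, pairwise scenario uncertainty, dominance,
and extremes-vs-climate-delta tables across runs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fuzzyrisk.drivers import (
    DominanceSummary,
    climate_deltas,
    dominance_summary,
    driver_difference,
    ensemble_dominance_counts,
    member_extremes,
)
from fuzzyrisk.ensemble import (
    ScenarioSummary,
    area_weighted_mean,
    high_variability,
    reduce_stack,
    scenario_pair_uncertainty,
    scenario_summary,
    stack_from_layers,
)
from fuzzyrisk.fuzzy import ConversionSpec, FuzzyLayer
from fuzzyrisk.grid_io import EnsembleStack, GridSpec, RasterLayer, write_layer
from fuzzyrisk.tree import LogicTree, load_tree, default_tree_path
from fuzzyrisk.vegetation import departure_layer, modal_vegtype
from fuzzyrisk.synthetic import SyntheticBundle, read_bundle

__all__ = [
    "PAPER_THRESHOLDS",
    "RunConfig",
    "ScenarioResult",
    "derive_thresholds",
    "derive_threshold_profile",
    "vegetation_stress_stack",
    "run_scenario",
    "compare_scenarios",
]

#: Frozen threshold profile as originally published (false = 10th pctile,
#: true = 90th pctile of the source baseline distributions, departure fixed
#: at 0-3).  Selectable when the real baseline rasters are unavailable.
PAPER_THRESHOLDS = {
    "mc2_biomass_burned": ConversionSpec(0.0, 110.0),
    "mc2_fire_frequency": ConversionSpec(0.0, 1.0),
    "mc2_biomass": ConversionSpec(31572.0, 73148.0),
    "mc2_live_biomass": ConversionSpec(5839.0, 29387.0),
    "observed_biomass": ConversionSpec(4053.0, 21844.0),
    "mc2_vegetation_stress": ConversionSpec(0.0, 3.0),
}

#: Nodes whose reduced layers are written as map products.
_MAP_NODES = ("biomass_loss_risk", "fire_loss_risk", "mortality_risk")


def derive_thresholds(
    baseline_layer: RasterLayer, p_false: float = 10.0, p_true: float = 90.0
) -> ConversionSpec:
    """Conversion thresholds from baseline-period percentiles.

    Linear-interpolation percentiles over valid cells; raises on degenerate
    (constant) layers where the two percentiles coincide.
    """
    if not (0.0 <= p_false < p_true <= 100.0):
        raise ValueError("percentiles must satisfy 0 <= p_false < p_true <= 100")
    values = baseline_layer.valid_values
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("degenerate baseline layer: needs >= 2 distinct values")
    lo, hi = np.percentile(values, [p_false, p_true], method="linear")
    if lo == hi:
        raise ValueError("degenerate thresholds: percentiles coincide")
    return ConversionSpec(float(lo), float(hi))


def derive_threshold_profile(
    bundle: SyntheticBundle, p_false: float = 10.0, p_true: float = 90.0
) -> dict:
    """Derive the full per-variable profile from a bundle's baseline layers.

    The four simulated variables use the baseline-period layers, observed
    biomass uses its own distribution, and vegetation stress keeps the fixed
    (0, 3) departure conversion.
    """
    profile = {
        var: derive_thresholds(bundle.baseline[var], p_false, p_true)
        for var in (
            "mc2_biomass_burned",
            "mc2_fire_frequency",
            "mc2_biomass",
            "mc2_live_biomass",
        )
    }
    profile["observed_biomass"] = derive_thresholds(
        bundle.observed_biomass, p_false, p_true
    )
    profile["mc2_vegetation_stress"] = ConversionSpec(0.0, 3.0)
    return profile


def vegetation_stress_stack(
    bundle: SyntheticBundle, scenario: str, period: str
) -> EnsembleStack:
    """Per-member departure layers (raw 0-3 values) for one scenario/period."""
    baseline_mode = modal_vegtype(bundle.baseline_veg_series)
    layers = []
    for series in bundle.veg_series[(scenario, period)]:
        future_mode = modal_vegtype(series)
        layers.append(departure_layer(baseline_mode, future_mode, bundle.departure_table))
    return stack_from_layers(layers, bundle.member_ids, "mc2_vegetation_stress")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``threshold_profile`` is ``"paper"`` (the frozen published profile),
    ``"derived"`` (percentiles of the bundle's baseline layers), or an
    explicit mapping of variable name to :class:`ConversionSpec`.
    """

    manifest_path: str | None = None
    tree_path: str | None = None
    threshold_profile: object = "derived"
    p_false: float = 10.0
    p_true: float = 90.0
    weighted: bool = False
    sd_ddof: int = 0
    pair_method: str = "paired"
    out_dir: str | None = None
    _bundle: SyntheticBundle | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_false < self.p_true <= 100.0):
            raise ValueError("percentiles must satisfy 0 <= p_false < p_true <= 100")

    @property
    def bundle(self) -> SyntheticBundle:
        if self._bundle is None:
            if self.manifest_path is None:
                raise ValueError("RunConfig needs a manifest_path or a bundle")
            self._bundle = read_bundle(self.manifest_path)
        return self._bundle

    def tree(self) -> LogicTree:
        tree = load_tree(self.tree_path or default_tree_path())
        if self.threshold_profile == "paper":
            return tree.with_thresholds(PAPER_THRESHOLDS)
        if self.threshold_profile == "derived":
            return tree.with_thresholds(
                derive_threshold_profile(self.bundle, self.p_false, self.p_true)
            )
        return tree.with_thresholds(dict(self.threshold_profile))

    def digest(self) -> str:
        payload = repr(
            (
                self.manifest_path,
                self.tree_path,
                str(self.threshold_profile),
                self.p_false,
                self.p_true,
                self.weighted,
                self.sd_ddof,
                self.pair_method,
            )
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ScenarioResult:
    """All products of one scenario/period run."""

    scenario: str
    period: str
    member_results: dict  # member_id -> TreeResult
    root_stack: EnsembleStack
    reductions: dict  # node -> {"min"/"mean"/"max"/"uncertainty" -> FuzzyLayer}
    summary: ScenarioSummary
    fire_mean: FuzzyLayer
    mortality_mean: FuzzyLayer
    driver_diff: RasterLayer
    member_dominance: dict  # member_id -> DominanceSummary
    dominance_counts: tuple[int, int]
    extremes: list  # MemberExtremes of the model-only risk node
    deltas: dict  # member_id -> (dT, dP)

    def node_stack(self, node: str) -> EnsembleStack:
        return stack_from_layers(
            [self.member_results[m].layers[node] for m in self.root_stack.member_ids],
            self.root_stack.member_ids,
            node,
        )


def _node_stacks(member_results: dict, member_ids, node: str) -> EnsembleStack:
    return stack_from_layers(
        [member_results[m].layers[node] for m in member_ids], member_ids, node
    )


def run_scenario(config: RunConfig, scenario: str, period: str) -> ScenarioResult:
    """Run the full analysis for one scenario and time period.

    Evaluates the tree per ensemble member, reduces the root and driver
    nodes, computes dominance and extremes, and (when ``out_dir`` is set)
    writes the map and table products plus a provenance record.
    """
    bundle = config.bundle
    tree = config.tree()
    key = (scenario, period)
    if key not in bundle.stacks:
        raise KeyError(f"missing input: no stacks for scenario/period {key}")

    stacks = dict(bundle.stacks[key])
    stacks["mc2_vegetation_stress"] = vegetation_stress_stack(bundle, scenario, period)
    grid = bundle.grid
    eval_grid = grid
    shared = {"observed_biomass": bundle.observed_biomass}
    member_results = tree.evaluate_ensemble(stacks, shared)
    member_ids = bundle.member_ids

    root = tree.root
    reductions: dict = {}
    for node in _MAP_NODES:
        if node not in member_results[member_ids[0]].layers:
            continue
        node_stack = _node_stacks(member_results, member_ids, node)
        reductions[node] = {
            "min": reduce_stack(node_stack, "min"),
            "mean": reduce_stack(node_stack, "mean"),
            "max": reduce_stack(node_stack, "max"),
            "uncertainty": high_variability(node_stack, ddof=config.sd_ddof),
        }

    root_stack = _node_stacks(member_results, member_ids, root)
    summary = scenario_summary(root_stack, eval_grid)

    # driver attribution on the model-only branch (without the observed gate)
    fire_stack = _node_stacks(member_results, member_ids, "fire_loss_risk")
    mort_stack = _node_stacks(member_results, member_ids, "mortality_risk")
    mc2_stack = _node_stacks(member_results, member_ids, "mc2_biomass_loss_risk")
    fire_mean = reduce_stack(fire_stack, "mean")
    mortality_mean = reduce_stack(mort_stack, "mean")
    diff = driver_difference(fire_mean, mortality_mean)
    member_dominance = {
        m: dominance_summary(
            member_results[m].layers["fire_loss_risk"],
            member_results[m].layers["mortality_risk"],
            member_results[m].layers["mc2_biomass_loss_risk"],
            grid,
            weighted=config.weighted,
        )
        for m in member_ids
    }
    counts = ensemble_dominance_counts(member_dominance.values())
    extremes = member_extremes(mc2_stack, eval_grid)

    result = ScenarioResult(
        scenario=scenario,
        period=period,
        member_results=member_results,
        root_stack=root_stack,
        reductions=reductions,
        summary=summary,
        fire_mean=fire_mean,
        mortality_mean=mortality_mean,
        driver_diff=diff,
        member_dominance=member_dominance,
        dominance_counts=counts,
        extremes=extremes,
        deltas=dict(bundle.deltas.get(key, {})),
    )
    if config.out_dir:
        _write_products(config, result)
    return result


def _write_products(config: RunConfig, result: ScenarioResult) -> None:
    out = os.path.join(config.out_dir, f"{result.scenario}_{result.period}")
    os.makedirs(out, exist_ok=True)
    for node, stats in result.reductions.items():
        for stat, layer in stats.items():
            write_layer(layer, os.path.join(out, f"{node}_{stat}.tif"))
    write_layer(result.driver_diff, os.path.join(out, "fire_minus_mortality.tif"))

    s = result.summary
    pd.DataFrame(
        [
            {
                "scenario": result.scenario,
                "period": result.period,
                "mean": s.mean,
                "min": s.min,
                "max": s.max,
                "uncertainty": s.uncertainty,
                **{f"member_{m}": v for m, v in s.member_means.items()},
            }
        ]
    ).to_csv(os.path.join(out, "summary.csv"), index=False)

    pd.DataFrame(
        [
            {
                "member_id": m,
                "zero_fraction": d.zero_fraction,
                "fire_fraction": d.fire_fraction,
                "mortality_fraction": d.mortality_fraction,
            }
            for m, d in result.member_dominance.items()
        ]
    ).to_csv(os.path.join(out, "dominance.csv"), index=False)

    deltas = result.deltas
    pd.DataFrame(
        [
            {
                "member_id": e.member_id,
                "d_temperature": deltas.get(e.member_id, (np.nan, np.nan))[0],
                "d_precipitation": deltas.get(e.member_id, (np.nan, np.nan))[1],
                "frac_at_max": e.frac_at_max,
                "frac_at_min": e.frac_at_min,
            }
            for e in result.extremes
        ]
    ).to_csv(os.path.join(out, "extremes.csv"), index=False)

    from fuzzyrisk import __version__

    with open(os.path.join(out, "provenance.json"), "w") as fh:
        json.dump(
            {
                "config_digest": config.digest(),
                "scenario": result.scenario,
                "period": result.period,
                "version": __version__,
                "numpy": np.__version__,
            },
            fh,
            indent=2,
            sort_keys=True,
        )


def compare_scenarios(results: dict) -> dict:
    """Cross-scenario comparison tables from ``(scenario, period) -> result``.

    Returns data frames: ``summary`` (regional mean/min/max/uncertainty per
    scenario and period), ``pair_uncertainty`` (forcing-pathway and
    fire-suppression pairings sharing climate futures), ``dominance``
    (min/max/mean of the three area fractions across members), ``counts``
    (fire- vs mortality-dominated member counts), and ``extremes``
    (per-member climate deltas vs shares of the ensemble extremes).
    """
    if len(results) < 2:
        raise ValueError("compare_scenarios needs at least 2 results")
    member_ids = None
    for res in results.values():
        ids = res.root_stack.member_ids
        if member_ids is None:
            member_ids = ids
        elif set(ids) != set(member_ids):
            raise ValueError("member mismatch across scenario results")

    summary_rows = []
    dominance_rows = []
    counts_rows = []
    extremes_rows = []
    for (scen, period), res in sorted(results.items()):
        s = res.summary
        summary_rows.append(
            {
                "scenario": scen,
                "period": period,
                "mean": s.mean,
                "min": s.min,
                "max": s.max,
                "uncertainty": s.uncertainty,
            }
        )
        fracs = {
            "zero": [d.zero_fraction for d in res.member_dominance.values()],
            "fire": [d.fire_fraction for d in res.member_dominance.values()],
            "mortality": [d.mortality_fraction for d in res.member_dominance.values()],
        }
        dominance_rows.append(
            {
                "scenario": scen,
                "period": period,
                **{
                    f"{k}_{stat}": float(getattr(np, stat)(v))
                    for k, v in fracs.items()
                    for stat in ("min", "max", "mean")
                },
            }
        )
        counts_rows.append(
            {
                "scenario": scen,
                "period": period,
                "fire_dominated": res.dominance_counts[0],
                "mortality_dominated": res.dominance_counts[1],
            }
        )
        for e in res.extremes:
            dt, dp = res.deltas.get(e.member_id, (np.nan, np.nan))
            extremes_rows.append(
                {
                    "scenario": scen,
                    "period": period,
                    "member_id": e.member_id,
                    "d_temperature": dt,
                    "d_precipitation": dp,
                    "frac_at_max": e.frac_at_max,
                    "frac_at_min": e.frac_at_min,
                }
            )

    pair_rows = []
    keys = set(results)
    for (ka, kb, label) in _scenario_pairs(keys):
        value = scenario_pair_uncertainty(
            results[ka].root_stack, results[kb].root_stack
        )
        pair_rows.append(
            {"pair": label, "period": ka[1], "uncertainty": value}
        )

    return {
        "summary": pd.DataFrame(summary_rows),
        "pair_uncertainty": pd.DataFrame(pair_rows),
        "dominance": pd.DataFrame(dominance_rows),
        "counts": pd.DataFrame(counts_rows),
        "extremes": pd.DataFrame(extremes_rows),
    }


def _scenario_pairs(keys):
    """Pathway (4.5 vs 8.5) and suppression (FS vs NFS) pairings per period.

    Works on the default scenario naming ``<pathway>_<suppression>``; other
    names simply yield no pairs.
    """
    parsed = {}
    for scen, period in keys:
        if "_" not in scen:
            continue
        pathway, suppression = scen.rsplit("_", 1)
        parsed[(pathway, suppression, period)] = (scen, period)
    pairs = []
    pathways = sorted({p for p, _, _ in parsed})
    suppressions = sorted({s for _, s, _ in parsed})
    periods = sorted({t for _, _, t in parsed})
    if len(pathways) == 2:
        for supp in suppressions:
            for t in periods:
                a = parsed.get((pathways[0], supp, t))
                b = parsed.get((pathways[1], supp, t))
                if a and b:
                    pairs.append((a, b, f"{pathways[0]} vs {pathways[1]}, {supp}"))
    if len(suppressions) == 2:
        for pathway in pathways:
            for t in periods:
                a = parsed.get((pathway, suppressions[0], t))
                b = parsed.get((pathway, suppressions[1], t))
                if a and b:
                    pairs.append(
                        (a, b, f"{suppressions[0]} vs {suppressions[1]}, {pathway}")
                    )
    return pairs
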