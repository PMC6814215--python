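"""Synthetic gridded ensembles with the statistical structure the analysis assumes.

Stands in for the undeposited vegetation-model output: per scenario and time
period, 20-member ensembles of biomass burned, fire frequency, total and
live biomass, annual vegetation-type codes, and per-member climate deltas,
plus baseline-period layers for threshold derivation and an observed-biomass
layer with a configurable zero fraction (default 11%).

Construction sketch (deterministic given one seed; per-member and per-stage
substreams are derived from fixed offsets so member counts can change
without reshuffling everything else):

* smooth latent fields (kernel-smoothed noise) for elevation, coastal
  proximity, and productivity define the landscape;
* baseline biomass increases with productivity, live biomass is a fraction
  of it; baseline fire increases with dryness and decreases with coastal
  proximity;
* each member draws a temperature factor and a precipitation anomaly; a
  scenario's forcing multiplier and the period's ramp scale the member's
  warming, fire variables respond exponentially to warming (and to the
  no-fire-suppression multiplier), vegetation types are bins of a climate
  index so warming shifts bins and produces nonzero departures;
* observed biomass is baseline biomass times lognormal noise with exactly
  ``ceil(zero_biomass_fraction * n_valid)`` lowest-productivity cells set
  to 0.

Latent driver fields are returned alongside the data (test-only) so
monotonicity tests need not peek at pipeline internals.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from fuzzyrisk.grid_io import (
    DepartureTable,
    EnsembleStack,
    GridSpec,
    RasterLayer,
    write_departure_table,
    load_departure_table,
    read_layer,
    read_stack,
    write_layer,
    write_stack,
)
from fuzzyrisk.vegetation import VegTypeSeries

__all__ = [
    "ScenarioSpec",
    "SyntheticConfig",
    "SyntheticBundle",
    "generate",
    "write_bundle",
    "read_bundle",
    "default_departure_table",
]

#: Ensemble variables produced per scenario and period.
STACK_VARIABLES = (
    "mc2_biomass_burned",
    "mc2_fire_frequency",
    "mc2_biomass",
    "mc2_live_biomass",
)

#: Ramp of the forcing through the century, per period label.
PERIOD_SCALES = {"early": 0.35, "mid": 0.7, "late": 1.0}


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario: a CO2-forcing analog and a fire-suppression analog."""

    name: str
    co2_forcing: float  # warming multiplier (high-pathway analog > moderate)
    fire_multiplier: float  # >1 without assumed fire suppression


DEFAULT_SCENARIOS = (
    ScenarioSpec("rcp45_fs", co2_forcing=1.0, fire_multiplier=1.0),
    ScenarioSpec("rcp45_nfs", co2_forcing=1.0, fire_multiplier=1.25),
    ScenarioSpec("rcp85_fs", co2_forcing=1.7, fire_multiplier=1.0),
    ScenarioSpec("rcp85_nfs", co2_forcing=1.7, fire_multiplier=1.25),
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_rows: int = 100
    n_cols: int = 100
    n_members: int = 20
    periods: tuple[str, ...] = ("early", "mid", "late")
    scenarios: tuple[ScenarioSpec, ...] = DEFAULT_SCENARIOS
    zero_biomass_fraction: float = 0.11
    smoothing_scale: float = 5.0
    member_spread: float = 1.0
    n_veg_years: int = 10
    mask_style: str = "ellipse"  # or "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("n_members must be >= 2")
        if not (0.0 <= self.zero_biomass_fraction < 1.0):
            raise ValueError("zero_biomass_fraction must lie in [0, 1)")
        if self.member_spread < 0:
            raise ValueError("member_spread must be nonnegative")
        for p in self.periods:
            if p not in PERIOD_SCALES:
                raise ValueError(f"unknown period {p!r}; known: {sorted(PERIOD_SCALES)}")
        names = [s.name for s in self.scenarios]
        if len(set(names)) != len(names):
            raise ValueError("scenario names must be unique")
        if self.mask_style not in ("ellipse", "full"):
            raise ValueError("mask_style must be 'ellipse' or 'full'")


@dataclass
class SyntheticBundle:
    """Everything one analysis run consumes, plus latent fields for tests."""

    config: SyntheticConfig
    grid: GridSpec
    member_ids: tuple[str, ...]
    departure_table: DepartureTable
    observed_biomass: RasterLayer
    baseline: dict  # variable -> RasterLayer (incl. temperature, precipitation)
    baseline_veg_series: VegTypeSeries
    stacks: dict  # (scenario, period) -> {variable -> EnsembleStack}
    veg_series: dict  # (scenario, period) -> [VegTypeSeries per member]
    climate: dict  # (scenario, period) -> {"temperature"/"precipitation" -> EnsembleStack}
    deltas: dict  # (scenario, period) -> {member_id -> (dT, dP)}
    latent: dict = field(default_factory=dict)  # test-only driver fields

    @property
    def scenario_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.config.scenarios)


def default_departure_table(n_types: int = 5) -> DepartureTable:
    """Synthetic expert table: departure grows with bin distance, capped at 3."""
    codes = tuple(range(1, n_types + 1))
    entries = {
        (a, b): float(min(3, abs(a - b)))
        for a in codes
        for b in codes
    }
    return DepartureTable(codes, entries)


def _stream_key(token) -> int:
    # process-independent hash (builtin hash() is salted per run)
    digest = hashlib.sha256(repr(token).encode()).digest()
    return int.from_bytes(digest[:4], "little")


def _rng(config: SyntheticConfig, *stream) -> np.random.Generator:
    # fixed-offset substreams: one root seed, stable per named stage/member
    return np.random.default_rng([config.seed, *(_stream_key(s) for s in stream)])


def _smooth_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Kernel-smoothed standard-normal field (unit variance after smoothing)."""
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=scale, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _veg_codes(climate_index: np.ndarray, codes: tuple[int, ...]) -> np.ndarray:
    """Bin a climate index into vegetation-type codes (warmer -> higher bin)."""
    # bin edges chosen so the baseline index (roughly N(10, 2^2) over the
    # landscape) spreads across all types
    edges = np.array([7.0, 9.0, 11.0, 13.0])
    binned = np.digitize(climate_index, edges) + codes[0]
    return np.clip(binned, codes[0], codes[-1])


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a deterministic synthetic bundle for the given config."""
    shape = (config.n_rows, config.n_cols)

    if config.mask_style == "ellipse":
        r = (np.arange(config.n_rows)[:, None] - (config.n_rows - 1) / 2) / (config.n_rows / 2)
        c = (np.arange(config.n_cols)[None, :] - (config.n_cols - 1) / 2) / (config.n_cols / 2)
        mask = (r**2 + c**2) <= 1.0
    else:
        mask = np.ones(shape, dtype=bool)
    grid = GridSpec.from_mask(mask)
    n_valid = grid.n_valid

    # --- latent landscape -------------------------------------------------
    frng = _rng(config, "fields")
    scale = config.smoothing_scale
    elevation = _smooth_field(frng, shape, scale)
    productivity_raw = 0.6 * _smooth_field(frng, shape, scale) + 0.4 * elevation
    productivity = 1.0 / (1.0 + np.exp(-productivity_raw))  # squash to (0, 1)
    col_frac = np.broadcast_to(
        np.arange(config.n_cols)[None, :] / max(config.n_cols - 1, 1), shape
    )
    coastal = np.clip(
        np.exp(-3.0 * col_frac) + 0.15 * _smooth_field(frng, shape, scale), 0.0, 1.0
    )
    dryness = np.clip(0.5 * (1.0 - coastal) + 0.3 * (1.0 - productivity)
                      + 0.15 * _smooth_field(frng, shape, scale) + 0.2, 0.0, None)

    # --- baseline layers --------------------------------------------------
    base_biomass = 15000.0 + 70000.0 * productivity
    base_live = base_biomass * (0.25 + 0.15 * productivity)
    base_temp = 10.0 + 2.0 * elevation * (-1.0) + 1.5 * (1.0 - coastal)
    base_precip = 1200.0 + 1500.0 * coastal + 300.0 * np.clip(elevation, 0, None)
    base_burned = 60.0 * dryness
    base_freq = np.clip(0.45 * dryness, 0.0, 1.0)

    def layer(values, name, units=""):
        return RasterLayer(grid, np.where(mask, values, np.nan), name, units)

    baseline = {
        "mc2_biomass_burned": layer(base_burned, "mc2_biomass_burned", "g C m-2"),
        "mc2_fire_frequency": layer(base_freq, "mc2_fire_frequency", "fraction"),
        "mc2_biomass": layer(base_biomass, "mc2_biomass", "g C m-2"),
        "mc2_live_biomass": layer(base_live, "mc2_live_biomass", "g C m-2"),
        "temperature": layer(base_temp, "temperature", "deg C"),
        "precipitation": layer(base_precip, "precipitation", "mm"),
    }

    # --- observed biomass with an exact zero fraction ---------------------
    orng = _rng(config, "observed")
    observed = base_biomass * orng.lognormal(mean=0.0, sigma=0.3, size=shape)
    n_zero = math.ceil(config.zero_biomass_fraction * n_valid)
    if n_zero > 0:
        prod_valid = productivity[mask]
        zero_order = np.argsort(prod_valid, kind="stable")[:n_zero]
        flat_idx = np.flatnonzero(mask.ravel())[zero_order]
        observed_flat = observed.ravel().copy()
        observed_flat[flat_idx] = 0.0
        observed = observed_flat.reshape(shape)
    observed_layer = layer(observed, "observed_biomass", "g C m-2")

    # --- members ----------------------------------------------------------
    member_ids = tuple(f"cf{i:02d}" for i in range(config.n_members))
    mrng = _rng(config, "members")
    temp_factor = 1.0 + 0.35 * config.member_spread * mrng.standard_normal(config.n_members)
    temp_factor = np.clip(temp_factor, 0.1, None)
    precip_anom = 180.0 * mrng.standard_normal(config.n_members)  # mixed sign
    member_pattern = np.stack(
        [
            _smooth_field(_rng(config, "member_pattern", i), shape, scale)
            for i in range(config.n_members)
        ]
    )

    table = default_departure_table()
    codes = table.codes

    # baseline vegetation: historical annual series around the base index
    years = tuple(range(1, config.n_veg_years + 1))
    bvrng = _rng(config, "veg_baseline")
    base_veg = np.stack(
        [
            _veg_codes(base_temp + 0.5 * bvrng.standard_normal(shape), codes)
            for _ in years
        ]
    )
    baseline_veg_series = VegTypeSeries(grid, years, np.where(mask, base_veg, -1))

    stacks: dict = {}
    veg_series: dict = {}
    climate: dict = {}
    deltas: dict = {}

    for scen in config.scenarios:
        for period in config.periods:
            key = (scen.name, period)
            ramp = PERIOD_SCALES[period]
            burned_m = np.empty((config.n_members,) + shape)
            freq_m = np.empty_like(burned_m)
            biomass_m = np.empty_like(burned_m)
            live_m = np.empty_like(burned_m)
            temp_m = np.empty_like(burned_m)
            precip_m = np.empty_like(burned_m)
            veg_members = []
            delta_map = {}
            for i, member_id in enumerate(member_ids):
                dt = 2.0 * scen.co2_forcing * ramp * temp_factor[i]
                dp = scen.co2_forcing * ramp * precip_anom[i]
                dt_field = dt + 0.4 * ramp * config.member_spread * member_pattern[i]
                temp_m[i] = base_temp + dt_field
                precip_m[i] = base_precip + dp
                fire_gain = np.exp(0.30 * dt_field) * scen.fire_multiplier
                burned_m[i] = base_burned * fire_gain
                freq_m[i] = np.clip(base_freq * np.exp(0.25 * dt_field)
                                    * scen.fire_multiplier, 0.0, 1.0)
                mem_noise = 0.03 * config.member_spread * member_pattern[i]
                biomass_m[i] = np.clip(base_biomass * (1.0 + mem_noise), 0.0, None)
                live_m[i] = np.clip(base_live * (1.0 + mem_noise), 0.0, None)
                vrng = _rng(config, "veg", scen.name, period, i)
                veg = np.stack(
                    [
                        _veg_codes(
                            base_temp + dt_field + 0.5 * vrng.standard_normal(shape),
                            codes,
                        )
                        for _ in years
                    ]
                )
                veg_members.append(
                    VegTypeSeries(grid, years, np.where(mask, veg, -1))
                )
                delta_map[member_id] = (float(dt), float(dp))
            stacks[key] = {
                "mc2_biomass_burned": EnsembleStack(
                    grid, member_ids, burned_m, "mc2_biomass_burned", "g C m-2"
                ),
                "mc2_fire_frequency": EnsembleStack(
                    grid, member_ids, freq_m, "mc2_fire_frequency", "fraction"
                ),
                "mc2_biomass": EnsembleStack(
                    grid, member_ids, biomass_m, "mc2_biomass", "g C m-2"
                ),
                "mc2_live_biomass": EnsembleStack(
                    grid, member_ids, live_m, "mc2_live_biomass", "g C m-2"
                ),
            }
            climate[key] = {
                "temperature": EnsembleStack(
                    grid, member_ids, temp_m, "temperature", "deg C"
                ),
                "precipitation": EnsembleStack(
                    grid, member_ids, precip_m, "precipitation", "mm"
                ),
            }
            veg_series[key] = veg_members
            deltas[key] = delta_map

    return SyntheticBundle(
        config=config,
        grid=grid,
        member_ids=member_ids,
        departure_table=table,
        observed_biomass=observed_layer,
        baseline=baseline,
        baseline_veg_series=baseline_veg_series,
        stacks=stacks,
        veg_series=veg_series,
        climate=climate,
        deltas=deltas,
        latent={
            "elevation": elevation,
            "productivity": productivity,
            "coastal": coastal,
            "dryness": dryness,
            "temp_factor": temp_factor,
            "precip_anom": precip_anom,
        },
    )


# ---------------------------------------------------------------------------
# on-disk bundle


def _veg_to_netcdf(series_list, path: str) -> None:
    import xarray as xr

    values = np.stack([s.values for s in series_list])  # member, year, y, x
    da = xr.DataArray(
        values.astype(np.int32),
        dims=("member", "year", "y", "x"),
        coords={"year": list(series_list[0].years)},
        name="vegtype",
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def _veg_from_netcdf(path: str, grid: GridSpec, n_members: int):
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        values = np.asarray(ds["vegtype"].values)
        years = tuple(int(y) for y in np.asarray(ds["year"].values))
    if values.shape[0] != n_members:
        raise ValueError(f"member count mismatch in {path}")
    return [VegTypeSeries(grid, years, values[i]) for i in range(values.shape[0])]


def write_bundle(bundle: SyntheticBundle, directory: str) -> str:
    """Write a bundle to ``directory``; returns the manifest path.

    Layout: baseline layers and observed biomass as GeoTIFF, ensemble
    stacks and vegetation series as NetCDF, the departure table and climate
    deltas as CSV, all listed in ``manifest.json``.
    """
    if not os.path.isdir(directory):
        raise FileNotFoundError(f"missing directory: {directory}")
    manifest: dict = {
        "member_ids": list(bundle.member_ids),
        "scenarios": [s.name for s in bundle.config.scenarios],
        "periods": list(bundle.config.periods),
        "baseline": {},
        "stacks": {},
        "climate": {},
        "veg_series": {},
        "n_veg_years": bundle.config.n_veg_years,
    }

    def rel(name: str) -> str:
        return name

    path = os.path.join(directory, "observed_biomass.tif")
    write_layer(bundle.observed_biomass, path)
    manifest["observed_biomass"] = rel("observed_biomass.tif")

    for var, lyr in bundle.baseline.items():
        fname = f"baseline_{var}.tif"
        write_layer(lyr, os.path.join(directory, fname))
        manifest["baseline"][var] = rel(fname)

    fname = "baseline_vegtype.nc"
    _veg_to_netcdf([bundle.baseline_veg_series], os.path.join(directory, fname))
    manifest["baseline_vegtype"] = rel(fname)

    for (scen, period), var_stacks in bundle.stacks.items():
        entry = {}
        for var, stack in var_stacks.items():
            fname = f"{scen}_{period}_{var}.nc"
            write_stack(stack, os.path.join(directory, fname))
            entry[var] = rel(fname)
        manifest["stacks"][f"{scen}/{period}"] = entry

    for (scen, period), var_stacks in bundle.climate.items():
        entry = {}
        for var, stack in var_stacks.items():
            fname = f"{scen}_{period}_{var}.nc"
            write_stack(stack, os.path.join(directory, fname))
            entry[var] = rel(fname)
        manifest["climate"][f"{scen}/{period}"] = entry

    for (scen, period), series_list in bundle.veg_series.items():
        fname = f"{scen}_{period}_vegtype.nc"
        _veg_to_netcdf(series_list, os.path.join(directory, fname))
        manifest["veg_series"][f"{scen}/{period}"] = rel(fname)

    write_departure_table(
        bundle.departure_table, os.path.join(directory, "departure_table.csv")
    )
    manifest["departure_table"] = rel("departure_table.csv")

    import pandas as pd

    rows = [
        {
            "scenario": scen,
            "period": period,
            "member_id": m,
            "d_temperature": dt,
            "d_precipitation": dp,
        }
        for (scen, period), dmap in bundle.deltas.items()
        for m, (dt, dp) in dmap.items()
    ]
    pd.DataFrame(rows).to_csv(os.path.join(directory, "climate_deltas.csv"), index=False)
    manifest["climate_deltas"] = rel("climate_deltas.csv")

    manifest_path = os.path.join(directory, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest_path


def read_bundle(manifest_path: str) -> SyntheticBundle:
    """Reload a bundle written by :func:`write_bundle` (latent fields empty)."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    directory = os.path.dirname(os.path.abspath(manifest_path))

    def p(name: str) -> str:
        return os.path.join(directory, name)

    observed = read_layer(p(manifest["observed_biomass"]))
    grid = observed.grid
    baseline = {
        var: read_layer(p(fname), var, grid=grid)
        for var, fname in manifest["baseline"].items()
    }
    baseline_veg = _veg_from_netcdf(p(manifest["baseline_vegtype"]), grid, 1)[0]
    member_ids = tuple(manifest["member_ids"])
    stacks: dict = {}
    climate: dict = {}
    veg_series: dict = {}
    for key, entry in manifest["stacks"].items():
        scen, period = key.split("/")
        stacks[(scen, period)] = {
            var: read_stack(p(fname), var, grid=grid) for var, fname in entry.items()
        }
    for key, entry in manifest["climate"].items():
        scen, period = key.split("/")
        climate[(scen, period)] = {
            var: read_stack(p(fname), var, grid=grid) for var, fname in entry.items()
        }
    for key, fname in manifest["veg_series"].items():
        scen, period = key.split("/")
        veg_series[(scen, period)] = _veg_from_netcdf(p(fname), grid, len(member_ids))

    import pandas as pd

    deltas: dict = {}
    df = pd.read_csv(p(manifest["climate_deltas"]))
    for row in df.itertuples():
        deltas.setdefault((row.scenario, row.period), {})[row.member_id] = (
            float(row.d_temperature),
            float(row.d_precipitation),
        )

    scenario_names = manifest["scenarios"]
    known = {s.name: s for s in DEFAULT_SCENARIOS}
    scenarios = tuple(
        known.get(name, ScenarioSpec(name, 1.0, 1.0)) for name in scenario_names
    )
    config = SyntheticConfig(
        n_rows=grid.n_rows,
        n_cols=grid.n_cols,
        n_members=len(member_ids),
        periods=tuple(manifest["periods"]),
        scenarios=scenarios,
        n_veg_years=int(manifest.get("n_veg_years", 10)),
        mask_style="full",  # mask is carried by the layers themselves
    )
    return SyntheticBundle(
        config=config,
        grid=grid,
        member_ids=member_ids,
        departure_table=load_departure_table(p(manifest["departure_table"])),
        observed_biomass=observed,
        baseline=baseline,
        baseline_veg_series=baseline_veg,
        stacks=stacks,
        veg_series=veg_series,
        climate=climate,
        deltas=deltas,
    )
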