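"""Modal vegetation type over a period and departure scoring against baseline.

The departure of a cell's modal vegetation type for a future period from its
baseline-period type, scored through an expert lookup table on [0, 3], is
the raw input behind the vegetation-stress node of the logic tree.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import xarray as xr

from fuzzyrisk.fuzzy import ConversionSpec, FuzzyLayer, convert_linear
from fuzzyrisk.grid_io import DepartureTable, GridSpec, RasterLayer

__all__ = [
    "VegTypeSeries",
    "modal_vegtype",
    "departure_layer",
    "vegetation_stress",
    "read_veg_series",
    "write_veg_series",
]

#: Conversion from departure values to vegetation stress (0 = no departure
#: fully false, 3 = maximal departure fully true).
STRESS_SPEC = ConversionSpec(0.0, 3.0)


@dataclass(frozen=True)
class VegTypeSeries:
    """Annual categorical vegetation-type codes: year x row x col."""

    grid: GridSpec
    years: tuple[int, ...]
    values: np.ndarray  # integer codes; -1 outside the valid mask

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        if len(years) < 1:
            raise ValueError("vegetation series must cover at least one year")
        values = np.asarray(self.values)
        expected = (len(years),) + self.grid.shape
        if values.shape != expected:
            raise ValueError(f"series shape {values.shape} != {expected}")
        values = np.where(self.grid.valid_mask[None, :, :], values, -1).astype(int)
        values.setflags(write=False)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)


def modal_vegtype(series: VegTypeSeries) -> RasterLayer:
    """Per-cell most frequent code over the series; ties go to the lowest code.

    The tie rule makes the result invariant to permutations of year order.
    """
    codes = np.unique(series.values[:, series.grid.valid_mask])
    codes = codes[codes >= 0]
    if codes.size == 0:
        raise ValueError("vegetation series has no valid codes")
    # counts per candidate code; argmax over codes sorted ascending gives the
    # lowest code among tied maxima
    counts = np.stack([(series.values == c).sum(axis=0) for c in codes])
    winner = codes[np.argmax(counts, axis=0)].astype(float)
    winner = np.where(series.grid.valid_mask, winner, np.nan)
    return RasterLayer(series.grid, winner, "modal_vegtype", "type code")


def departure_layer(
    baseline_mode: RasterLayer,
    future_mode: RasterLayer,
    table: DepartureTable,
) -> RasterLayer:
    """Score per-cell disparity between baseline and future modal types."""
    baseline_mode.grid.require_same(future_mode.grid, "departure_layer")
    departure = table.lookup(baseline_mode.values, future_mode.values)
    return RasterLayer(
        baseline_mode.grid, departure, "vegetation_departure", "departure value"
    )


def vegetation_stress(departure: RasterLayer) -> FuzzyLayer:
    """Fuzzify departure values with the fixed (0, 3) conversion."""
    return convert_linear(departure, STRESS_SPEC)


def read_veg_series(path: str, variable_name: str = "vegtype") -> VegTypeSeries:
    """Read a vegetation-type series from NetCDF with dims ``(year, y, x)``."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable_name not in ds:
            raise KeyError(f"variable absent: {variable_name!r} not in {path}")
        da = ds[variable_name]
        if "year" not in da.dims:
            raise ValueError(f"absent year dimension in {path}")
        da = da.transpose("year", ...)
        years = [int(y) for y in np.asarray(ds["year"].values)]
        values = np.asarray(da.values)
    mask = values[0] >= 0
    return VegTypeSeries(GridSpec.from_mask(mask), tuple(years), values)


def write_veg_series(series: VegTypeSeries, path: str, variable_name: str = "vegtype") -> None:
    da = xr.DataArray(
        series.values.astype(np.int32),
        dims=("year", "y", "x"),
        coords={"year": list(series.years)},
        name=variable_name,
    )
    da.to_dataset().to_netcdf(path, engine="scipy")
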