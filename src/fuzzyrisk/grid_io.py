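"""Grid data model and readers/writers for layers, ensemble stacks, and tables.

Every downstream module consumes the types defined here.  The model is
grid-agnostic: all inputs must be co-registered, and cross-layer operations
check shape and validity-mask equality only — no geospatial metadata is
interpreted.

On-disk conventions
-------------------
* Single 2-D layers: GeoTIFF (float32, GDAL_NODATA tag) or NetCDF (dims
  ``(y, x)``, NaN fill).
* Ensemble stacks: NetCDF with dims ``(member, y, x)`` and a ``member``
  label coordinate (NETCDF3 via the scipy backend, so no compiled NetCDF
  library is required).
* Departure lookup tables: CSV with columns
  ``baseline_type, future_type, departure``.

Layers are stored at 32-bit float width; round trips are bit-exact at that
width (compare with tolerance 1e-6 against float64 sources).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

__all__ = [
    "GridSpec",
    "RasterLayer",
    "EnsembleStack",
    "DepartureTable",
    "GridMismatchError",
    "read_layer",
    "write_layer",
    "read_stack",
    "write_stack",
    "load_departure_table",
    "write_departure_table",
]

#: TIFF tag used by GDAL to record the nodata value of a band.
GDAL_NODATA_TAG = 42113

_NETCDF_ENGINE = "scipy"
_NETCDF_SUFFIXES = (".nc", ".nc3", ".cdf", ".netcdf")


class GridMismatchError(ValueError):
    """Raised when layers on different grids enter a cross-layer operation."""


@dataclass(frozen=True)
class GridSpec:
    """Shape, validity mask, and per-cell area weights of a co-registered grid.

    Parameters
    ----------
    n_rows, n_cols :
        Grid dimensions.
    valid_mask :
        Boolean ``(n_rows, n_cols)`` array, ``True`` inside the study area.
    cell_area_weights :
        Nonnegative finite per-cell weights used by area-weighted statistics.
        Defaults to uniform weights.
    """

    n_rows: int
    n_cols: int
    valid_mask: np.ndarray = None  # type: ignore[assignment]
    cell_area_weights: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        shape = (self.n_rows, self.n_cols)
        mask = self.valid_mask
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError(f"valid_mask shape {mask.shape} != grid shape {shape}")
        if not mask.any():
            raise ValueError("grid must contain at least one valid cell")
        weights = self.cell_area_weights
        if weights is None:
            weights = np.ones(shape, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if weights.shape != shape:
            raise ValueError(f"weights shape {weights.shape} != grid shape {shape}")
        if not np.isfinite(weights).all():
            raise ValueError("cell_area_weights must be finite")
        if (weights < 0).any():
            raise ValueError("cell_area_weights must be nonnegative")
        mask.setflags(write=False)
        weights.setflags(write=False)
        object.__setattr__(self, "valid_mask", mask)
        object.__setattr__(self, "cell_area_weights", weights)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def same_as(self, other: "GridSpec") -> bool:
        """Shape and mask equality — the co-registration check."""
        return self.shape == other.shape and bool(
            (self.valid_mask == other.valid_mask).all()
        )

    def require_same(self, other: "GridSpec", context: str = "operation") -> None:
        if not self.same_as(other):
            raise GridMismatchError(f"grid mismatch in {context}")

    @classmethod
    def from_mask(cls, mask: np.ndarray, weights: np.ndarray | None = None) -> "GridSpec":
        mask = np.asarray(mask, dtype=bool)
        return cls(mask.shape[0], mask.shape[1], mask, weights)


def _conform_values(values: np.ndarray, grid: GridSpec, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"{what} shape {values.shape} != grid shape {grid.shape}")
    out = np.where(grid.valid_mask, values, np.nan)
    if np.isnan(out[grid.valid_mask]).any():
        raise ValueError(f"{what} contains missing values inside the valid mask")
    out.setflags(write=False)
    return out


@dataclass(frozen=True)
class RasterLayer:
    """One co-registered 2-D grid of values; NaN everywhere outside the mask."""

    grid: GridSpec
    values: np.ndarray
    variable_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", _conform_values(self.values, self.grid, "layer values")
        )

    @property
    def valid_values(self) -> np.ndarray:
        """1-D array of the values inside the valid mask."""
        return self.values[self.grid.valid_mask]

    def with_values(self, values: np.ndarray, variable_name: str | None = None,
                    units: str | None = None) -> "RasterLayer":
        return RasterLayer(
            self.grid,
            values,
            self.variable_name if variable_name is None else variable_name,
            self.units if units is None else units,
        )


@dataclass(frozen=True)
class EnsembleStack:
    """member x row x col array of one variable across N climate futures."""

    grid: GridSpec
    member_ids: tuple[str, ...]
    values: np.ndarray
    variable_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        ids = tuple(str(m) for m in self.member_ids)
        if len(ids) < 1:
            raise ValueError("stack must have at least one member")
        if len(set(ids)) != len(ids):
            raise ValueError("member_ids must be unique")
        values = np.asarray(self.values, dtype=float)
        expected = (len(ids),) + self.grid.shape
        if values.shape != expected:
            raise ValueError(f"stack shape {values.shape} != {expected}")
        out = np.where(self.grid.valid_mask[None, :, :], values, np.nan)
        if np.isnan(out[:, self.grid.valid_mask]).any():
            raise ValueError("stack contains missing values inside the valid mask")
        out.setflags(write=False)
        object.__setattr__(self, "member_ids", ids)
        object.__setattr__(self, "values", out)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    def member(self, member_id: str) -> RasterLayer:
        """Extract one member as a layer."""
        try:
            i = self.member_ids.index(member_id)
        except ValueError:
            raise KeyError(f"member {member_id!r} not in stack") from None
        return RasterLayer(self.grid, self.values[i], self.variable_name, self.units)

    def layers(self):
        """Iterate ``(member_id, RasterLayer)`` in member order."""
        for i, m in enumerate(self.member_ids):
            yield m, RasterLayer(self.grid, self.values[i], self.variable_name, self.units)


@dataclass(frozen=True)
class DepartureTable:
    """Expert lookup of (baseline type, future type) -> departure in [0, 3].

    The table must be total on its declared type set, with a zero diagonal.
    Symmetry is NOT assumed: departure(A, B) may differ from departure(B, A).
    """

    codes: tuple[int, ...]
    entries: dict = field(repr=False)  # (baseline, future) -> float

    def __post_init__(self) -> None:
        codes = tuple(sorted(int(c) for c in self.codes))
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate vegetation type codes")
        entries = {(int(a), int(b)): float(v) for (a, b), v in self.entries.items()}
        for (a, b), v in entries.items():
            if a not in codes or b not in codes:
                raise ValueError(f"entry ({a}, {b}) uses an undeclared code")
            if not (0.0 <= v <= 3.0):
                raise ValueError(
                    f"departure value outside [0, 3] for pair ({a}, {b}): {v}"
                )
        for a in codes:
            for b in codes:
                if (a, b) not in entries:
                    raise ValueError(f"missing pair ({a}, {b}) in departure table")
            if entries[(a, a)] != 0.0:
                raise ValueError(f"diagonal departure for type {a} must be 0")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "entries", entries)

    def lookup(self, baseline: np.ndarray, future: np.ndarray) -> np.ndarray:
        """Vectorized departure lookup; raises on codes absent from the table."""
        baseline = np.asarray(baseline)
        future = np.asarray(future)
        index = {c: i for i, c in enumerate(self.codes)}
        n = len(self.codes)
        matrix = np.empty((n, n), dtype=float)
        for (a, b), v in self.entries.items():
            matrix[index[a], index[b]] = v

        def to_index(arr: np.ndarray, which: str) -> np.ndarray:
            out = np.full(arr.shape, -1, dtype=int)
            finite = np.isfinite(arr.astype(float))
            for c, i in index.items():
                out[finite & (arr == c)] = i
            bad = finite & (out < 0)
            if bad.any():
                missing = sorted(set(np.unique(arr[bad]).tolist()))
                raise ValueError(
                    f"{which} vegetation code(s) absent from departure table: {missing}"
                )
            return out

        bi = to_index(baseline, "baseline")
        fi = to_index(future, "future")
        result = np.full(baseline.shape, np.nan, dtype=float)
        ok = (bi >= 0) & (fi >= 0)
        result[ok] = matrix[bi[ok], fi[ok]]
        return result


def _is_netcdf(path: str) -> bool:
    return os.path.splitext(path)[1].lower() in _NETCDF_SUFFIXES


def read_layer(
    path: str,
    variable_name: str | None = None,
    grid: GridSpec | None = None,
    units: str = "",
) -> RasterLayer:
    """Read one 2-D layer from GeoTIFF or NetCDF.

    The validity mask is derived from the format's nodata convention
    (GDAL_NODATA tag for TIFF, _FillValue/NaN for NetCDF).  When a reference
    ``grid`` is supplied, the result is checked against it and the reference
    (with its weights) is attached.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if _is_netcdf(path):
        with xr.open_dataset(path, engine=_NETCDF_ENGINE) as ds:
            if variable_name is None:
                data_vars = list(ds.data_vars)
                if len(data_vars) != 1:
                    raise ValueError(
                        f"variable_name required; file has variables {data_vars}"
                    )
                variable_name = data_vars[0]
            if variable_name not in ds:
                raise KeyError(f"variable absent: {variable_name!r} not in {path}")
            da = ds[variable_name]
            if da.ndim != 2:
                raise ValueError(f"expected 2-D variable, got dims {da.dims}")
            values = np.asarray(da.values, dtype=float)
            units = units or str(da.attrs.get("units", ""))
        name = variable_name
    else:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = np.asarray(page.asarray(), dtype=float)
            if values.ndim != 2:
                raise ValueError(f"expected single-band 2-D TIFF, got {values.shape}")
            if GDAL_NODATA_TAG in page.tags:
                nodata = float(page.tags[GDAL_NODATA_TAG].value)
                if np.isnan(nodata):
                    pass  # NaN already marks nodata
                else:
                    values[values == nodata] = np.nan
        name = variable_name or os.path.splitext(os.path.basename(path))[0]
    mask = np.isfinite(values)
    if grid is not None:
        if grid.shape != values.shape or not (mask == grid.valid_mask).all():
            raise GridMismatchError(f"grid mismatch reading {path}")
        return RasterLayer(grid, values, name, units)
    return RasterLayer(GridSpec.from_mask(mask), values, name, units)


def write_layer(layer: RasterLayer, path: str, nodata: float = -9999.0) -> None:
    """Write a layer as float32 GeoTIFF (GDAL_NODATA tag) or NetCDF (NaN fill)."""
    _check_writable(path)
    if _is_netcdf(path):
        name = layer.variable_name or "layer"
        da = xr.DataArray(
            layer.values.astype(np.float32),
            dims=("y", "x"),
            name=name,
            attrs={"units": layer.units} if layer.units else {},
        )
        da.to_dataset().to_netcdf(path, engine=_NETCDF_ENGINE)
    else:
        out = np.where(layer.grid.valid_mask, layer.values, nodata).astype(np.float32)
        tag_value = "nan" if np.isnan(nodata) else repr(float(nodata))
        tifffile.imwrite(
            path, out, extratags=[(GDAL_NODATA_TAG, "s", 0, tag_value, True)]
        )


def read_stack(
    path: str,
    variable_name: str | None = None,
    grid: GridSpec | None = None,
) -> EnsembleStack:
    """Read an ensemble stack from NetCDF with dims ``(member, y, x)``.

    Member ids are taken from the ``member`` coordinate in file order.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine=_NETCDF_ENGINE) as ds:
        if variable_name is None:
            data_vars = [v for v in ds.data_vars]
            if len(data_vars) != 1:
                raise ValueError(f"variable_name required; file has {data_vars}")
            variable_name = data_vars[0]
        if variable_name not in ds:
            raise KeyError(f"variable absent: {variable_name!r} not in {path}")
        da = ds[variable_name]
        if "member" not in da.dims:
            raise ValueError(f"absent member dimension in {path} ({da.dims})")
        if da.ndim != 3:
            raise ValueError(f"expected dims (member, y, x), got {da.dims}")
        da = da.transpose("member", ...)
        if "member" in ds.coords:
            member_ids = [str(m) for m in np.asarray(ds["member"].values)]
        else:
            member_ids = [str(i) for i in range(da.sizes["member"])]
        values = np.asarray(da.values, dtype=float)
        units = str(da.attrs.get("units", ""))
    mask = np.isfinite(values).all(axis=0)
    if grid is not None:
        if grid.shape != mask.shape or not (mask == grid.valid_mask).all():
            raise GridMismatchError(f"grid mismatch reading {path}")
    else:
        grid = GridSpec.from_mask(mask)
    return EnsembleStack(grid, tuple(member_ids), values, variable_name, units)


def write_stack(stack: EnsembleStack, path: str) -> None:
    """Write an ensemble stack as NetCDF with dims ``(member, y, x)``."""
    _check_writable(path)
    da = xr.DataArray(
        stack.values.astype(np.float32),
        dims=("member", "y", "x"),
        coords={"member": list(stack.member_ids)},
        name=stack.variable_name or "stack",
        attrs={"units": stack.units} if stack.units else {},
    )
    da.to_dataset().to_netcdf(path, engine=_NETCDF_ENGINE)


def load_departure_table(path: str) -> DepartureTable:
    """Load and validate a departure lookup CSV.

    Columns: ``baseline_type, future_type, departure``.  The declared type
    set is the union of codes in the two type columns; the table must be
    total on it with a zero diagonal and values in [0, 3].
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"baseline_type", "future_type", "departure"}
    if not required.issubset(df.columns):
        raise ValueError(f"departure table must have columns {sorted(required)}")
    codes = sorted(set(df["baseline_type"].astype(int)) | set(df["future_type"].astype(int)))
    entries = {
        (int(r.baseline_type), int(r.future_type)): float(r.departure)
        for r in df.itertuples()
    }
    return DepartureTable(tuple(codes), entries)


def write_departure_table(table: DepartureTable, path: str) -> None:
    _check_writable(path)
    rows = [
        {"baseline_type": a, "future_type": b, "departure": v}
        for (a, b), v in sorted(table.entries.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _check_writable(path: str) -> None:
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"destination directory does not exist: {parent}")
    if not os.access(parent, os.W_OK) or (
        os.path.exists(path) and not os.access(path, os.W_OK)
    ):
        raise PermissionError(f"destination not writable: {path}")
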