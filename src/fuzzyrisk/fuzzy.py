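"""Fuzzy normalization and the And/Or/Union operators with source attribution.

Fuzzy truth runs from 0 (*fully false*) to 1 (*fully true*).  Raw values are
normalized with a two-threshold linear ramp; combined with per-cell minimum
(And), maximum (Or), or mean (Union).  For And/Or the result at a cell comes
from exactly one input (up to ties), so those operators also return an
attribution layer naming the source input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from fuzzyrisk.grid_io import GridSpec, RasterLayer

__all__ = [
    "ConversionSpec",
    "FuzzyLayer",
    "AttributionLayer",
    "TIE_NONE",
    "convert_linear",
    "convert_linear_scalar",
    "fuzzy_and",
    "fuzzy_or",
    "fuzzy_union",
]


@dataclass(frozen=True)
class ConversionSpec:
    """Two-threshold linear conversion from raw values to fuzzy truth.

    ``minthresh`` is the *fully false* threshold and ``maxthresh`` the
    *fully true* threshold, in raw-variable units.  ``minthresh > maxthresh``
    produces a decreasing ramp (not used by the default model, but supported).
    """

    minthresh: float
    maxthresh: float

    def __post_init__(self) -> None:
        lo, hi = float(self.minthresh), float(self.maxthresh)
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("conversion thresholds must be finite")
        if lo == hi:
            raise ValueError("degenerate conversion: minthresh == maxthresh")
        object.__setattr__(self, "minthresh", lo)
        object.__setattr__(self, "maxthresh", hi)


class FuzzyLayer(RasterLayer):
    """A raster layer whose valid values are fuzzy truths in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        v = self.valid_values
        if v.size and ((v < 0.0) | (v > 1.0)).any():
            raise ValueError("fuzzy values must lie in [0, 1]")


#: Attribution index marking cells where no single input supplied the result.
TIE_NONE = -1


@dataclass(frozen=True)
class AttributionLayer:
    """Per-cell index of the input layer that supplied an And/Or result.

    ``indices`` holds the lowest attaining input index per valid cell
    (``TIE_NONE`` outside the mask); ``tie`` flags cells where more than one
    input attains the extremum.  ``input_names`` gives index -> name.
    """

    grid: GridSpec
    indices: np.ndarray
    tie: np.ndarray
    input_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        tie = np.asarray(self.tie, dtype=bool)
        if idx.shape != self.grid.shape or tie.shape != self.grid.shape:
            raise ValueError("attribution arrays must match the grid shape")
        idx = np.where(self.grid.valid_mask, idx, TIE_NONE)
        n = len(self.input_names) if self.input_names else idx.max() + 1
        inside = idx[self.grid.valid_mask]
        if inside.size and ((inside < 0) | (inside >= max(n, 1))).any():
            raise ValueError("attribution index outside input list")
        idx.setflags(write=False)
        tie.setflags(write=False)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "tie", tie)
        object.__setattr__(self, "input_names", tuple(self.input_names))


def convert_linear_scalar(inputval: float, spec: ConversionSpec) -> float:
    """Scalar form of :func:`convert_linear` (used by the per-cell oracle)."""
    lo, hi = spec.minthresh, spec.maxthresh
    if lo < hi:
        if inputval < lo:
            return 0.0
        if inputval > hi:
            return 1.0
        return (inputval - lo) / (hi - lo)
    # decreasing ramp
    if inputval > lo:
        return 0.0
    if inputval < hi:
        return 1.0
    return (inputval - lo) / (hi - lo)


def convert_linear(layer: RasterLayer, spec: ConversionSpec) -> FuzzyLayer:
    """Normalize a raw layer to fuzzy truth with a two-threshold linear ramp.

    With ``minthresh < maxthresh``: 0 below the false threshold, 1 above the
    true threshold, linear in between; both boundary values map exactly
    (``convert(minthresh) == 0``, ``convert(maxthresh) == 1``).  Reversed
    thresholds give the mirrored decreasing ramp.
    """
    lo, hi = spec.minthresh, spec.maxthresh
    with np.errstate(invalid="ignore"):
        ramp = (layer.values - lo) / (hi - lo)
    fuzzy = np.clip(ramp, 0.0, 1.0)
    return FuzzyLayer(layer.grid, fuzzy, layer.variable_name, "fuzzy truth")


def _check_inputs(inputs: Sequence[FuzzyLayer], op: str) -> GridSpec:
    if len(inputs) < 2:
        raise ValueError(f"{op} requires at least 2 inputs, got {len(inputs)}")
    grid = inputs[0].grid
    for layer in inputs[1:]:
        grid.require_same(layer.grid, op)
    return grid


def _extremum(
    inputs: Sequence[FuzzyLayer], take_max: bool, name: str
) -> tuple[FuzzyLayer, AttributionLayer]:
    grid = _check_inputs(inputs, name)
    stack = np.stack([layer.values for layer in inputs])
    # inputs are NaN at identical (masked) cells, so plain min/max propagates
    # NaN exactly where the mask excludes cells
    result = stack.max(axis=0) if take_max else stack.min(axis=0)
    attains = stack == result[None, :, :]
    indices = np.argmax(attains, axis=0)  # lowest attaining index
    tie = attains.sum(axis=0) > 1
    indices = np.where(grid.valid_mask, indices, TIE_NONE)
    tie = np.where(grid.valid_mask, tie, False)
    names = tuple(layer.variable_name for layer in inputs)
    return (
        FuzzyLayer(grid, result, name, "fuzzy truth"),
        AttributionLayer(grid, indices, tie, names),
    )


def fuzzy_and(inputs: Sequence[FuzzyLayer], name: str = "and") -> tuple[FuzzyLayer, AttributionLayer]:
    """Per-cell minimum; attribution names the (lowest-index) minimizing input."""
    return _extremum(inputs, take_max=False, name=name)


def fuzzy_or(inputs: Sequence[FuzzyLayer], name: str = "or") -> tuple[FuzzyLayer, AttributionLayer]:
    """Per-cell maximum; attribution names the (lowest-index) maximizing input."""
    return _extremum(inputs, take_max=True, name=name)


def fuzzy_union(inputs: Sequence[FuzzyLayer], name: str = "union") -> FuzzyLayer:
    """Per-cell arithmetic mean of the inputs (no attribution: means have no
    single source)."""
    grid = _check_inputs(inputs, name)
    stack = np.stack([layer.values for layer in inputs])
    result = stack.mean(axis=0)
    return FuzzyLayer(grid, result, name, "fuzzy truth")
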