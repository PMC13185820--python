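"""Temporal stability (mu/sigma) of annual raster stacks, and aridity classification.

Stability of an annual series is the ratio of its mean to its sample standard
deviation: a dimensionless signal-to-noise measure where larger values mean
smaller relative interannual fluctuation.  Maps are computed per grid cell
over the full period or over moving decadal windows; cells whose series is
constant (sigma = 0) or too short are undefined and carried as NaN, never as
zero or infinity, so that downstream correlations can skip them explicitly.

The aridity index AI is annual precipitation over annual potential
evapotranspiration (MAP/PET); cells are classified on the UNEP breakpoints
(hyper-arid < 0.05 <= arid < 0.20 <= semi-arid < 0.50 <= dry sub-humid
< 0.65 <= humid); a value exactly on an edge falls in the drier class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

__all__ = [
    "StabilityMap",
    "WindowedStability",
    "AridityClassMap",
    "ARIDITY_EDGES",
    "ARIDITY_CLASSES",
    "stability",
    "stability_map",
    "moving_window_stability",
    "aridity",
]

#: Default AI class edges (UNEP), left-closed / right-open bins.
ARIDITY_EDGES = (0.05, 0.20, 0.50, 0.65)
ARIDITY_CLASSES = ("hyper-arid", "arid", "semi-arid", "dry sub-humid", "humid")


@dataclass
class StabilityMap:
    """Per-cell mu/sigma values for one variable over one year window.

    ``values`` is a 2-D float array with NaN at undefined cells (masked
    input, sigma = 0, or fewer than two valid years).
    """

    values: np.ndarray
    window: tuple[int, int]
    source: str = ""
    ddof: int = 1

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where stability is defined."""
        return np.isfinite(self.values)

    def to_dataarray(self) -> xr.DataArray:
        da = xr.DataArray(self.values, dims=("row", "col"), name="stability")
        da.attrs.update(
            source=self.source, year_start=self.window[0], year_end=self.window[1]
        )
        return da


@dataclass
class WindowedStability:
    """Sequence of moving-window stability maps for one variable.

    ``values`` has shape (n_windows, rows, cols); ``labels`` holds the
    inclusive (start_year, end_year) of each window.
    """

    values: np.ndarray
    labels: list[tuple[int, int]]
    window: int
    source: str = ""

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def maps(self) -> list[StabilityMap]:
        return [
            StabilityMap(self.values[i], self.labels[i], self.source)
            for i in range(self.n_windows)
        ]

    def to_dataarray(self) -> xr.DataArray:
        da = xr.DataArray(
            self.values,
            dims=("window", "row", "col"),
            coords={"window": [f"{a}-{b}" for a, b in self.labels]},
            name="stability",
        )
        da.attrs.update(source=self.source, window_length=self.window)
        return da


@dataclass
class AridityClassMap:
    """Mean aridity index per cell and its dryland class."""

    ai: np.ndarray
    classes: np.ndarray  # integer class codes, -1 where undefined
    edges: tuple[float, ...] = ARIDITY_EDGES
    labels: tuple[str, ...] = field(default=ARIDITY_CLASSES)

    def class_name(self, code: int) -> str:
        return self.labels[code] if code >= 0 else "undefined"


def stability(series, ddof: int = 1) -> float:
    """mu/sigma of an annual series; NaN if sigma is 0.

    Missing values are dropped; fewer than two remaining values is an error.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("stability needs at least 2 non-missing values")
    sd = x.std(ddof=ddof)
    if sd == 0:
        return float("nan")
    return float(x.mean() / sd)


def _stack_array(stack) -> tuple[np.ndarray, np.ndarray]:
    """Return (values with year as axis 0, year labels)."""
    if isinstance(stack, xr.DataArray):
        da = stack.transpose("year", "row", "col")
        return np.asarray(da.values, dtype=float), np.asarray(da["year"].values)
    arr = np.asarray(stack, dtype=float)
    return arr, np.arange(arr.shape[0])


def _cellwise_stability(block: np.ndarray, ddof: int) -> np.ndarray:
    """Vectorised mu/sigma along axis 0, NaN-aware, NaN where degenerate."""
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        n = np.isfinite(block).sum(axis=0)
        vals = np.where(np.isfinite(block), block, np.nan)
        mu = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0, ddof=ddof)
        out = mu / sd
    out[(n < 2) | (sd == 0) | ~np.isfinite(out)] = np.nan
    return out


def stability_map(stack, years=None, ddof: int = 1, source: str = "") -> StabilityMap:
    """Per-cell stability of an annual (year, row, col) stack.

    ``years`` restricts to an inclusive (start, end) range of year labels;
    default is the full period.
    """
    arr, labels = _stack_array(stack)
    if years is not None:
        y0, y1 = years
        sel = (labels >= y0) & (labels <= y1)
        if not sel.any():
            raise ValueError(f"empty year range {years}")
        arr, labels = arr[sel], labels[sel]
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 years")
    vals = _cellwise_stability(arr, ddof)
    return StabilityMap(vals, (int(labels[0]), int(labels[-1])), source, ddof)


def moving_window_stability(
    stack, window: int = 10, ddof: int = 1, source: str = ""
) -> WindowedStability:
    """Stability maps over every length-``window`` run of consecutive years.

    An n-year stack yields n - window + 1 maps (34 years, window 10 -> 25),
    labelled by the inclusive start/end years of each window.
    """
    arr, labels = _stack_array(stack)
    n_years = arr.shape[0]
    if window > n_years:
        raise ValueError(f"window {window} exceeds {n_years} available years")
    if window < 2:
        raise ValueError("window must be >= 2")
    n_win = n_years - window + 1
    out = np.empty((n_win,) + arr.shape[1:], dtype=float)
    win_labels = []
    for s in range(n_win):
        out[s] = _cellwise_stability(arr[s : s + window], ddof)
        win_labels.append((int(labels[s]), int(labels[s + window - 1])))
    return WindowedStability(out, win_labels, window, source)


def aridity(map_stack, pet_stack, edges=ARIDITY_EDGES) -> AridityClassMap:
    """Mean annual aridity index (MAP/PET) per cell and its dryland class.

    AI is computed per cell-year and averaged over the period; cells with
    PET <= 0 in any year are masked.  AI exactly on a class edge falls in
    the drier class.
    """
    p, _ = _stack_array(map_stack)
    pet, _ = _stack_array(pet_stack)
    if p.shape != pet.shape:
        raise ValueError("MAP and PET stacks must share shape")
    bad = (pet <= 0) | ~np.isfinite(pet) | ~np.isfinite(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        ai_annual = np.where(bad, np.nan, p / pet)
    ai = np.nanmean(ai_annual, axis=0)
    ai[np.any(bad, axis=0)] = np.nan
    codes = np.full(ai.shape, -1, dtype=int)
    ok = np.isfinite(ai)
    # side="left": ai exactly on an edge goes to the drier class
    codes[ok] = np.searchsorted(np.asarray(edges), ai[ok], side="left")
    return AridityClassMap(ai, codes, tuple(edges))
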