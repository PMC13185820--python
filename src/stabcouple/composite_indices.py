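"""Composite environmental indices: per-category PC1 of standardized variables.

Six predictor categories feed the respiration regression: climate (Cli) and
vegetation (Plant) are time-varying and enter the PCA together with their
trailing three-year moving averages (past years only, capturing cumulative
effects); topography (Gra), soil microbial (Mic), soil physical (Phy) and
soil chemical (Chem) are static.  Each category is reduced to the first
principal component of its z-scored variables, fitted once globally on a
seeded random sample of cell-years so indices are comparable across space.

PC sign is arbitrary, so each category carries a reference variable (MAT for
Cli, NPP for Plant, elevation for Gra, MBC for Mic, clay for Phy, SOC for
Chem) whose loading is oriented positive; this pins the regression
coefficients downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryIndex",
    "CompositeIndexSet",
    "CATEGORY_VARIABLES",
    "REFERENCE_VARIABLES",
    "moving_average",
    "build_category_index",
    "build_indices",
    "extract_at_sites",
]

#: Variables per category, as named in a SyntheticWorld dataset.
CATEGORY_VARIABLES = {
    "Cli": ["MAT", "Tmax", "Tmin", "MAP", "radiation", "AET", "PET"],
    "Plant": ["NPP", "LAI", "FVC", "CUE", "WUE"],
    "Gra": ["elevation", "slope", "aspect"],
    "Mic": ["MBC", "MBN", "MBP"],
    "Phy": ["sand", "silt", "clay", "bulk_density", "VWC", "pH", "CEC"],
    "Chem": ["SOC", "TN", "CN_ratio"],
}

#: Category -> variable whose PC1 loading is oriented positive.
REFERENCE_VARIABLES = {
    "Cli": "MAT",
    "Plant": "NPP",
    "Gra": "elevation",
    "Mic": "MBC",
    "Phy": "clay",
    "Chem": "SOC",
}

TIME_VARYING = ("Cli", "Plant")


def moving_average(stack, window: int = 3):
    """Trailing moving average along the year axis.

    Year t averages years max(0, t-window+1)..t, so the first window-1 years
    use the shorter run that is available; output length equals input length.
    Accepts an xarray DataArray with a ``year`` dim or a plain array with
    year as axis 0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if isinstance(stack, xr.DataArray):
        if window > stack.sizes["year"]:
            raise ValueError("window exceeds number of years")
        return stack.rolling(year=window, min_periods=1).mean()
    arr = np.asarray(stack, dtype=float)
    if window > arr.shape[0]:
        raise ValueError("window exceeds number of years")
    out = np.empty_like(arr)
    c = np.cumsum(arr, axis=0)
    for t in range(arr.shape[0]):
        s = max(0, t - window + 1)
        out[t] = (c[t] - (c[s - 1] if s > 0 else 0)) / (t - s + 1)
    return out


@dataclass
class CategoryIndex:
    """One composite index: PC1 loadings, standardization and scores.

    Index values are the z-scored features projected onto the unit-norm PC1
    loadings, then divided by ``score_scale`` (the SD of the raw projection
    over the fit sample) so the index itself has zero mean and unit variance
    over that sample.
    """

    name: str
    values: xr.DataArray  # (year,row,col) for time-varying, (row,col) static
    loadings: pd.Series  # feature -> unit-norm PC1 weight
    variance_explained: float
    standardization: pd.DataFrame  # feature -> mean, sd
    time_varying: bool
    score_scale: float = 1.0

    def project(self, features: pd.DataFrame) -> np.ndarray:
        """Index values for rows of a feature table (columns = loadings index)."""
        z = (features[self.loadings.index] - self.standardization["mean"]) / (
            self.standardization["sd"]
        )
        return z.to_numpy() @ self.loadings.to_numpy() / self.score_scale


@dataclass
class CompositeIndexSet:
    """The six PC1 index fields plus their fitted PCA metadata."""

    indices: dict[str, CategoryIndex]
    grid_attrs: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> CategoryIndex:
        return self.indices[name]

    @property
    def names(self) -> list[str]:
        return list(self.indices)

    def loadings_table(self) -> pd.DataFrame:
        rows = []
        for idx in self.indices.values():
            for var, w in idx.loadings.items():
                rows.append(
                    {
                        "category": idx.name,
                        "variable": var,
                        "loading": w,
                        "variance_explained": idx.variance_explained,
                    }
                )
        return pd.DataFrame(rows)

    def at_cell_year(self, row: int, col: int, year: int) -> dict[str, float]:
        out = {}
        for name, idx in self.indices.items():
            da = idx.values
            if idx.time_varying:
                out[name] = float(da.sel(year=year).values[row, col])
            else:
                out[name] = float(da.values[row, col])
        return out


def _pc1(z: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component of already-standardized data.

    Returns (unit-norm loading vector, fraction of variance explained),
    from an eigen-decomposition of the correlation matrix.
    """
    c = np.cov(z, rowvar=False, ddof=1)
    c = np.atleast_2d(c)
    evals, evecs = np.linalg.eigh(c)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    return evecs[:, 0], float(evals[0] / total) if total > 0 else float("nan")


def build_category_index(
    variables: dict[str, xr.DataArray],
    name: str,
    include_moving_avg: bool = False,
    ma_window: int = 3,
    reference: str | None = None,
    sample_size: int | None = 2000,
    seed: int = 0,
) -> CategoryIndex:
    """PC1 composite index of one variable category.

    Time-varying categories contribute each variable and (optionally) its
    trailing moving average as separate features.  Variables are z-scored
    over a seeded random sample of cell-years (``sample_size=None`` uses
    every valid cell-year), PC1 is fitted on that sample, and the index is
    evaluated everywhere by projecting the standardized features onto the
    loadings.
    """
    if len(variables) < 2:
        raise ValueError("need at least 2 variables for a composite index")
    first = next(iter(variables.values()))
    time_varying = "year" in first.dims

    feats: dict[str, np.ndarray] = {}
    for var, da in variables.items():
        if time_varying:
            arr = np.asarray(da.transpose("year", "row", "col").values, dtype=float)
            feats[var] = arr
            if include_moving_avg:
                feats[f"{var}_ma{ma_window}"] = moving_average(arr, ma_window)
        else:
            feats[var] = np.asarray(da.values, dtype=float)

    names = list(feats)
    flat = np.column_stack([feats[k].reshape(-1) for k in names])
    valid = np.isfinite(flat).all(axis=1)
    flat_valid = flat[valid]
    rng = np.random.default_rng(seed)
    if sample_size is not None and sample_size < flat_valid.shape[0]:
        pick = rng.choice(flat_valid.shape[0], size=sample_size, replace=False)
        sample = flat_valid[pick]
    else:
        sample = flat_valid

    mean = sample.mean(axis=0)
    sd = sample.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        bad = [names[i] for i in np.where(zero)[0]]
        raise ValueError(f"constant variable(s) over the PCA sample: {bad}")

    loadings, var_expl = _pc1((sample - mean) / sd)
    ref = reference or REFERENCE_VARIABLES.get(name)
    if ref is not None and ref in names and loadings[names.index(ref)] < 0:
        loadings = -loadings

    sample_scores = ((sample - mean) / sd) @ loadings
    score_scale = float(sample_scores.std(ddof=1))
    scores = ((flat - mean) / sd) @ loadings / score_scale
    scores[~valid] = np.nan
    if time_varying:
        shape = feats[names[0]].shape
        values = xr.DataArray(
            scores.reshape(shape),
            dims=("year", "row", "col"),
            coords={"year": first["year"].values},
            name=name,
        )
    else:
        values = xr.DataArray(
            scores.reshape(feats[names[0]].shape), dims=("row", "col"), name=name
        )

    return CategoryIndex(
        name=name,
        values=values,
        loadings=pd.Series(loadings, index=names),
        variance_explained=var_expl,
        standardization=pd.DataFrame({"mean": mean, "sd": sd}, index=names),
        time_varying=time_varying,
        score_scale=score_scale,
    )


def build_indices(
    data: xr.Dataset,
    sample_size: int = 2000,
    seed: int = 0,
    ma_window: int = 3,
    categories: dict[str, list[str]] | None = None,
) -> CompositeIndexSet:
    """Build all six composite indices from a world-like dataset.

    CUE (NPP/GPP) and WUE (NPP/AET) are derived on the fly when absent.
    """
    ds = data
    if "CUE" not in ds and "GPP" in ds:
        with np.errstate(divide="ignore", invalid="ignore"):
            ds = ds.assign(CUE=lambda d: (d["NPP"] / d["GPP"]).where(d["GPP"] > 0))
    if "WUE" not in ds and "AET" in ds:
        with np.errstate(divide="ignore", invalid="ignore"):
            ds = ds.assign(WUE=lambda d: (d["NPP"] / d["AET"]).where(d["AET"] > 0))

    cats = categories or CATEGORY_VARIABLES
    indices = {}
    for i, (name, varnames) in enumerate(cats.items()):
        present = [v for v in varnames if v in ds]
        if len(present) < 2:
            raise ValueError(f"category {name}: fewer than 2 variables present")
        variables = {v: ds[v] for v in present}
        indices[name] = build_category_index(
            variables,
            name,
            include_moving_avg=name in TIME_VARYING,
            ma_window=ma_window,
            sample_size=sample_size,
            seed=seed + i,  # per-category stream, deterministic in seed
        )
    attrs = {k: ds.attrs[k] for k in ("lat0", "lon0", "cell_size") if k in ds.attrs}
    return CompositeIndexSet(indices, grid_attrs=attrs)


def nearest_cell(lat, lon, lat0: float, lon0: float, cell: float) -> tuple:
    """Map coordinates to the nearest grid cell centre; ties go to the lower index.

    The grid is pseudo-geographic: cell (r, c) is centred at
    (lat0 - r*cell, lon0 + c*cell).
    """
    r = (lat0 - np.asarray(lat, dtype=float)) / cell
    c = (np.asarray(lon, dtype=float) - lon0) / cell
    # np.round half-to-even would send .5 either way; floor(x+0.5) rounds the
    # midpoint up in grid coordinates, which for rows/cols means the tie goes
    # to the *higher* fractional index -- so use ceil(x-0.5) for lower-index ties
    r_idx = np.ceil(r - 0.5).astype(int)
    c_idx = np.ceil(c - 0.5).astype(int)
    return r_idx, c_idx


def extract_at_sites(
    indices: CompositeIndexSet,
    records: pd.DataFrame,
    lat_col: str = "Latitude",
    lon_col: str = "Longitude",
    year_col: str = "Study_midyear",
    rs_col: str = "Rs_annual",
    eco_col: str = "Ecosystem_type",
) -> pd.DataFrame:
    """Design table: one row per record with the six index values at its cell-year.

    Records whose coordinates fall outside the grid or whose year is outside
    the stack range are dropped with a logged count.
    """
    cols = list(indices.names) + ["ecosystem", "Rs_annual", "Site_ID", "row", "col", "year"]
    if records.empty:
        return pd.DataFrame(columns=cols)

    ga = indices.grid_attrs
    lat0, lon0, cell = ga["lat0"], ga["lon0"], ga["cell_size"]
    any_idx = next(iter(indices.indices.values()))
    tv = [ix for ix in indices.indices.values() if ix.time_varying]
    years = np.asarray(tv[0].values["year"].values) if tv else None
    shape = any_idx.values.shape[-2:]

    r_idx, c_idx = nearest_cell(
        records[lat_col].to_numpy(), records[lon_col].to_numpy(), lat0, lon0, cell
    )
    yr = np.floor(pd.to_numeric(records[year_col], errors="coerce")).to_numpy()
    ok = (
        (r_idx >= 0)
        & (r_idx < shape[0])
        & (c_idx >= 0)
        & (c_idx < shape[1])
        & np.isfinite(yr)
    )
    if years is not None:
        ok &= np.isin(yr, years)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("extract_at_sites: dropped %d records outside grid/date range", dropped)

    sel = records.loc[ok].reset_index(drop=True)
    r_sel, c_sel, y_sel = r_idx[ok], c_idx[ok], yr[ok].astype(int)
    out = {}
    for name, idx in indices.indices.items():
        arr = np.asarray(idx.values.values)
        if idx.time_varying:
            ypos = np.searchsorted(years, y_sel)
            out[name] = arr[ypos, r_sel, c_sel]
        else:
            out[name] = arr[r_sel, c_sel]
    design = pd.DataFrame(out)
    design["ecosystem"] = sel[eco_col].to_numpy() if eco_col in sel else "all"
    design["Rs_annual"] = pd.to_numeric(sel[rs_col], errors="coerce").to_numpy()
    design["Site_ID"] = sel["Site_ID"].to_numpy() if "Site_ID" in sel else np.arange(len(sel))
    design["row"], design["col"], design["year"] = r_sel, c_sel, y_sel
    return design
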