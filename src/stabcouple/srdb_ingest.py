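"""Reading and filtering SRDB-style soil-respiration records.

The Global Soil Respiration Database (SRDB) compiles published site-year
flux measurements.  The filter chain retains records that (1) report an
annual flux, (2) carry complete longitude/latitude/year metadata, (3) fall
inside a year range (1985-2018 by default), and (4) lie within mean +- k*SD
of the annual flux, with the mean and SD computed over the records that
survive steps 1-3.  Every intermediate count is recorded so a run can be
audited step by step.

Fold assignment for validation is blocked by Site_ID: every record of a
site shares a fold, preventing within-site leakage between training and
test data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SRDBColumnError",
    "FilterReport",
    "DEFAULT_COLUMNS",
    "read_srdb",
    "filter_records",
    "site_blocked_split",
]

#: canonical name -> column in the CSV (SRDB v2020 dialect by default)
DEFAULT_COLUMNS = {
    "site": "Site_ID",
    "lat": "Latitude",
    "lon": "Longitude",
    "year": "Study_midyear",
    "rs": "Rs_annual",
    "ecosystem": "Ecosystem_type",
}

_NUMERIC = ("lat", "lon", "year", "rs")


class SRDBColumnError(ValueError):
    """Raised when required columns are absent from an input CSV."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing required SRDB columns: {self.missing}")


def read_srdb(path, columns: dict | None = None) -> pd.DataFrame:
    """Read an SRDB-style CSV into one row per record.

    Unparseable numeric fields become missing (NaN), never zero.  The
    ecosystem column is optional; all other mapped columns are required.
    """
    colmap = {**DEFAULT_COLUMNS, **(columns or {})}
    try:
        raw = pd.read_csv(path, low_memory=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty SRDB file: {path}") from None
    required = {k: v for k, v in colmap.items() if k != "ecosystem"}
    missing = [v for v in required.values() if v not in raw.columns]
    if missing:
        raise SRDBColumnError(missing)
    if len(raw) == 0:
        raise ValueError(f"SRDB file has a header but no records: {path}")
    for key in _NUMERIC:
        raw[colmap[key]] = pd.to_numeric(raw[colmap[key]], errors="coerce")
    raw.attrs["colmap"] = colmap
    return raw


@dataclass
class FilterReport:
    """Record counts after each filter step, plus the outlier bounds used."""

    counts: dict[str, int] = field(default_factory=dict)
    n_sites: int = 0
    n_records_with_ecosystem: int = 0
    outlier_bounds: tuple[float, float] = (float("nan"), float("nan"))
    sd_k: float = 3.0
    second_pass_removals: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "counts": self.counts,
            "n_sites": self.n_sites,
            "n_records_with_ecosystem": self.n_records_with_ecosystem,
            "outlier_bounds": list(self.outlier_bounds),
            "sd_k": self.sd_k,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def filter_records(
    raw: pd.DataFrame,
    year_min: int = 1985,
    year_max: int = 2018,
    sd_k: float = 3.0,
    per_ecosystem: bool = False,
    columns: dict | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the four-step filter chain; returns (filtered table, report).

    Records with a fractional measurement year are assigned to the integer
    floor year before the range check.  Outlier statistics are pooled over
    the whole surviving table unless ``per_ecosystem`` is set.  An empty
    result is legal and simply reported.
    """
    colmap = {**DEFAULT_COLUMNS, **(columns or {}), **raw.attrs.get("colmap", {})}
    rs, lat, lon, yr = (colmap[k] for k in ("rs", "lat", "lon", "year"))
    counts = {"raw": len(raw)}

    annual = raw[raw[rs].notna()]
    counts["annual_only"] = len(annual)

    meta = annual[annual[lat].notna() & annual[lon].notna() & annual[yr].notna()]
    counts["metadata_complete"] = len(meta)

    year_floor = np.floor(meta[yr].to_numpy(dtype=float))
    in_range = meta[(year_floor >= year_min) & (year_floor <= year_max)]
    counts["in_year_range"] = len(in_range)

    def bounds_of(vals: pd.Series) -> tuple[float, float]:
        mu, sd = vals.mean(), vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:  # degenerate: nothing can be an outlier
            return -np.inf, np.inf
        return mu - sd_k * sd, mu + sd_k * sd

    eco_col = colmap.get("ecosystem")
    if per_ecosystem and eco_col in in_range.columns:
        keep = pd.Series(False, index=in_range.index)
        lo_all, hi_all = np.inf, -np.inf
        for _, grp in in_range.groupby(eco_col, dropna=False):
            lo, hi = bounds_of(grp[rs])
            lo_all, hi_all = min(lo_all, lo), max(hi_all, hi)
            keep.loc[grp.index] = grp[rs].between(lo, hi)
        filtered = in_range[keep]
        bounds = (lo_all, hi_all)
    else:
        bounds = bounds_of(in_range[rs])
        filtered = in_range[in_range[rs].between(*bounds)]
    counts["post_outlier"] = len(filtered)

    site_col = colmap["site"]
    report = FilterReport(
        counts=counts,
        n_sites=int(filtered[site_col].nunique()) if len(filtered) else 0,
        n_records_with_ecosystem=(
            int(filtered[eco_col].notna().sum())
            if eco_col in filtered.columns
            else len(filtered)
        ),
        outlier_bounds=bounds,
        sd_k=sd_k,
    )
    return filtered.copy(), report


def site_blocked_split(
    filtered: pd.DataFrame,
    train_frac: float = 0.8,
    per_ecosystem: bool = True,
    seed: int = 0,
    columns: dict | None = None,
) -> pd.Series:
    """Assign each record to 'train' or 'test' with whole sites kept together.

    Within each ecosystem class (or globally when ``per_ecosystem`` is
    False), the share of *sites* in the training fold is the closest
    achievable to ``train_frac``; an ecosystem with a single site sends it
    to train with a warning.  The train/test Site_ID sets are disjoint by
    construction.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    colmap = {**DEFAULT_COLUMNS, **(columns or {}), **filtered.attrs.get("colmap", {})}
    site_col, eco_col = colmap["site"], colmap.get("ecosystem")
    rng = np.random.default_rng(seed)

    if per_ecosystem and eco_col in filtered.columns:
        groups = filtered.groupby(eco_col, dropna=False)[site_col].unique()
    else:
        groups = pd.Series({"all": filtered[site_col].unique()})

    train_sites: set = set()
    for eco, sites in groups.items():
        sites = np.asarray(sorted(map(str, sites)))
        if len(sites) == 1:
            warnings.warn(
                f"ecosystem {eco!r} has a single site; assigned to train",
                stacklevel=2,
            )
            train_sites.add(sites[0])
            continue
        rng.shuffle(sites)
        n_train = int(np.clip(round(train_frac * len(sites)), 1, len(sites) - 1))
        train_sites.update(sites[:n_train])

    fold = np.where(
        filtered[site_col].astype(str).isin(train_sites), "train", "test"
    )
    return pd.Series(fold, index=filtered.index, name="fold")
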