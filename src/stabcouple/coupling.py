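"""Above-belowground stability coupling maps and their summaries.

Coupling at a cell is the Pearson correlation between two stability series
computed over the same moving windows (e.g. NPP stability vs soil
respiration stability over 25 decadal windows).  Because consecutive
windows share most of their years, the window series are strongly
autocorrelated and the nominal t test for a correlation is badly
anticonservative; significance here therefore defaults to an
effective-sample-size correction in the Pyper-Peterman style: n_eff is n
divided by 1 + 2*sum_k (1 - k/n) rho_A(k)*rho_B(k), the Bartlett-weighted
sum over all lags, and each cell's critical |r| comes from the t
distribution at that cell's n_eff.  The uncorrected threshold (0.396 at
25 windows, alpha = 0.05) remains available via ``dof_correction="none"``.

Also here: the joint low/high percentile classification of two stability
maps, stratified coupling summaries over ecosystem or aridity classes, and
the dominant-predictor map (which annual driver co-varies most with annual
respiration in each cell).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stability import AridityClassMap, StabilityMap, WindowedStability

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingMap",
    "BivariateClassMap",
    "BIVARIATE_CLASSES",
    "r_critical",
    "windowed_coupling",
    "bivariate_class_map",
    "stratified_mean_r",
    "dominant_predictor_map",
]


def r_critical(n: float, alpha: float = 0.05) -> float:
    """Two-sided critical |r| for a Pearson correlation with n samples."""
    if n < 3:
        return 1.0
    t = stats.t.ppf(1 - alpha / 2, n - 2)
    return float(t / np.sqrt(n - 2 + t * t))


@dataclass
class CouplingMap:
    """Per-cell windowed correlation with its significance threshold.

    ``r_crit`` is a scalar under ``dof_correction="none"`` and a per-cell
    array under the overlap correction (each cell's threshold reflects its
    own effective sample size); the flag is |r| >= r_crit either way.
    """

    r: np.ndarray
    n_windows: int
    r_crit: float | np.ndarray
    alpha: float
    n_eff: float
    dof_correction: str

    @property
    def significant(self) -> np.ndarray:
        """True where the correlation is defined and |r| >= r_crit."""
        with np.errstate(invalid="ignore"):
            return np.isfinite(self.r) & (np.abs(self.r) >= self.r_crit)

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.r)


def _acf_stack(z: np.ndarray, maxlag: int) -> np.ndarray:
    """Autocorrelations (lag, cell...) of already-centred window series."""
    denom = (z * z).sum(axis=0)
    out = np.empty((maxlag,) + z.shape[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in range(1, maxlag + 1):
            out[k - 1] = (z[:-k] * z[k:]).sum(axis=0) / denom
    return out


def windowed_coupling(
    series_a: WindowedStability,
    series_b: WindowedStability,
    alpha: float = 0.05,
    dof_correction: str = "overlap",
) -> CouplingMap:
    """Per-cell Pearson r between two window-stability series.

    Cells with an undefined stability in any window of either series are
    masked (listwise).  With ``dof_correction="overlap"`` (default) the
    critical |r| uses the Pyper-Peterman effective sample size at the
    median over valid cells; ``"none"`` uses the plain t threshold at the
    window count.
    """
    if series_a.n_windows != series_b.n_windows:
        raise ValueError("window counts differ between the two series")
    n = series_a.n_windows
    if n < 3:
        raise ValueError("need at least 3 windows for a correlation")
    if dof_correction not in ("overlap", "none"):
        raise ValueError(f"unknown dof_correction {dof_correction!r}")

    a = np.asarray(series_a.values, dtype=float)
    b = np.asarray(series_b.values, dtype=float)
    valid = np.isfinite(a).all(axis=0) & np.isfinite(b).all(axis=0)
    za = np.where(valid, a - a.mean(axis=0), np.nan)
    zb = np.where(valid, b - b.mean(axis=0), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (za * zb).sum(axis=0) / np.sqrt(
            (za * za).sum(axis=0) * (zb * zb).sum(axis=0)
        )
    r[~valid] = np.nan

    if dof_correction == "overlap":
        maxlag = n - 2
        aca, acb = _acf_stack(za, maxlag), _acf_stack(zb, maxlag)
        # Bartlett-type weights (1 - k/n): the asymptotic variance of r
        # between two independent autocorrelated series
        wgt = (1 - np.arange(1, maxlag + 1) / n)[:, None, None]
        with np.errstate(invalid="ignore"):
            infl = 1 + 2 * np.nansum(wgt * aca * acb, axis=0)
        n_eff_cells = np.clip(n / np.clip(infl, 1.0, None), 3.0, float(n))
        rc = np.full(r.shape, np.nan)
        tcrit = stats.t.ppf(1 - alpha / 2, n_eff_cells[valid] - 2)
        rc[valid] = tcrit / np.sqrt(n_eff_cells[valid] - 2 + tcrit**2)
        n_eff = float(np.nanmedian(np.where(valid, n_eff_cells, np.nan)))
        return CouplingMap(r, n, rc, alpha, n_eff, dof_correction)
    return CouplingMap(r, n, r_critical(float(n), alpha), alpha, float(n), dof_correction)


BIVARIATE_CLASSES = ("low-low", "low-high", "high-low", "high-high", "intermediate")


@dataclass
class BivariateClassMap:
    """Joint low/high classification of two maps against their own percentiles."""

    classes: np.ndarray  # codes into BIVARIATE_CLASSES, -1 undefined
    thresholds: dict
    labels: tuple = BIVARIATE_CLASSES

    def counts(self) -> pd.Series:
        vals, cnt = np.unique(self.classes[self.classes >= 0], return_counts=True)
        out = pd.Series(0, index=list(self.labels))
        for v, c in zip(vals, cnt):
            out.iloc[v] = c
        return out


def bivariate_class_map(
    stab_a: StabilityMap,
    stab_b: StabilityMap,
    p_low: float = 10,
    p_high: float = 90,
) -> BivariateClassMap:
    """Classify cells jointly as low/high tails of two stability maps.

    'Low' means at or below a map's own ``p_low`` percentile, 'high' at or
    above its ``p_high`` percentile (computed over defined cells only);
    everything else is intermediate.  A degenerate map whose percentiles
    coincide classifies all its cells as intermediate.
    """
    va, vb = stab_a.values, stab_b.values
    if va.shape != vb.shape:
        raise ValueError("stability maps on different grids")
    valid = np.isfinite(va) & np.isfinite(vb)
    out = np.full(va.shape, -1, dtype=int)
    thr = {}
    flags = {}
    for key, v in (("a", va), ("b", vb)):
        lo, hi = np.nanpercentile(v[valid], [p_low, p_high]) if valid.any() else (np.nan, np.nan)
        thr[key] = (float(lo), float(hi))
        if lo < hi:
            low, high = valid & (v <= lo), valid & (v >= hi)
        else:  # degenerate: percentiles coincide, everything is intermediate
            low = high = np.zeros_like(valid)
        flags[key] = (low, high)
    low_a, high_a = flags["a"]
    low_b, high_b = flags["b"]
    out[valid] = 4  # intermediate unless a tail combination applies
    out[low_a & low_b] = 0
    out[low_a & high_b] = 1
    out[high_a & low_b] = 2
    out[high_a & high_b] = 3
    return BivariateClassMap(out, {"a": thr["a"], "b": thr["b"], "p": (p_low, p_high)})


def stratified_mean_r(coupling: CouplingMap, strata, labels=None) -> pd.DataFrame:
    """Mean, SD and cell count of coupling r per stratum.

    ``strata`` is an integer class map (ecosystem codes) or an
    AridityClassMap, whose classes are already ordered dry to humid.
    Empty strata are reported with count 0.
    """
    if isinstance(strata, AridityClassMap):
        codes = strata.classes
        labels = labels or list(strata.labels)
    else:
        codes = np.asarray(strata)
    if codes.shape != coupling.r.shape:
        raise ValueError("strata map not aligned with coupling grid")
    r = coupling.r
    sig = coupling.significant
    n_classes = (max(int(codes.max()), len(labels) - 1 if labels else 0) + 1) if codes.size else 0
    rows = []
    for k in range(n_classes):
        m = (codes == k) & np.isfinite(r)
        name = labels[k] if labels is not None and k < len(labels) else k
        if not m.any():
            rows.append({"stratum": name, "mean_r": np.nan, "sd_r": np.nan,
                         "n_cells": 0, "frac_significant": np.nan})
            continue
        rows.append(
            {
                "stratum": name,
                "mean_r": float(r[m].mean()),
                "sd_r": float(r[m].std(ddof=1)) if m.sum() > 1 else np.nan,
                "n_cells": int(m.sum()),
                "frac_significant": float(sig[m].mean()),
            }
        )
    return pd.DataFrame(rows)


def dominant_predictor_map(
    rs_stack,
    predictor_stacks: dict,
    method: str = "correlation",
) -> tuple[np.ndarray, list[str]]:
    """Which predictor's annual series co-varies most with annual respiration.

    Per cell, the contribution of each predictor is the absolute Pearson
    correlation of its annual series with the respiration series
    (``method="correlation"``, default) or the absolute standardized
    regression coefficient from a joint linear fit (``method="std_coef"``).
    Ties break by the order of ``predictor_stacks``; cells where every
    contribution is undefined are coded -1.

    Returns (code map, predictor names in code order).
    """
    import xarray as _xr

    def _arr(x):
        if isinstance(x, _xr.DataArray):
            x = x.transpose("year", "row", "col").values
        return np.asarray(x, dtype=float)

    names = list(predictor_stacks)
    rs = _arr(rs_stack)
    preds = [_arr(p) for p in predictor_stacks.values()]
    Y = rs.shape[0]
    if Y < 3:
        raise ValueError("need at least 3 years")
    if method not in ("correlation", "std_coef"):
        raise ValueError(f"unknown method {method!r}")

    zr = rs - rs.mean(axis=0)
    sr = np.sqrt((zr * zr).sum(axis=0))
    contribs = np.empty((len(preds),) + rs.shape[1:])
    if method == "correlation":
        for i, p in enumerate(preds):
            zp = p - p.mean(axis=0)
            sp = np.sqrt((zp * zp).sum(axis=0))
            with np.errstate(invalid="ignore", divide="ignore"):
                contribs[i] = np.abs((zr * zp).sum(axis=0) / (sr * sp))
    else:
        R, C = rs.shape[1:]
        contribs[:] = np.nan
        for rr in range(R):
            for cc in range(C):
                X = np.column_stack([p[:, rr, cc] for p in preds])
                y = rs[:, rr, cc]
                sx = X.std(axis=0, ddof=1)
                sy = y.std(ddof=1)
                if sy == 0 or np.any(~np.isfinite(X)) or np.any(sx == 0):
                    continue
                Z = (X - X.mean(axis=0)) / sx
                b, *_ = np.linalg.lstsq(
                    np.column_stack([np.ones(Y), Z]), (y - y.mean()) / sy, rcond=None
                )
                contribs[:, rr, cc] = np.abs(b[1:])

    contribs = np.where(np.isfinite(contribs), contribs, -np.inf)
    all_bad = np.all(contribs == -np.inf, axis=0)
    codes = np.argmax(contribs, axis=0)  # argmax keeps the first (fixed order) on ties
    codes[all_bad] = -1
    if all_bad.any():
        logger.info("dominant_predictor_map: %d cells undefined", int(all_bad.sum()))
    return codes, names
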