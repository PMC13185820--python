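"""Soil-respiration upscaling: per-ecosystem nonlinear stepwise regression.

The regression predicts annual soil respiration from the six composite
environmental indices and their squares,

    Rs = b0 + b1*Cli + b2*Cli^2 + b3*Plant + b4*Plant^2 + b5*Gra + b6*Gra^2
            + b7*Mic + b8*Mic^2 + b9*Phy + b10*Phy^2 + b11*Chem + b12*Chem^2 + e,

fitted separately within each ecosystem class.  Term selection is stepwise
(bidirectional, starting from the intercept-only model); the criterion is
configurable -- BIC by default, AIC, or classical partial-F entry/removal
p-values.  BIC is the default because with 12 candidate terms a per-term
false-inclusion rate must stay low for the selected support to be stable
across refits; AIC admits a spurious term with probability ~0.16 each.

Validation is site-blocked: all records of a Site_ID share a fold, so the
held-out metrics (Pearson R, MAE, RMSE) measure transfer to unseen sites
rather than interpolation within a site.  A vegetation-free random forest
(climate, soil, microbial and topography features only) provides an
independent reconstruction used to cross-check stability coupling without
any vegetation input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "INDEX_NAMES",
    "EQ1_TERMS",
    "Selection",
    "RegressionFitSet",
    "ValidationMetrics",
    "eq1_design_matrix",
    "eq1_evaluate",
    "fit_eq1",
    "predict_grid",
    "validate",
    "fit_rf_novegetation",
    "rf_predict_grid",
]

INDEX_NAMES = ["Cli", "Plant", "Gra", "Mic", "Phy", "Chem"]
EQ1_TERMS = [t for n in INDEX_NAMES for t in (n, n + "2")]

#: feature names that would leak vegetation information into the "no
#: vegetation" random forest (matched case-insensitively as substrings)
VEGETATION_TAINTED = (
    "plant", "npp", "lai", "fvc", "gpp", "ndvi", "evi", "sif", "cue", "wue",
    "biomass", "vegetation",
)


def eq1_design_matrix(design: pd.DataFrame) -> pd.DataFrame:
    """The 12 candidate term columns (each index and its square)."""
    out = {}
    for name in INDEX_NAMES:
        x = design[name].to_numpy(dtype=float)
        out[name] = x
        out[name + "2"] = x * x
    return pd.DataFrame(out, index=design.index)


def eq1_evaluate(beta: np.ndarray, index_arrays: dict[str, np.ndarray]) -> np.ndarray:
    """Evaluate the regression for a 13-vector (b0 then term coefficients)."""
    out = np.full_like(next(iter(index_arrays.values())), beta[0], dtype=float)
    for j, term in enumerate(EQ1_TERMS, start=1):
        if beta[j] == 0:
            continue
        name = term.rstrip("2") if term.endswith("2") else term
        x = index_arrays[name]
        out = out + beta[j] * (x * x if term.endswith("2") else x)
    return out


@dataclass
class Selection:
    """Stepwise-selection settings."""

    criterion: str = "bic"  # "bic" | "aic" | "pvalue"
    direction: str = "both"  # "both" | "forward"
    p_enter: float = 0.01
    p_remove: float = 0.05

    def __post_init__(self):
        if self.criterion not in ("bic", "aic", "pvalue"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.direction not in ("both", "forward"):
            raise ValueError(f"unknown direction {self.direction!r}")


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _ic(rss: float, n: int, k: int, criterion: str) -> float:
    pen = 2.0 if criterion == "aic" else np.log(n)
    return n * np.log(max(rss, 1e-300) / n) + pen * k


def _stepwise(X: pd.DataFrame, y: np.ndarray, sel: Selection) -> list[str]:
    """Bidirectional stepwise over candidate columns; returns selected names."""
    n = len(y)
    candidates = list(X.columns)
    included: list[str] = []

    def rss_of(cols):
        M = np.column_stack([np.ones(n)] + [X[c].to_numpy() for c in cols])
        return _ols(M, y)[1], M.shape[1]

    current_rss, k = rss_of(included)
    for _ in range(4 * len(candidates)):
        changed = False
        # forward: best candidate by RSS reduction
        remaining = [c for c in candidates if c not in included]
        if remaining:
            trials = [(rss_of(included + [c])[0], c) for c in remaining]
            best_rss, best_c = min(trials)
            if sel.criterion == "pvalue":
                dfe = n - (k + 1)
                if dfe > 0 and best_rss > 0:
                    f = (current_rss - best_rss) / (best_rss / dfe)
                    accept = stats.f.sf(f, 1, dfe) < sel.p_enter
                else:  # perfect fit: any reduction to ~0 is accepted
                    accept = best_rss < current_rss * (1 - 1e-12)
            else:
                accept = _ic(best_rss, n, k + 1, sel.criterion) < _ic(
                    current_rss, n, k, sel.criterion
                )
            if accept:
                included.append(best_c)
                current_rss, k = best_rss, k + 1
                changed = True
        # backward: weakest included term
        if sel.direction == "both" and included:
            trials = [
                (rss_of([c for c in included if c != d])[0], d) for d in included
            ]
            worst_rss, worst_d = min(trials)
            if sel.criterion == "pvalue":
                dfe = n - k
                if dfe > 0 and current_rss > 0:
                    f = (worst_rss - current_rss) / (current_rss / dfe)
                    drop = stats.f.sf(f, 1, dfe) > sel.p_remove
                else:
                    drop = worst_rss <= current_rss * (1 + 1e-12)
            else:
                drop = _ic(worst_rss, n, k - 1, sel.criterion) <= _ic(
                    current_rss, n, k, sel.criterion
                )
            if drop:
                included.remove(worst_d)
                current_rss, k = worst_rss, k - 1
                changed = True
        if not changed:
            break
    return included


@dataclass
class RegressionFitSet:
    """Per-ecosystem coefficients, selected-term flags and diagnostics.

    ``coefficients`` has one row per fitted ecosystem class with columns
    b0 + the 12 terms; a term excluded by selection has coefficient exactly
    0 and flag False.
    """

    coefficients: pd.DataFrame
    included: pd.DataFrame
    resid_sd: pd.Series
    n_train: pd.Series
    selection: Selection
    skipped: list = field(default_factory=list)

    @property
    def ecosystems(self) -> list:
        return list(self.coefficients.index)

    def beta(self, eco) -> np.ndarray:
        return self.coefficients.loc[eco].to_numpy()

    def predict(self, design: pd.DataFrame, fallback=None) -> np.ndarray:
        """Predict rows of a design table, dispatching on the ecosystem column."""
        terms = eq1_design_matrix(design)
        out = np.full(len(design), np.nan)
        eco_col = design["ecosystem"].to_numpy()
        for e in np.unique(eco_col):
            key = e if e in self.coefficients.index else fallback
            if key is None or key not in self.coefficients.index:
                raise KeyError(f"no fit for ecosystem {e!r} and no fallback")
            b = self.coefficients.loc[key].to_numpy()
            m = eco_col == e
            out[m] = b[0] + terms.loc[m].to_numpy() @ b[1:]
        return out

    def to_json(self, path):
        payload = {
            "coefficients": self.coefficients.to_dict(orient="index"),
            "included": self.included.astype(bool).to_dict(orient="index"),
            "resid_sd": self.resid_sd.to_dict(),
            "n_train": self.n_train.to_dict(),
            "selection": vars(self.selection),
            "skipped": list(self.skipped),
        }
        import json

        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def fit_eq1(
    design: pd.DataFrame,
    selection: Selection | None = None,
    response: str = "Rs_annual",
    min_rows: int = 20,
) -> RegressionFitSet:
    """Fit the respiration regression per ecosystem class with stepwise selection.

    Classes with fewer than ``min_rows`` complete rows (13 parameters plus
    margin) are skipped with a warning and recorded in ``skipped``.
    Deterministic given the design table.
    """
    sel = selection or Selection()
    cols = ["b0"] + EQ1_TERMS
    coefs, flags, sds, ns, skipped = {}, {}, {}, {}, []
    for e, grp in design.groupby("ecosystem", sort=True):
        grp = grp.dropna(subset=INDEX_NAMES + [response])
        if len(grp) < min_rows:
            logger.warning("ecosystem %r: %d rows < %d, skipped", e, len(grp), min_rows)
            skipped.append(e)
            continue
        X = eq1_design_matrix(grp)
        y = grp[response].to_numpy(dtype=float)
        chosen = _stepwise(X, y, sel)
        M = np.column_stack([np.ones(len(y))] + [X[c].to_numpy() for c in chosen])
        beta_sel, rss = _ols(M, y)
        dfe = max(len(y) - M.shape[1], 1)
        b = pd.Series(0.0, index=cols)
        b["b0"] = beta_sel[0]
        for c, v in zip(chosen, beta_sel[1:]):
            b[c] = v
        coefs[e] = b
        flags[e] = pd.Series([t in chosen for t in EQ1_TERMS], index=EQ1_TERMS)
        sds[e] = np.sqrt(rss / dfe)
        ns[e] = len(y)
    if not coefs:
        raise ValueError("no ecosystem class had enough rows to fit")
    return RegressionFitSet(
        pd.DataFrame(coefs).T[cols],
        pd.DataFrame(flags).T[EQ1_TERMS],
        pd.Series(sds),
        pd.Series(ns),
        sel,
        skipped,
    )


def predict_grid(
    fits: RegressionFitSet,
    indices,
    ecosystem_map,
    eco_names=None,
    fallback=None,
) -> xr.DataArray:
    """Gridded annual respiration from fitted coefficients and index fields.

    ``ecosystem_map`` holds integer class codes; ``eco_names`` maps codes to
    the class labels used when fitting (defaults to the codes themselves).
    Negative predictions are floored at 0 with a logged count.
    """
    eco = np.asarray(
        ecosystem_map.values if hasattr(ecosystem_map, "values") else ecosystem_map
    )
    tv = [indices[n] for n in INDEX_NAMES if indices[n].time_varying]
    years = np.asarray(tv[0].values["year"].values)
    Y = len(years)
    R, C = eco.shape
    arrays = {}
    for n in INDEX_NAMES:
        ci = indices[n]
        a = np.asarray(ci.values.values, dtype=float)
        arrays[n] = a if ci.time_varying else np.broadcast_to(a, (Y, R, C))

    out = np.full((Y, R, C), np.nan)
    for code in np.unique(eco):
        label = eco_names(code) if callable(eco_names) else (
            eco_names[code] if eco_names is not None else code
        )
        key = label if label in fits.coefficients.index else fallback
        if key is None or key not in fits.coefficients.index:
            raise KeyError(f"no fit for ecosystem {label!r} and no fallback")
        m = eco == code
        out[:, m] = eq1_evaluate(fits.beta(key), {n: arrays[n][:, m] for n in INDEX_NAMES})
    neg = int((out < 0).sum())
    if neg:
        logger.info("predict_grid: floored %d negative cell-year predictions", neg)
    out = np.clip(out, 0, None)
    return xr.DataArray(
        out,
        dims=("year", "row", "col"),
        coords={"year": years, "row": np.arange(R), "col": np.arange(C)},
        name="Rs_pred",
    )


@dataclass
class ValidationMetrics:
    """Held-out agreement between predicted and observed respiration."""

    r: float
    mae: float
    rmse: float
    n_test: int
    per_ecosystem: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        return {"R": self.r, "MAE": self.mae, "RMSE": self.rmse, "n_test": self.n_test}


def _metrics(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float]:
    err = yhat - y
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if len(y) < 2 or np.std(y) == 0 or np.std(yhat) == 0:
        r = float("nan")  # undefined for constant series, reported as missing
    else:
        r = float(np.corrcoef(y, yhat)[0, 1])
    return r, mae, rmse


def validate(
    fits: RegressionFitSet,
    design: pd.DataFrame,
    folds,
    response: str = "Rs_annual",
    fallback=None,
) -> ValidationMetrics:
    """R / MAE / RMSE on held-out records, with a per-ecosystem breakdown."""
    test = design.loc[np.asarray(folds) == "test"]
    if test.empty:
        raise ValueError("empty test fold")
    yhat = fits.predict(test, fallback=fallback)
    y = test[response].to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(yhat)
    r, mae, rmse = _metrics(y[ok], yhat[ok])
    rows = {}
    for e, grp in test.loc[ok].groupby("ecosystem"):
        ge = fits.predict(grp, fallback=fallback)
        rr, mm, ss = _metrics(grp[response].to_numpy(dtype=float), ge)
        rows[e] = {"R": rr, "MAE": mm, "RMSE": ss, "n": len(grp)}
    return ValidationMetrics(r, mae, rmse, int(ok.sum()), pd.DataFrame(rows).T)


def _check_untainted(feature_cols) -> None:
    bad = [
        c for c in feature_cols if any(t in c.lower() for t in VEGETATION_TAINTED)
    ]
    if bad:
        raise ValueError(f"vegetation-tainted features not allowed here: {bad}")


def fit_rf_novegetation(
    design: pd.DataFrame,
    n_trees: int = 5000,
    cv_folds: int = 10,
    seed: int = 0,
    feature_cols: tuple[str, ...] = ("Cli", "Gra", "Mic", "Phy", "Chem"),
    response: str = "Rs_annual",
) -> tuple[RandomForestRegressor, ValidationMetrics]:
    """Random-forest respiration model with all vegetation features excluded.

    Guards against vegetation-derived columns by name, runs seeded k-fold CV
    (metrics pooled over held-out predictions), then refits on all rows.
    """
    _check_untainted(feature_cols)
    d = design.dropna(subset=list(feature_cols) + [response])
    X = d[list(feature_cols)].to_numpy(dtype=float)
    y = d[response].to_numpy(dtype=float)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    yhat = np.empty_like(y)
    for tr, te in kf.split(X):
        m = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
        m.fit(X[tr], y[tr])
        yhat[te] = m.predict(X[te])
    r, mae, rmse = _metrics(y, yhat)
    model = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    model.fit(X, y)
    model.feature_names_ = list(feature_cols)
    return model, ValidationMetrics(r, mae, rmse, len(y))


def rf_predict_grid(model: RandomForestRegressor, indices) -> xr.DataArray:
    """Evaluate a fitted (vegetation-free) forest on every grid cell-year."""
    feats = list(getattr(model, "feature_names_", ("Cli", "Gra", "Mic", "Phy", "Chem")))
    _check_untainted(feats)
    tv = [indices[n] for n in feats if indices[n].time_varying]
    years = np.asarray(tv[0].values["year"].values) if tv else np.array([0])
    first = indices[feats[0]].values
    R, C = first.shape[-2:]
    Y = len(years)
    cols = []
    for n in feats:
        ci = indices[n]
        a = np.asarray(ci.values.values, dtype=float)
        if not ci.time_varying:
            a = np.broadcast_to(a, (Y, R, C))
        cols.append(a.reshape(Y * R * C))
    X = np.column_stack(cols)
    pred = model.predict(X).reshape(Y, R, C)
    return xr.DataArray(
        pred,
        dims=("year", "row", "col"),
        coords={"year": years, "row": np.arange(R), "col": np.arange(C)},
        name="Rs_rf",
    )
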