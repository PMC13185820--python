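"""Stepwise regression oracles, grid prediction, validation metrics, RF guard."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from stabcouple.composite_indices import CategoryIndex, CompositeIndexSet
from stabcouple.srdb_ingest import site_blocked_split
from stabcouple.upscaling import (
    EQ1_TERMS,
    INDEX_NAMES,
    RegressionFitSet,
    Selection,
    ValidationMetrics,
    fit_eq1,
    fit_rf_novegetation,
    predict_grid,
    rf_predict_grid,
    validate,
)

STRICT = Selection("pvalue", p_enter=0.005, p_remove=0.01)


def _design(rng, n, beta=None, noise=0.1, eco="all"):
    """Simulated design table with standard-normal indices."""
    d = pd.DataFrame({k: rng.normal(size=n) for k in INDEX_NAMES})
    y = np.zeros(n)
    if beta:
        for term, b in beta.items():
            if term == "b0":
                y += b
            elif term.endswith("2"):
                y += b * d[term[:-1]] ** 2
            else:
                y += b * d[term]
    y += rng.normal(0, noise, n)
    d["Rs_annual"] = y
    d["ecosystem"] = eco
    return d


class TestFitEq1:
    def test_sparse_generating_model_recovered_exactly(self, rng):
        """Rs = 2 + 3*Cli - 1*Plant^2 + small noise -> exactly those terms."""
        design = _design(rng, 500, {"b0": 2, "Cli": 3, "Plant2": -1}, noise=0.1)
        fits = fit_eq1(design, STRICT)
        inc = fits.included.loc["all"]
        assert set(inc[inc].index) == {"Cli", "Plant2"}
        assert fits.coefficients.loc["all", "Cli"] == pytest.approx(3, abs=0.05)
        assert fits.coefficients.loc["all", "Plant2"] == pytest.approx(-1, abs=0.05)
        assert fits.coefficients.loc["all", "b0"] == pytest.approx(2, abs=0.05)

    def test_noiseless_full_model_interpolated(self, rng):
        beta = {"b0": 5.0}
        beta.update({t: 1.0 + 0.1 * i for i, t in enumerate(EQ1_TERMS)})
        design = _design(rng, 400, beta, noise=0.0)
        fits = fit_eq1(design, Selection("bic"))
        for t in EQ1_TERMS:
            assert fits.coefficients.loc["all", t] == pytest.approx(beta[t], abs=1e-6)

    def test_pure_noise_keeps_intercept_only_in_most_replicates(self):
        rng = np.random.default_rng(12345)
        clean = 0
        for _ in range(100):
            design = _design(rng, 300, {"b0": 1.0}, noise=1.0)
            fits = fit_eq1(design, STRICT)
            clean += not fits.included.loc["all"].any()
        assert clean >= 90

    def test_excluded_terms_are_exactly_zero(self, rng):
        design = _design(rng, 500, {"b0": 1, "Cli": 5}, noise=0.2)
        fits = fit_eq1(design, STRICT)
        excluded = ~fits.included.loc["all"]
        assert (fits.coefficients.loc["all", EQ1_TERMS][excluded.values] == 0).all()

    def test_underdetermined_class_skipped_with_warning(self, rng):
        d1 = _design(rng, 100, {"b0": 1, "Cli": 2}, eco="big")
        d2 = _design(rng, 5, {"b0": 1}, eco="tiny")
        fits = fit_eq1(pd.concat([d1, d2], ignore_index=True), STRICT)
        assert "tiny" in fits.skipped
        assert "big" in fits.ecosystems

    def test_no_fittable_class_raises(self, rng):
        with pytest.raises(ValueError):
            fit_eq1(_design(rng, 4, {"b0": 1}), STRICT)


def _mini_indices(rng, Y=4, R=3, C=3, zero=False):
    indices = {}
    years = np.arange(1985, 1985 + Y)
    for i, n in enumerate(INDEX_NAMES):
        tv = n in ("Cli", "Plant")
        if zero:
            arr = np.zeros((Y, R, C)) if tv else np.zeros((R, C))
        else:
            arr = rng.normal(size=(Y, R, C)) if tv else rng.normal(size=(R, C))
        da = (
            xr.DataArray(arr, dims=("year", "row", "col"), coords={"year": years})
            if tv
            else xr.DataArray(arr, dims=("row", "col"))
        )
        indices[n] = CategoryIndex(
            n, da, pd.Series([1.0], index=["x"]), 1.0,
            pd.DataFrame({"mean": [0.0], "sd": [1.0]}, index=["x"]), tv,
        )
    return CompositeIndexSet(indices)


def _fitset(coeffs: dict) -> RegressionFitSet:
    cols = ["b0"] + EQ1_TERMS
    table = pd.DataFrame({e: pd.Series(c, index=cols).fillna(0.0) for e, c in coeffs.items()}).T
    inc = table[EQ1_TERMS] != 0
    return RegressionFitSet(table[cols], inc, pd.Series(0.0, index=table.index),
                            pd.Series(0, index=table.index), Selection())


class TestPredictGrid:
    def test_zero_indices_return_intercept_per_class(self, rng):
        idx = _mini_indices(rng, zero=True)
        eco = np.array([[0, 0, 1], [1, 0, 1], [0, 1, 0]])
        fits = _fitset({0: {"b0": 3.0, "Cli": 2.0}, 1: {"b0": 7.0}})
        pred = predict_grid(fits, idx, eco)
        assert np.allclose(pred.values[:, eco == 0], 3.0)
        assert np.allclose(pred.values[:, eco == 1], 7.0)

    def test_changing_one_cell_class_only_changes_that_cell(self, rng):
        idx = _mini_indices(rng)
        eco = np.zeros((3, 3), dtype=int)
        fits = _fitset({0: {"b0": 3.0, "Plant": 2.0}, 1: {"b0": 9.0, "Plant": -1.0}})
        base = predict_grid(fits, idx, eco).values
        eco2 = eco.copy()
        eco2[1, 1] = 1
        changed = predict_grid(fits, idx, eco2).values
        diff = np.abs(base - changed).sum(axis=0)
        assert diff[1, 1] > 0
        diff[1, 1] = 0
        assert np.allclose(diff, 0)

    def test_negative_predictions_floored(self, rng):
        idx = _mini_indices(rng, zero=True)
        fits = _fitset({0: {"b0": -5.0}})
        pred = predict_grid(fits, idx, np.zeros((3, 3), dtype=int))
        assert (pred.values == 0).all()

    def test_unmapped_class_without_fallback_raises(self, rng):
        idx = _mini_indices(rng)
        fits = _fitset({0: {"b0": 1.0}})
        with pytest.raises(KeyError):
            predict_grid(fits, idx, np.full((3, 3), 5))

    def test_unmapped_class_uses_fallback(self, rng):
        idx = _mini_indices(rng, zero=True)
        fits = _fitset({0: {"b0": 4.0}})
        pred = predict_grid(fits, idx, np.full((3, 3), 5), fallback=0)
        assert np.allclose(pred.values, 4.0)


class TestValidate:
    def test_perfect_predictions(self, rng):
        design = _design(rng, 60, {"b0": 2, "Cli": 3}, noise=0.0)
        fits = _fitset({"all": {"b0": 2.0, "Cli": 3.0}})
        folds = np.array(["test"] * 60)
        m = validate(fits, design, folds)
        assert m.r == pytest.approx(1.0)
        assert m.mae == pytest.approx(0.0, abs=1e-10)
        assert m.rmse == pytest.approx(0.0, abs=1e-10)

    def test_constant_prediction_reports_missing_r(self, rng):
        design = _design(rng, 50, {"b0": 2, "Cli": 3}, noise=0.1)
        fits = _fitset({"all": {"b0": 5.0}})
        m = validate(fits, design, np.array(["test"] * 50))
        assert np.isnan(m.r)
        y = design["Rs_annual"]
        assert m.mae == pytest.approx(np.abs(y - 5.0).mean())

    def test_rmse_at_least_mae(self, rng):
        design = _design(rng, 200, {"b0": 1, "Plant": 2}, noise=0.5)
        fits = fit_eq1(design, STRICT)
        folds = np.where(rng.random(200) < 0.7, "train", "test")
        m = validate(fits, design, folds)
        assert m.rmse >= m.mae >= 0

    def test_empty_test_fold_raises(self, rng):
        design = _design(rng, 30, {"b0": 1})
        with pytest.raises(ValueError):
            validate(_fitset({"all": {"b0": 1.0}}), design, np.array(["train"] * 30))


class TestVegetationFreeForest:
    def test_vegetation_tainted_feature_rejected(self, rng):
        design = _design(rng, 100, {"b0": 1})
        design["NPP_mean"] = rng.normal(size=100)
        with pytest.raises(ValueError, match="vegetation"):
            fit_rf_novegetation(design, n_trees=10, cv_folds=2,
                                feature_cols=("Cli", "NPP_mean"))

    def test_plant_index_rejected(self, rng):
        design = _design(rng, 100, {"b0": 1})
        with pytest.raises(ValueError, match="vegetation"):
            fit_rf_novegetation(design, n_trees=10, cv_folds=2,
                                feature_cols=("Cli", "Plant"))

    def test_seeded_determinism(self, rng):
        design = _design(rng, 150, {"b0": 1, "Cli": 2, "Chem": 1}, noise=0.3)
        _, m1 = fit_rf_novegetation(design, n_trees=50, cv_folds=5, seed=3)
        _, m2 = fit_rf_novegetation(design, n_trees=50, cv_folds=5, seed=3)
        assert m1.as_dict() == m2.as_dict()

    def test_shuffled_response_has_no_skill(self, rng):
        design = _design(rng, 400, {"b0": 1, "Cli": 3}, noise=0.2)
        design["Rs_annual"] = rng.permutation(design["Rs_annual"].to_numpy())
        _, m = fit_rf_novegetation(design, n_trees=100, cv_folds=5, seed=0)
        assert abs(m.r) < 0.15

    def test_grid_prediction_matches_model_on_features(self, rng):
        design = _design(rng, 200, {"b0": 1, "Cli": 2}, noise=0.2)
        model, _ = fit_rf_novegetation(design, n_trees=30, cv_folds=4, seed=1)
        idx = _mini_indices(rng)
        pred = rf_predict_grid(model, idx)
        assert pred.shape == (4, 3, 3)
        assert np.isfinite(pred.values).all()


class TestLeakageProperty:
    def test_site_blocked_cv_not_better_than_random_split(self, coupled_world):
        """With per-site noise, blocking sites cannot look better than mixing
        a site's years across folds."""
        from stabcouple import sample_sites
        from stabcouple.composite_indices import extract_at_sites

        rng = np.random.default_rng(5)
        tab = sample_sites(coupled_world, n_sites=150, max_years_per_site=8,
                           obs_noise_sd=30.0, site_effect_sd=150.0, seed=6)
        design = extract_at_sites(coupled_world.indices, tab)

        def cv_r(folds):
            fits = fit_eq1(design[np.asarray(folds) == "train"], Selection("bic"))
            pooled = fit_eq1(design.assign(ecosystem="__g__"), Selection("bic"))
            fits.coefficients.loc["__g__"] = pooled.coefficients.loc["__g__"]
            return validate(fits, design, folds, fallback="__g__").r

        blocked = site_blocked_split(
            design, seed=1, columns={"site": "Site_ID", "ecosystem": "ecosystem"}
        )
        random_folds = np.where(rng.random(len(design)) < 0.8, "train", "test")
        assert cv_r(blocked) <= cv_r(random_folds)


def test_validation_metrics_dict_roundtrip():
    m = ValidationMetrics(0.9, 10.0, 12.0, 100)
    assert m.as_dict() == {"R": 0.9, "MAE": 10.0, "RMSE": 12.0, "n_test": 100}
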