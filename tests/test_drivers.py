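"""Coarse-grid aggregation, importance, partial correlations, varpart, SEM."""

import numpy as np
import pandas as pd
import pytest

from stabcouple.drivers import (
    DEFAULT_SEM_SPEC,
    aggregate_to_degree,
    fit_sem,
    partial_correlations,
    productivity_pc1,
    rf_importance,
    variance_partition,
)
from stabcouple.stability import StabilityMap


class TestAggregateToDegree:
    def test_uniform_map_aggregates_to_constant(self):
        maps = {"v": StabilityMap(np.full((8, 8), 3.0), (0, 1))}
        out = aggregate_to_degree(maps, np.zeros((8, 8), dtype=int))
        assert np.allclose(out["v"], 3.0)
        assert len(out) == 4  # 8x8 fine cells -> 2x2 blocks of 4x4

    def test_small_block_mean(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        maps = {"v": StabilityMap(vals, (0, 1))}
        out = aggregate_to_degree(maps, np.zeros((2, 2), dtype=int),
                                  cell_deg=0.5, fine_deg=0.25)
        assert out["v"].iloc[0] == pytest.approx(2.5)

    def test_matches_brute_force_groupby_oracle(self, rng):
        vals = rng.normal(size=(12, 12))
        vals[rng.random((12, 12)) < 0.1] = np.nan
        eco = rng.integers(0, 3, (12, 12))
        out = aggregate_to_degree({"v": StabilityMap(vals, (0, 1))}, eco)
        for _, row in out.iterrows():
            bi, bj = int(row["coarse_row"]), int(row["coarse_col"])
            block = vals[bi * 4:(bi + 1) * 4, bj * 4:(bj + 1) * 4]
            assert row["v"] == pytest.approx(np.nanmean(block), rel=1e-12)
            eco_block = eco[bi * 4:(bi + 1) * 4, bj * 4:(bj + 1) * 4]
            v, c = np.unique(eco_block, return_counts=True)
            assert row["ecosystem"] == v[np.argmax(c)]

    def test_blocks_below_valid_fraction_dropped(self):
        vals = np.full((8, 8), 2.0)
        vals[:4, :4] = np.nan  # first block fully invalid
        out = aggregate_to_degree({"v": StabilityMap(vals, (0, 1))},
                                  np.zeros((8, 8), dtype=int))
        assert len(out) == 3

    def test_nothing_valid_raises(self):
        with pytest.raises(ValueError):
            aggregate_to_degree({"v": StabilityMap(np.full((4, 4), np.nan), (0, 1))},
                                np.zeros((4, 4), dtype=int))


class TestProductivityPC1:
    def test_identical_columns_fully_explained(self, rng):
        x = rng.normal(size=200)
        scores, ve = productivity_pc1(x, x)
        assert ve == pytest.approx(1.0)
        assert np.corrcoef(scores, x)[0, 1] == pytest.approx(1.0)

    def test_independent_columns_split_variance(self, rng):
        scores, ve = productivity_pc1(rng.normal(size=3000), rng.normal(size=3000))
        assert ve == pytest.approx(0.5, abs=0.05)

    def test_matches_eigendecomposition_oracle(self, rng):
        a = rng.normal(size=300)
        b = 0.6 * a + rng.normal(0, 0.8, 300)
        scores, ve = productivity_pc1(a, b)
        z = np.column_stack([(a - a.mean()) / a.std(ddof=1), (b - b.mean()) / b.std(ddof=1)])
        evals, evecs = np.linalg.eigh(np.cov(z, rowvar=False))
        v1 = evecs[:, np.argmax(evals)]
        if v1[0] < 0:
            v1 = -v1
        np.testing.assert_allclose(scores, z @ v1, atol=1e-10)
        assert ve == pytest.approx(evals.max() / evals.sum())

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            productivity_pc1(np.ones(50), rng.normal(size=50))


def _sample(rng, n=300, couple=0.7):
    ts, ps, ai = rng.normal(size=(3, n))
    prod = couple * ts + np.sqrt(1 - couple**2) * rng.normal(size=n)
    rs = 0.8 * prod + 0.3 * ts + rng.normal(0, 0.5, n)
    eco = rng.integers(0, 3, n)
    return pd.DataFrame({"temp_stab": ts, "precip_stab": ps, "ai_stab": ai,
                         "prod_pc1": prod, "rs_stab": rs, "ecosystem": eco})


class TestRFImportance:
    def test_perfect_signal_ranked_first_and_significant(self, rng):
        d = _sample(rng, 200)
        d["rs_stab"] = d["prod_pc1"]
        out = rf_importance(d, n_perm=99, n_trees=100, seed=1)
        assert out.loc[0, "predictor"] == "prod_pc1"
        assert out.loc[0, "p_perm"] < 0.05

    def test_shuffled_response_nothing_significant(self, rng):
        d = _sample(rng, 200)
        d["rs_stab"] = rng.permutation(d["rs_stab"].to_numpy())
        out = rf_importance(d, n_perm=99, n_trees=100, seed=2)
        assert (out["p_perm"] > 0.05).all()

    def test_constant_response_rejected(self, rng):
        d = _sample(rng, 100)
        d["rs_stab"] = 1.0
        with pytest.raises(ValueError):
            rf_importance(d, n_perm=9)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            rf_importance(_sample(rng, 30), n_perm=9)


class TestPartialCorrelations:
    def test_pure_signal_and_pure_noise_partials(self, rng):
        n = 400
        x1, x2 = rng.normal(size=(2, n))
        d = pd.DataFrame({"rs_stab": x1, "prod_pc1": x1 + 1e-9 * rng.normal(size=n),
                          "temp_stab": x2, "precip_stab": rng.normal(size=n),
                          "ai_stab": rng.normal(size=n)})
        out = partial_correlations(d, group_col=None).set_index("predictor")
        assert out.loc["prod_pc1", "partial_r"] > 0.999
        assert abs(out.loc["temp_stab", "partial_r"]) < 0.15

    def test_exact_additive_case(self, rng):
        n = 200
        x1, x2 = rng.normal(size=(2, n))
        d = pd.DataFrame({"rs_stab": x1 + x2, "prod_pc1": x1, "temp_stab": x2,
                          "precip_stab": rng.normal(size=n),
                          "ai_stab": rng.normal(size=n)})
        out = partial_correlations(d, group_col=None).set_index("predictor")
        assert out.loc["prod_pc1", "partial_r"] == pytest.approx(1.0, abs=1e-6)
        assert out.loc["temp_stab", "partial_r"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_independent_pingouin_oracle_per_group(self, rng):
        import pingouin as pg

        d = _sample(rng, 400)
        preds = ["prod_pc1", "temp_stab", "precip_stab", "ai_stab"]
        out = partial_correlations(d, group_col="ecosystem")
        for g, grp in d.groupby("ecosystem"):
            for x in preds:
                controls = [c for c in preds if c != x]
                expected = float(
                    pg.partial_corr(data=grp, x=x, y="rs_stab", covar=controls)["r"].iloc[0]
                )
                got = out[(out["group"] == g) & (out["predictor"] == x)]["partial_r"].iloc[0]
                assert got == pytest.approx(expected, abs=1e-8)

    def test_fdr_adjustment_never_decreases_p(self, rng):
        out = partial_correlations(_sample(rng, 300), group_col="ecosystem")
        ok = out["p"].notna()
        assert (out.loc[ok, "p_fdr"] >= out.loc[ok, "p"] - 1e-12).all()


class TestVariancePartition:
    def test_closure_of_raw_fractions(self, rng):
        vp = variance_partition(_sample(rng, 200))
        assert abs(sum(vp["raw"].values()) - 1.0) < 1e-10

    def test_orthogonal_single_driver(self, rng):
        n = 500
        x1 = rng.normal(size=n)
        d = pd.DataFrame({"rs_stab": x1 + rng.normal(0, 0.5, n), "prod_pc1": x1,
                          "temp_stab": rng.normal(size=n),
                          "precip_stab": rng.normal(size=n),
                          "ai_stab": rng.normal(size=n)})
        vp = variance_partition(d)
        assert vp["raw"]["unique1"] == pytest.approx(vp["r2"]["set1"], abs=0.02)
        assert abs(vp["raw"]["shared"]) < 0.02

    def test_duplicated_sets_share_everything(self, rng):
        n = 300
        x = rng.normal(size=n)
        d = pd.DataFrame({"rs_stab": x + rng.normal(0, 0.3, n), "a": x, "b": x})
        vp = variance_partition(d, set1=("a",), set2=("b",))
        assert abs(vp["raw"]["unique1"]) < 0.02
        assert abs(vp["raw"]["unique2"]) < 0.02
        assert vp["raw"]["shared"] == pytest.approx(vp["r2"]["full"], abs=0.05)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            variance_partition(_sample(rng, 20))


class TestSEM:
    def _generate(self, rng, n, beta_prod, beta_rs):
        ts, ps, ai = rng.normal(size=(3, n))
        lin = beta_prod[0] * ts + beta_prod[1] * ps + beta_prod[2] * ai
        prod = lin + np.sqrt(max(1 - np.sum(np.square(beta_prod)), 0.05)) * rng.normal(size=n)
        lin2 = beta_rs[0] * prod + beta_rs[1] * ts + beta_rs[2] * ps + beta_rs[3] * ai
        rs = lin2 + np.sqrt(max(1 - 0.6, 0.05)) * rng.normal(size=n)
        return pd.DataFrame({"temp_stab": ts, "precip_stab": ps, "ai_stab": ai,
                             "prod_pc1": prod, "rs_stab": rs})

    def test_paths_recovered_from_generative_model(self, rng):
        true_prod = (0.5, 0.3, 0.2)
        d = self._generate(rng, 2000, true_prod, (0.5, 0.2, 0.0, 0.0))
        res = fit_sem(d)
        paths = res.paths.set_index(["to", "from"])["coef"]
        for b, src in zip(true_prod, ("temp_stab", "precip_stab", "ai_stab")):
            assert paths[("prod_pc1", src)] == pytest.approx(b, abs=0.05)
        assert res.saturated  # default topology estimates every path

    def test_reduced_model_fit_criteria_pass_on_true_topology(self, rng):
        d = self._generate(rng, 2000, (0.5, 0.3, 0.2), (0.5, 0.2, 0.0, 0.0))
        spec = {"prod_pc1": ["temp_stab", "precip_stab", "ai_stab"],
                "rs_stab": ["prod_pc1", "temp_stab"]}
        res = fit_sem(d, spec)
        assert res.df > 0 and not res.saturated
        assert res.passed
        assert res.chi2_df <= 2 and res.rmsea <= 0.05

    def test_null_path_rarely_significant(self):
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(50):
            d = self._generate(rng, 400, (0.5, 0.3, 0.2), (0.0, 0.4, 0.0, 0.0))
            res = fit_sem(d)
            row = res.paths.set_index(["to", "from"]).loc[("rs_stab", "prod_pc1")]
            hits += bool(row["significant"])
        assert hits <= 5  # productivity->respiration path is truly zero

    def test_indirect_climate_path_on_coupled_generative_model(self, rng):
        d = self._generate(rng, 1000, (0.6, 0.2, 0.1), (0.6, 0.1, 0.0, 0.0))
        res = fit_sem(d)
        paths = res.paths.set_index(["to", "from"])
        assert paths.loc[("prod_pc1", "temp_stab"), "significant"]
        assert paths.loc[("rs_stab", "prod_pc1"), "significant"]
        indirect = (paths.loc[("prod_pc1", "temp_stab"), "coef"]
                    * paths.loc[("rs_stab", "prod_pc1"), "coef"])
        assert indirect > 0.2

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_sem(self._generate(rng, 50, (0.5, 0.3, 0.2), (0.5, 0.2, 0, 0)))
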