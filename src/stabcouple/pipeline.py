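"""End-to-end orchestration: world -> records -> product -> coupling -> drivers.

One master seed expands deterministically (via numpy SeedSequence) into
per-stage seeds, so stages are independently reproducible and a rerun with
an identical config writes byte-identical outputs; a JSON manifest records
the config hash, per-stage seeds and a SHA-256 checksum of every file the
run produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coupling as cpl
from . import drivers as drv
from . import srdb_ingest as ingest
from . import stability as stab
from . import upscaling as ups
from .composite_indices import extract_at_sites
from .synthetic_world import WorldConfig, generate_world, sample_sites

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

STAGE_NAMES = ("world", "sites", "split", "rf", "drivers")


@dataclass
class RunConfig:
    """Everything one run needs; round-trips through YAML unchanged."""

    seed: int = 0
    world: WorldConfig = field(default_factory=lambda: WorldConfig(seed=0))
    # site sampling
    n_sites: int = 300
    max_years_per_site: int = 8
    missing_frac: float = 0.02
    outlier_frac: float = 0.01
    obs_noise_sd: float = 50.0  # g C m-2 yr-1, per-record measurement error
    site_effect_sd: float = 0.0
    # filtering
    year_min: int = 1985
    year_max: int = 2018
    sd_k: float = 3.0
    # regression / validation
    train_frac: float = 0.8
    selection_criterion: str = "bic"
    selection_direction: str = "both"
    # stability & coupling
    window: int = 10
    alpha: float = 0.05
    dof_correction: str = "overlap"
    p_low: float = 10.0
    p_high: float = 90.0
    # vegetation-free random forest (0 trees disables the stage)
    rf_trees: int = 300
    rf_cv_folds: int = 10
    # driver attribution
    cell_deg: float = 1.0
    drivers_n_perm: int = 199
    drivers_rf_trees: int = 200

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(len(STAGE_NAMES) + 1)
        return {n: int(state[i + 1] % 2**31) for i, n in enumerate(STAGE_NAMES)}

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["world"]["beta_true"] = self.world.beta_true.to_dict(orient="list")
        d["world"]["aridity_gradient"] = list(self.world.aridity_gradient)
        d["world"]["temp_stability_gradient"] = list(self.world.temp_stability_gradient)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        w = d.pop("world", {})
        if w.get("beta_true") is not None:
            from .upscaling import EQ1_TERMS

            beta = pd.DataFrame(w["beta_true"])
            w["beta_true"] = beta[[c for c in ["b0"] + EQ1_TERMS if c in beta.columns]]
        for k in ("aridity_gradient", "temp_stability_gradient"):
            if k in w:
                w[k] = tuple(w[k])
        cfg = cls(world=WorldConfig(**w), **d)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


class _StageRunner:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.timings: dict[str, float] = {}

    def run(self, name, fn):
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        try:
            out = fn()
        except Exception as e:
            raise RuntimeError(
                f"stage {name!r} failed ({e}); partial outputs kept in {self.outdir}"
            ) from e
        self.timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: done in %.2fs", name, self.timings[name])
        return out


def run_all(config: RunConfig, outdir) -> dict:
    """Execute every stage in dependency order; returns the manifest dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    runner = _StageRunner(out)

    # --- synthetic world (seed derived from the master seed) ---
    wcfg = dataclasses.replace(config.world, seed=seeds["world"])
    world = runner.run("world", lambda: generate_world(wcfg))
    world.to_netcdf(out / "world.nc")
    world.indices.loadings_table().to_csv(out / "index_loadings.csv", index=False)

    # --- site records + SRDB-style ingest/filter ---
    def _sites():
        tab = sample_sites(
            world,
            n_sites=config.n_sites,
            max_years_per_site=config.max_years_per_site,
            missing_frac=config.missing_frac,
            outlier_frac=config.outlier_frac,
            obs_noise_sd=config.obs_noise_sd,
            site_effect_sd=config.site_effect_sd,
            seed=seeds["sites"],
        )
        tab.to_csv(out / "sites_raw.csv", index=False)
        return tab

    runner.run("sites", _sites)
    raw = ingest.read_srdb(out / "sites_raw.csv")
    filtered, report = ingest.filter_records(
        raw, year_min=config.year_min, year_max=config.year_max, sd_k=config.sd_k
    )
    filtered.to_csv(out / "sites_filtered.csv", index=False)
    report.to_json(out / "filter_report.json")

    # --- design table, site-blocked validation, full-data fit, prediction ---
    design = extract_at_sites(world.indices, filtered)
    design.to_csv(out / "design.csv", index=False)
    folds = ingest.site_blocked_split(
        design,
        train_frac=config.train_frac,
        seed=seeds["split"],
        columns={"site": "Site_ID", "ecosystem": "ecosystem"},
    )
    sel = ups.Selection(config.selection_criterion, config.selection_direction)

    def _fit_validate():
        fits_train = ups.fit_eq1(design[folds == "train"], sel)
        pooled = ups.fit_eq1(design.assign(ecosystem="__global__"), sel)
        for f in (fits_train,):
            f.coefficients.loc["__global__"] = pooled.coefficients.loc["__global__"]
        metrics = ups.validate(fits_train, design, folds, fallback="__global__")
        fits_full = ups.fit_eq1(design, sel)
        fits_full.coefficients.loc["__global__"] = pooled.coefficients.loc["__global__"]
        return fits_train, fits_full, metrics

    fits_train, fits_full, metrics = runner.run("fit", _fit_validate)
    fits_full.to_json(out / "fits.json")
    _write_json(metrics.as_dict(), out / "validation_metrics.json")
    rs_pred = ups.predict_grid(
        fits_full,
        world.indices,
        world.data["ecosystem"],
        eco_names=world.eco_name,
        fallback="__global__",
    )
    rs_pred.to_dataset(name="Rs_pred").to_netcdf(out / "rs_pred.nc", engine="scipy")

    # --- stability, aridity, coupling ---
    npp, mapp, pet, mat = (world.data[k] for k in ("NPP", "MAP", "PET", "MAT"))
    ai_stack = (mapp / pet).rename("AI")
    rs_stab = stab.stability_map(rs_pred, source="Rs")
    npp_stab = stab.stability_map(npp, source="NPP")
    ws_rs = stab.moving_window_stability(rs_pred, config.window, source="Rs")
    ws_npp = stab.moving_window_stability(npp, config.window, source="NPP")
    coup = cpl.windowed_coupling(
        ws_npp, ws_rs, alpha=config.alpha, dof_correction=config.dof_correction
    )
    # the generator's true respiration is also available in a synthetic run;
    # coupling against it separates real coupling from structure introduced
    # by the regression reconstruction itself
    ws_true = stab.moving_window_stability(world.rs_true, config.window, source="Rs_true")
    coup_true = cpl.windowed_coupling(
        ws_npp, ws_true, alpha=config.alpha, dof_correction=config.dof_correction
    )
    arid = stab.aridity(mapp, pet)
    biv = cpl.bivariate_class_map(npp_stab, rs_stab, config.p_low, config.p_high)
    dom_codes, dom_names = cpl.dominant_predictor_map(
        rs_pred, {"NPP": npp, "LAI": world.data["LAI"], "MAT": mat, "MAP": mapp, "AI": ai_stack}
    )
    strat_arid = cpl.stratified_mean_r(coup, arid)
    strat_eco = cpl.stratified_mean_r(
        coup,
        np.asarray(world.data["ecosystem"].values),
        labels=[world.eco_name(i) for i in range(int(world.data["ecosystem"].max()) + 1)],
    )
    strat_arid.to_csv(out / "coupling_by_aridity.csv", index=False)
    strat_eco.to_csv(out / "coupling_by_ecosystem.csv", index=False)
    coupling_summary = {
        "mean_r": float(np.nanmean(coup.r)),
        "frac_significant": float(coup.significant[coup.mask].mean()),
        "mean_r_true": float(np.nanmean(coup_true.r)),
        "frac_significant_true": float(coup_true.significant[coup_true.mask].mean()),
        "r_crit": float(np.nanmedian(coup.r_crit)),
        "n_eff": coup.n_eff,
        "n_windows": coup.n_windows,
        "bivariate_counts": {k: int(v) for k, v in biv.counts().items()},
        "dominant_predictor_counts": {
            dom_names[i]: int((dom_codes == i).sum()) for i in range(len(dom_names))
        },
    }
    _write_json(coupling_summary, out / "coupling_summary.json")

    # --- vegetation-free random forest cross-check ---
    if config.rf_trees > 0:

        def _rf():
            model, rf_metrics = ups.fit_rf_novegetation(
                design,
                n_trees=config.rf_trees,
                cv_folds=config.rf_cv_folds,
                seed=seeds["rf"],
            )
            rs_rf = ups.rf_predict_grid(model, world.indices)
            ws_rf = stab.moving_window_stability(rs_rf, config.window, source="Rs_rf")
            coup_rf = cpl.windowed_coupling(
                ws_npp, ws_rf, alpha=config.alpha, dof_correction=config.dof_correction
            )
            return rf_metrics, coup_rf

        rf_metrics, coup_rf = runner.run("rf", _rf)
        _write_json(
            {
                **rf_metrics.as_dict(),
                "coupling_mean_r": float(np.nanmean(coup_rf.r)),
                "coupling_frac_significant": float(
                    coup_rf.significant[coup_rf.mask].mean()
                ),
            },
            out / "rf_novegetation.json",
        )

    # --- driver attribution at coarse scale ---
    def _drivers():
        maps = {
            "rs_stab": rs_stab,
            "npp_stab": npp_stab,
            "lai_stab": stab.stability_map(world.data["LAI"], source="LAI"),
            "temp_stab": stab.stability_map(mat, source="MAT"),
            "precip_stab": stab.stability_map(mapp, source="MAP"),
            "ai_stab": stab.stability_map(ai_stack, source="AI"),
        }
        table = drv.aggregate_to_degree(
            maps, world.data["ecosystem"], cell_deg=config.cell_deg
        )
        pc1, ve = drv.productivity_pc1(table["npp_stab"], table["lai_stab"])
        table["prod_pc1"] = pc1
        table.to_csv(out / "driver_sample.csv", index=False)
        res = {"prod_pc1_variance_explained": ve, "n_cells": len(table)}
        if len(table) >= 50:
            imp = drv.rf_importance(
                table,
                n_perm=config.drivers_n_perm,
                n_trees=config.drivers_rf_trees,
                seed=seeds["drivers"],
            )
            imp.to_csv(out / "rf_importance.csv", index=False)
            res["rf_importance"] = imp.to_dict(orient="records")
        pcor = drv.partial_correlations(table)
        pcor.to_csv(out / "partial_correlations.csv", index=False)
        if len(table) >= 30:
            res["variance_partition"] = drv.variance_partition(table)
        if len(table) >= 100:
            sem = drv.fit_sem(table)
            res["sem"] = {
                "paths": sem.edge_list(),
                "chi2": sem.chi2, "df": sem.df, "p": sem.p_value,
                "rmsea": sem.rmsea, "cfi": sem.cfi,
                "saturated": sem.saturated, "passed": sem.passed,
            }
        return res

    driver_results = runner.run("drivers", _drivers)
    _write_json(driver_results, out / "driver_results.json")

    # --- provenance manifest ---
    config.to_yaml(out / "config.yaml")
    outputs = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "timings_s": runner.timings,
        "outputs": outputs,
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
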