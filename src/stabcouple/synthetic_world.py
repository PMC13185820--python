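"""Synthetic gridded world with known generative parameters.

A small abstract grid (rows x cols, pseudo-geo-referenced at 0.25deg per
cell) carries 34 annual steps of climate and vegetation, static soil and
topography fields, an ecosystem map, and a soil-respiration stack generated
from the composite-index regression with known per-ecosystem coefficients.
Columns span an aridity gradient (mean MAP/PET) and rows span an interannual
temperature-variability gradient, so stability and coupling patterns have a
known spatial structure to test against.

Vegetation is climate-driven: annual NPP follows a saturating response to
the annual aridity index times a Gaussian temperature response, plus
multiplicative noise.  Water limitation therefore amplifies precipitation
fluctuations in dry cells, giving the arid end of the grid larger relative
NPP variability -- and, in coupled mode, a stronger above-belowground
stability coupling -- than the humid end.

In ``coupled`` mode the true respiration of a cell-year is the regression
evaluated on that cell's own composite indices; in ``decoupled`` mode the
two time-varying indices (Cli, Plant) are replaced by independent surrogate
series with the same per-cell mean and interannual SD before respiration is
generated, severing any statistical link between respiration stability and
vegetation stability while leaving the vegetation stacks untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .composite_indices import CompositeIndexSet, build_indices
from .upscaling import EQ1_TERMS, INDEX_NAMES, eq1_evaluate

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "ECOSYSTEM_NAMES",
    "default_beta",
    "generate_world",
    "sample_sites",
]

ECOSYSTEM_NAMES = (
    "bareland",
    "cropland",
    "grassland",
    "shrubland",
    "needleleaf forest",
    "broadleaf forest",
    "mixed forest",
    "wetland",
)

#: pseudo-geographic anchor of cell (0, 0) and cell size in degrees
LAT0, LON0, CELL_SIZE = 60.0, -180.0, 0.25


def default_beta(n_ecosystems: int = 8) -> pd.DataFrame:
    """Per-ecosystem regression coefficients used by default.

    The true term set is sparse: a linear climate effect, a dominant linear
    vegetation effect with a quadratic, and linear soil/topography effects;
    the remaining quadratic candidates are exactly 0, so support recovery by
    stepwise selection is well-posed.  Units are g C m-2 yr-1 per (unit) index.
    Magnitudes vary smoothly across ecosystem classes; the vegetation term
    dominates so that, in coupled mode, respiration fluctuations track
    vegetation fluctuations, as in a substrate-limited belowground system.
    """
    base = np.array(
        # b0    Cli  Cli2 Plant Plant2  Gra  Gra2  Mic Mic2  Phy  Phy2 Chem Chem2
        [900.0, 100, 0.0, 350, 40.0, -50, 0.0, 70, 0.0, -60, 0.0, 90, 0.0]
    )
    rows = []
    for e in range(n_ecosystems):
        scale = 0.9 + 0.25 * e / max(n_ecosystems - 1, 1)
        b = base.copy()
        b[1:] *= scale
        b[0] = 900.0 + 60.0 * e
        rows.append(b)
    return pd.DataFrame(
        rows, columns=["b0"] + EQ1_TERMS, index=list(range(n_ecosystems))
    )


@dataclass
class WorldConfig:
    """Generative parameters of a synthetic world."""

    grid_rows: int = 30
    grid_cols: int = 30
    n_years: int = 34
    year0: int = 1985
    n_ecosystems: int = 8
    aridity_gradient: tuple[float, float] = (0.12, 1.5)
    temp_stability_gradient: tuple[float, float] = (0.25, 0.9)
    beta_true: pd.DataFrame | None = None
    noise_sd: float = 10.0
    coupling_mode: str = "coupled"
    seed: int = 0
    # secondary knobs (interannual coefficients of variation etc.)
    map_cv: float = 0.3
    npp_noise_cv: float = 0.06
    # SD (across cells) of the log-slope of interannual variability over the
    # period: climate/vegetation anomalies grow or shrink per cell, so
    # stability genuinely drifts across moving windows (a strongly
    # nonstationary, changing-climate regime; 0 gives a stationary world)
    volatility_trend_sd: float = 1.8
    pca_sample_size: int = 2000
    window: int = 10  # downstream moving-window length the world must admit

    def __post_init__(self):
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_years < 12:
            raise ValueError("n_years must be >= 12 (needs >= 3 ten-year windows)")
        if self.n_years < self.window:
            raise ValueError("n_years too short for the configured window length")
        if self.coupling_mode not in ("coupled", "decoupled"):
            raise ValueError("coupling_mode must be 'coupled' or 'decoupled'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.temp_stability_gradient) <= 0:
            raise ValueError("temperature-variability gradient must be positive")
        if min(self.aridity_gradient) <= 0:
            raise ValueError("aridity gradient must be positive")
        if self.n_ecosystems < 2:
            raise ValueError("need at least 2 ecosystem classes")
        if self.beta_true is None:
            self.beta_true = default_beta(self.n_ecosystems)

    def to_yaml(self, path):
        d = asdict(self)
        d["beta_true"] = self.beta_true.to_dict(orient="list")
        d["aridity_gradient"] = list(self.aridity_gradient)
        d["temp_stability_gradient"] = list(self.temp_stability_gradient)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "seed" not in d:
            raise ValueError("world config must state an explicit seed")
        if d.get("beta_true") is not None:
            beta = pd.DataFrame(d["beta_true"])
            order = [c for c in ["b0"] + EQ1_TERMS if c in beta.columns]
            d["beta_true"] = beta[order]
        for k in ("aridity_gradient", "temp_stability_gradient"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SyntheticWorld:
    """Generated stacks, indices and ground truth for one configuration."""

    data: xr.Dataset
    indices: CompositeIndexSet
    beta_true: pd.DataFrame
    config: WorldConfig
    ecosystem_names: tuple[str, ...] = field(default=ECOSYSTEM_NAMES)

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.data["year"].values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.sizes["row"], self.data.sizes["col"]

    @property
    def rs_true(self) -> xr.DataArray:
        return self.data["Rs_true"]

    def eco_name(self, code: int) -> str:
        return self.ecosystem_names[code % len(self.ecosystem_names)]

    def to_netcdf(self, path):
        self.data.to_netcdf(path, engine="scipy")


def _smooth_field(rng, shape, coarse: int = 4) -> np.ndarray:
    """Standard-normal-ish field with spatial structure at ~``coarse`` cells."""
    r, c = shape
    cr, cc = r // coarse + 2, c // coarse + 2
    base = rng.normal(size=(cr, cc))
    up = np.kron(base, np.ones((coarse, coarse)))[:r, :c]
    return 0.8 * up + 0.2 * rng.normal(size=(r, c))


def _voronoi_ecosystems(rng, shape, n_eco: int) -> np.ndarray:
    """Contiguous ecosystem patches: nearest of n_eco seeded anchor cells."""
    r, c = shape
    anchors = np.column_stack(
        [rng.uniform(0, r, size=n_eco), rng.uniform(0, c, size=n_eco)]
    )
    rr, cc = np.meshgrid(np.arange(r), np.arange(c), indexing="ij")
    d = (rr[..., None] - anchors[:, 0]) ** 2 + (cc[..., None] - anchors[:, 1]) ** 2
    eco = np.argmin(d, axis=-1)
    # anchors may collide on tiny grids; re-label to keep classes contiguous 0..k-1
    present = np.unique(eco)
    relabel = {p: i for i, p in enumerate(present)}
    return np.vectorize(relabel.get)(eco)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a world; identical config (including seed) gives identical output."""
    cfg = config
    R, C, Y = cfg.grid_rows, cfg.grid_cols, cfg.n_years
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    years = np.arange(cfg.year0, cfg.year0 + Y)

    ai_lo, ai_hi = cfg.aridity_gradient
    ai_target = np.tile(np.linspace(ai_lo, ai_hi, C), (R, 1))
    sd_lo, sd_hi = cfg.temp_stability_gradient
    temp_sd = np.tile(np.linspace(sd_hi, sd_lo, R)[:, None], (1, C))

    # per-cell drift of interannual variability: anomalies are scaled by a
    # log-linear path over the period, shared by climate and vegetation noise
    g = np.clip(rng.normal(0, cfg.volatility_trend_sd, (R, C)), -2.2, 2.2)
    vol = np.exp(g[None, :, :] * (np.arange(Y)[:, None, None] - (Y - 1) / 2) / Y)

    # --- climate ---
    mat_mean = 4.0 + 18.0 * (np.arange(R) / max(R - 1, 1))[:, None] + rng.normal(
        0, 1.0, (R, C)
    )
    mat = mat_mean + rng.normal(size=(Y, R, C)) * temp_sd * vol
    tmax = mat + 10.0 + np.abs(rng.normal(0, 0.2, (Y, R, C)))
    tmin = mat - 10.0 - np.abs(rng.normal(0, 0.2, (Y, R, C)))
    pet_mean = np.clip(800.0 + 40.0 * mat_mean + rng.normal(0, 50, (R, C)), 300, None)
    pet = pet_mean * np.clip(1 + rng.normal(0, 0.03, (Y, R, C)) * vol, 0.5, None)
    # single-year relative anomalies are clamped: droughts can remove at most
    # ~85% of a year's precipitation and pluvials at most double it
    mapp = ai_target * pet_mean * (
        1 + np.clip(rng.normal(0, cfg.map_cv, (Y, R, C)) * vol, -0.85, 1.0)
    )
    radiation = 140.0 + 4.0 * mat_mean + rng.normal(0, 3, (Y, R, C))
    ai_annual = mapp / pet
    # smooth Budyko-type partitioning with the same half-saturation as the
    # vegetation water response, so water-use efficiency (NPP/AET) stays
    # bounded across the whole aridity range
    aet = pet * ai_annual / (ai_annual + 0.35)

    # --- vegetation: water-limited saturating response x temperature optimum ---
    veg = (ai_annual / (ai_annual + 0.35)) * np.exp(-((mat - 18.0) ** 2) / (2 * 14.0**2))
    npp = np.clip(
        1300.0 * veg * (1 + rng.normal(0, cfg.npp_noise_cv, (Y, R, C)) * vol), 0, None
    )
    lai = np.clip(8.0 * (1 - np.exp(-npp / 1500.0)) * (1 + rng.normal(0, 0.01, (Y, R, C))), 0, None)
    fvc = np.clip(1 - np.exp(-0.45 * lai), 0, 1)
    cue = np.clip(0.45 + rng.normal(0, 0.008, (Y, R, C)), 0.3, 0.6)
    gpp = npp / cue

    # --- ecosystems & static soils ---
    eco = _voronoi_ecosystems(rng, (R, C), cfg.n_ecosystems)
    n_eco = int(eco.max()) + 1
    soc_base = np.array([20, 60, 80, 60, 120, 110, 115, 180], dtype=float)
    cn_base = np.array([9, 10, 11, 12, 20, 16, 18, 15], dtype=float)
    tex_alpha = np.array(  # sand, silt, clay Dirichlet concentration per class
        [[8, 2, 1], [4, 4, 2], [4, 4, 3], [6, 3, 2], [5, 4, 2], [4, 4, 3], [4, 4, 3], [3, 4, 4]],
        dtype=float,
    )
    idx8 = np.arange(n_eco) % 8
    # wide within-class spread: soil carbon varies by multiples inside a
    # biome, which also keeps an index and its square distinguishable within
    # one ecosystem class
    soc = soc_base[idx8][eco] * np.exp(rng.normal(0, 0.5, (R, C)))
    cn = np.clip(cn_base[idx8][eco] + rng.normal(0, 1.0, (R, C)), 5, None)
    tn = soc / cn
    tex = np.stack(
        [rng.dirichlet(tex_alpha[idx8[e]]) for e in eco.ravel()]
    ).reshape(R, C, 3) * 100.0
    sand, silt, clay = tex[..., 0], tex[..., 1], tex[..., 2]
    bulk = np.clip(1.45 - 0.0015 * soc + rng.normal(0, 0.08, (R, C)), 0.7, 1.8)
    vwc = np.clip(0.05 + 0.004 * clay + rng.normal(0, 0.03, (R, C)), 0.01, 0.6)
    ph = np.clip(6.8 + rng.normal(0, 0.7, (R, C)), 3.5, 9.0)
    cec = np.clip(4.0 + 0.35 * clay + rng.normal(0, 2.0, (R, C)), 1, None)
    # microbial pools: only a weak link to SOC, so the microbial index stays
    # identifiable next to the chemical index within an ecosystem class
    mbc = 30.0 * soc**0.4 * np.exp(rng.normal(0, 0.45, (R, C)))
    mbn = mbc / 8.0 * np.exp(rng.normal(0, 0.15, (R, C)))
    mbp = mbc / 30.0 * np.exp(rng.normal(0, 0.15, (R, C)))

    # --- topography ---
    elevation = np.clip(900.0 + 700.0 * _smooth_field(rng, (R, C)), 0, None)
    gy, gx = np.gradient(elevation)
    slope = np.clip(np.hypot(gy, gx) / 40.0 + np.abs(rng.normal(0, 2, (R, C))), 0, 45)
    aspect = rng.uniform(0, 360, (R, C))

    coords = {"year": years, "row": np.arange(R), "col": np.arange(C)}
    tdims, sdims = ("year", "row", "col"), ("row", "col")
    ds = xr.Dataset(
        {
            "MAT": (tdims, mat), "Tmax": (tdims, tmax), "Tmin": (tdims, tmin),
            "MAP": (tdims, mapp), "radiation": (tdims, radiation),
            "AET": (tdims, aet), "PET": (tdims, pet),
            "NPP": (tdims, npp), "LAI": (tdims, lai), "FVC": (tdims, fvc),
            "GPP": (tdims, gpp), "CUE": (tdims, cue), "WUE": (tdims, npp / aet),
            "SOC": (sdims, soc), "TN": (sdims, tn), "CN_ratio": (sdims, cn),
            "sand": (sdims, sand), "silt": (sdims, silt), "clay": (sdims, clay),
            "bulk_density": (sdims, bulk), "VWC": (sdims, vwc), "pH": (sdims, ph),
            "CEC": (sdims, cec),
            "MBC": (sdims, mbc), "MBN": (sdims, mbn), "MBP": (sdims, mbp),
            "elevation": (sdims, elevation), "slope": (sdims, slope),
            "aspect": (sdims, aspect),
            "ecosystem": (sdims, eco.astype(np.int32)),
        },
        coords=coords,
        attrs={"lat0": LAT0, "lon0": LON0, "cell_size": CELL_SIZE, "year0": cfg.year0},
    )

    # --- composite indices, then ground-truth respiration ---
    idx_seed = int(np.random.SeedSequence(cfg.seed).generate_state(2)[1] % 2**31)
    indices = build_indices(ds, sample_size=cfg.pca_sample_size, seed=idx_seed)

    index_arrays = {}
    for name in INDEX_NAMES:
        ci = indices[name]
        arr = np.asarray(ci.values.values, dtype=float)
        if not ci.time_varying:
            arr = np.broadcast_to(arr, (Y, R, C)).copy()
        index_arrays[name] = arr

    if cfg.coupling_mode == "decoupled":
        for name in ("Cli", "Plant"):
            a = index_arrays[name]
            mu, sd = a.mean(axis=0), a.std(axis=0, ddof=1)
            index_arrays[name] = mu + rng.normal(size=(Y, R, C)) * sd

    beta = cfg.beta_true
    rs = np.zeros((Y, R, C))
    for e in range(n_eco):
        m = eco == e
        b = beta.loc[e % len(beta)].to_numpy()
        vals = eq1_evaluate(b, {k: v[:, m] for k, v in index_arrays.items()})
        rs[:, m] = vals
    # observation/model error scales with the cell's variability regime
    rs = np.clip(rs + rng.normal(0, cfg.noise_sd, (Y, R, C)) * vol, 0, None)
    ds["Rs_true"] = (tdims, rs)

    return SyntheticWorld(ds, indices, beta.copy(), cfg)


def sample_sites(
    world: SyntheticWorld,
    n_sites: int = 300,
    max_years_per_site: int = 8,
    missing_frac: float = 0.0,
    outlier_frac: float = 0.0,
    obs_noise_sd: float = 0.0,
    site_effect_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """SRDB-like site-year records drawn from a world's true respiration.

    Each site is one grid cell (unique Site_ID), sampled without replacement;
    site-years are drawn without replacement within the world's year span.
    ``missing_frac`` of records get a blanked coordinate or year (to exercise
    metadata filters); ``outlier_frac`` are pushed beyond +-3 SD of the
    pooled respiration mean.  ``site_effect_sd`` adds a per-site random
    offset shared by all of a site's years (spatial leakage structure);
    ``obs_noise_sd`` adds independent per-record noise.
    """
    for name, f in (("missing_frac", missing_frac), ("outlier_frac", outlier_frac)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    R, C = world.shape
    if n_sites > R * C:
        raise ValueError("n_sites exceeds number of land cells")
    rng = np.random.default_rng(seed)
    cells = rng.choice(R * C, size=n_sites, replace=False)
    rows_, cols_ = np.divmod(cells, C)
    years = world.years
    rs = np.asarray(world.rs_true.values)
    eco = np.asarray(world.data["ecosystem"].values)
    site_fx = rng.normal(0, site_effect_sd, n_sites) if site_effect_sd > 0 else np.zeros(n_sites)

    recs = []
    for i in range(n_sites):
        r, c = int(rows_[i]), int(cols_[i])
        k = int(rng.integers(1, max_years_per_site + 1))
        yrs = rng.choice(years, size=min(k, len(years)), replace=False)
        for y in np.sort(yrs):
            yi = int(y - years[0])
            val = rs[yi, r, c] + site_fx[i] + rng.normal(0, obs_noise_sd)
            recs.append(
                {
                    "Site_ID": f"S{i:05d}",
                    "Latitude": LAT0 - r * CELL_SIZE,
                    "Longitude": LON0 + c * CELL_SIZE,
                    "Study_midyear": float(y),
                    "Rs_annual": float(val),
                    "Ecosystem_type": world.eco_name(int(eco[r, c])),
                }
            )
    tab = pd.DataFrame(recs)
    n = len(tab)

    if outlier_frac > 0 and n:
        k = int(round(outlier_frac * n))
        pick = rng.choice(n, size=k, replace=False)
        mu, sd = tab["Rs_annual"].mean(), tab["Rs_annual"].std(ddof=1)
        signs = rng.choice([-1.0, 1.0], size=k)
        tab.loc[pick, "Rs_annual"] = mu + signs * (4.0 + np.abs(rng.normal(0, 0.5, k))) * sd
    if missing_frac > 0 and n:
        k = int(round(missing_frac * n))
        pick = rng.choice(n, size=k, replace=False)
        which = rng.random(k) < 0.5
        tab.loc[pick[which], "Latitude"] = np.nan
        tab.loc[pick[~which], "Study_midyear"] = np.nan
    return tab
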