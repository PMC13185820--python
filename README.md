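# stabcouple

Tools for studying the coupling between aboveground and belowground
ecosystem stability: upscaling annual soil respiration (Rs) from sparse
site records to a grid, measuring the temporal stability of above- and
belowground fluxes, mapping how tightly the two are coupled across moving
decadal windows, biomes and aridity classes, and attributing that coupling
to productivity versus climate stability.

The package is aimed at ecosystem ecologists and carbon-cycle modellers.
Everything runs end-to-end on a synthetic gridded world with known
generative parameters, so each stage of the analysis can be checked against
ground truth before it is pointed at real data products.

## The model

Site-level annual soil respiration is predicted from six composite
environmental indices — climate (Cli), vegetation (Plant), topography
(Gra), soil microbial (Mic), soil physical (Phy) and soil chemical (Chem),
each the first principal component of its z-scored variable category, with
time-varying categories including trailing 3-year moving averages — through
a nonlinear stepwise regression fitted per ecosystem type:

    Rs = β₀ + β₁·Cli + β₂·Cli² + β₃·Plant + β₄·Plant² + β₅·Gra + β₆·Gra²
            + β₇·Mic + β₈·Mic² + β₉·Phy + β₁₀·Phy² + β₁₁·Chem + β₁₂·Chem² + ε

Temporal stability of any annual series is μ/σ (mean over sample standard
deviation).  Coupling at a grid cell is the Pearson correlation between the
μ/σ series of two variables computed over 10-year moving windows (34 annual
steps → 25 windows).  Because consecutive windows share 9 of 10 years, the
window series are strongly autocorrelated and the naive t test for a
correlation rejects ~40% of truly independent cells; significance therefore
uses an effective sample size n_eff = n / (1 + 2·Σₖ (1−k/n)·ρ_A(k)·ρ_B(k))
per cell (see `docs/methods.md`).

Driver attribution aggregates stability maps to a coarse sampling grid and
applies random-forest importance with permutation p-values, partial
correlations with false-discovery-rate control, variance partitioning, and
a recursive path model (climate stability → productivity stability → Rs
stability) with χ²/df, RMSEA and CFI fit statistics.

## Worked example

Run the coupled-world demonstration (30×30 grid, 34 years, ~1300 site-year
records, full pipeline):

```bash
stabcouple run --config configs/demo_coupled.yaml --out runs/coupled
stabcouple run --config configs/demo_decoupled.yaml --out runs/decoupled
```

From `runs/coupled` (seed 7):

* `filter_report.json` — `{"raw": 1317, "metadata_complete": 1291,
  "post_outlier": 1277}`, 299 sites retained: the injected 2% missing
  metadata and 1% extreme values are removed by the four-step filter.
* `validation_metrics.json` — site-blocked hold-out `R = 0.99,
  MAE = 43.6, RMSE = 54.0` (flux units g C m⁻² yr⁻¹): the regression
  transfers to unseen sites because record noise, not site identity,
  limits the fit.
* `coupling_summary.json` — `mean_r = 0.948` with 98% of cells significant:
  above- and belowground stability move together nearly everywhere in a
  world whose respiration is substrate-driven.

The decoupled twin (`runs/decoupled`) shows `mean_r_true = −0.005` with
5.4% of cells significant at α = 0.05 — the calibrated null.  Its
reconstruction-based `mean_r = 0.75` illustrates a real methodological
caveat: a regression product inherits temporal structure from its
predictors, so coupling measured on a reconstruction must be interpreted
against exactly this kind of null experiment (`docs/methods.md`).

Every stage is also exposed as a library function
(`stabcouple.generate_world`, `fit_eq1`, `stability_map`,
`windowed_coupling`, `fit_sem`, ...) and as CLI subcommands
(`stabcouple ingest | indices | upscale | stability | couple | drivers | run`).

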