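# Methods

This note documents the models, the synthetic world the package is tested
on, the statistical choices that were genuinely open, and what the tests do
and do not demonstrate about real data.

## Composite indices

Twenty-eight environmental variables are grouped into six categories:
climate (MAT, annual maximum/minimum temperature, MAP, solar radiation,
AET, PET), vegetation (NPP, LAI, FVC, CUE = NPP/GPP, WUE = NPP/AET), soil
chemistry (SOC, TN, C:N), soil physics (sand, silt, clay, bulk density,
volumetric water content, pH, CEC), soil microbes (microbial biomass C, N,
P) and topography (elevation, slope, aspect).  Time-varying categories
(climate, vegetation) contribute each variable and its trailing three-year
moving average — past years only, since the motivation is cumulative
carry-over effects on respiration; the first two years use the shorter
window that exists.

Each category is reduced to the first principal component of its z-scored
features, fitted once globally on a seeded random sample of cell-years
(default 2,000) so the index is comparable across space.  Three conventions
pin the result down:

* **Correlation-matrix PCA** (z-scoring), since the features have wildly
  different units.
* **Sign**: the loading of a reference variable (MAT, NPP, elevation, MBC,
  clay, SOC respectively) is oriented positive; a PC's sign is otherwise
  arbitrary and the regression coefficients would not be reproducible.
* **Unit-variance scores**: the raw projection onto unit-norm loadings has
  sample SD equal to √λ₁ (≈2.4–3.3 for 10–14 strongly correlated
  features); index values are divided by that SD so one index unit is one
  sample SD.  Coefficients of the respiration regression are therefore in
  flux units per SD of the index, and quadratic terms act on a known scale.

## Respiration regression

The regression (intercept plus the six indices and their squares, 13
candidate terms) is fitted separately per ecosystem class by bidirectional
stepwise selection from the intercept-only model, then ordinary least
squares on the selected support.  The selection criterion is configurable:

* **BIC** (default): with 12 candidates, an AIC-type penalty admits a
  spurious term with probability ≈0.16 each, so a selected support would
  rarely be stable across refits; BIC keeps the per-term false-inclusion
  rate near 1%.
* **AIC**, for users who prefer prediction-oriented selection.
* **Partial-F p-values** (`p_enter`/`p_remove`): the strictest option and
  the one used in the support-recovery experiments, where the question is
  exactly "is the true term set selected?" (p_enter = 0.001 there).

Excluded terms carry coefficient exactly 0.  Classes with fewer than 20
complete rows are skipped with a warning.  Grid predictions dispatch on the
ecosystem map, floor negative predictions at zero (logged), and accept a
fallback class (the pipeline fits a pooled all-ecosystem model for cells
whose class had no sites).

Validation is site-blocked: all records of a Site_ID share a fold, and the
per-ecosystem share of sites in the training fold is the closest achievable
to 80%.  The package also computes record-level random splits, which leak
whenever records of one site share noise; the leakage experiment below
quantifies the gap.

## Stability, aridity, and coupling

Stability is μ/σ with the sample (n−1) standard deviation — the choice is
configurable and recorded, since either convention appears in the
literature.  Cells with σ = 0 or fewer than two valid years are undefined
(NaN), never 0 or ∞, so that downstream correlations skip them explicitly
(listwise per cell).  Moving windows of 10 years over 34 annual steps give
25 maps labelled by inclusive start/end years.

The aridity index is annual MAP/PET averaged over the period; classes
follow the UNEP breakpoints (0.05, 0.20, 0.50, 0.65), and a value exactly
on an edge falls in the drier class.

**Coupling significance.** The Pearson correlation between two stability
series over overlapping windows does not have the textbook null
distribution: with 25 windows sharing 9 of 10 years, simulation shows
SD(r) ≈ 0.42 under independence and the plain t threshold (|r| ≥ 0.396)
rejects ~42% of truly independent cells.  The default test therefore uses
an effective sample size in the Pyper–Peterman style,

    n_eff = n / (1 + 2·Σ_{k=1}^{n-2} (1 − k/n)·ρ̂_A(k)·ρ̂_B(k)),

the Bartlett-weighted cross-product of the two series' sample
autocorrelations, clipped to [3, n], with a per-cell critical |r| from the
t distribution at n_eff − 2 degrees of freedom.  Calibration was verified
by simulation: false-positive rates of 3.8–4.9% at α = 5% under both
stationary and trending-variability nulls, against 42% uncorrected.  The
uncorrected threshold remains available (`dof_correction="none"`) and is
the right choice when the window values are serially independent.  A
consequence worth knowing: a cell whose two series share only a smooth
monotone trend carries ≈1 effective observation and can never be
significant — which is honest, since "both trended" is exactly what chance
produces easily.

The bivariate map classifies cells jointly against each stability map's own
10th/90th percentiles; a degenerate all-equal map classifies as
intermediate.  The dominant-predictor map uses the absolute Pearson
correlation of each predictor's annual series with annual respiration per
cell (a standardized-regression-coefficient alternative is behind
`method="std_coef"`); ties break by the fixed predictor order.

## Driver attribution

Stability maps are averaged over 4×4 fine-cell blocks (0.25° cells → 1°
sampling units); blocks with fewer than 25% valid fine cells are dropped
and the block's ecosystem is the modal class.  Aboveground productivity
stability is the PC1 of NPP and LAI stability (sign-oriented on NPP) — two
nearly collinear metrics are collapsed to avoid double counting.  Climate
stability means μ/σ of annual temperature, precipitation, and aridity
index.

* **Random-forest importance** uses impurity importance of a seeded forest
  with permutation p-values from refitting on shuffled responses (default
  999 shuffles; the null is the full fitting pipeline, not a Gaussian
  approximation).
* **Partial correlations** (response vs each predictor, controlling for the
  others, per ecosystem class) are computed by the residual-regression
  identity — correlate the OLS residuals of both variables on the controls —
  which remains exact when the response is a perfect linear function of the
  predictors, where inverse-correlation-matrix implementations lose the
  sign.  p-values use the t distribution with n − 2 − k degrees of freedom
  and are Benjamini–Hochberg adjusted jointly across the whole
  group × predictor table.
* **Variance partitioning** splits adjusted R² into unique and shared
  fractions of the productivity and climate predictor sets; the four raw
  fractions sum to 1 exactly and negative components (possible with
  adjusted R²) are reported floored with a flag.
* **The path model** is a recursive system of observed variables (climate
  stabilities → productivity PC1 → respiration stability, plus direct
  climate paths).  For recursive systems the maximum-likelihood path
  estimates coincide with per-equation OLS on standardized complete cases;
  the implied covariance is assembled from the path matrix and residual
  variances (exogenous block free), and χ² = (n−1)·F_ML with
  RMSEA = √(max(χ²−df, 0)/(df·(n−1))) and CFI against the independence
  baseline.  Fit passes when χ²/df ≤ 2, P > 0.05 and RMSEA ≤ 0.05.  The
  default topology is saturated (df = 0); it is flagged as trivially
  fitting, and fit statistics become meaningful for user topologies that
  drop paths.

## The synthetic world

The generator produces an abstract grid (0.25° pseudo-geo-referencing, 34
annual steps) whose columns span a mean-aridity gradient (AI 0.12–1.5) and
whose rows span an interannual temperature-SD gradient (0.25–0.9 °C).
Vegetation is climate-driven: NPP = 1300 · AI_t/(AI_t+0.35) ·
exp(−(T−18)²/(2·14²)) g C m⁻² yr⁻¹ times multiplicative noise (CV 6%), so
water limitation amplifies precipitation anomalies in dry cells; LAI, FVC,
GPP (via CUE ≈ 0.45) and WUE derive from NPP and water fluxes with small
idiosyncratic noise.  AET follows a smooth Budyko-type curve with the same
half-saturation as the vegetation response, which keeps WUE bounded across
the aridity range.  Static soils are drawn per ecosystem class (Voronoi
patches of seeded anchors) with wide within-class spread — SOC lognormal
(σ = 0.5), texture Dirichlet summing to 100%, microbial pools only weakly
tied to SOC so the microbial and chemical indices stay separately
identifiable within a class.

True respiration is the regression evaluated on the cell's own composite
indices with known per-ecosystem coefficients (vegetation term dominant:
Plant 350, Plant² 40, Cli 100, statics 50–90, intercept 900–1320 flux
units), plus Gaussian noise (default SD 10) and a floor at zero.

**Nonstationary variability.**  Interannual anomalies of precipitation,
temperature, PET and the noise terms are scaled by a per-cell log-linear
volatility path, exp(g·(t−t̄)/T) with g ~ N(0, 1.8) clipped to ±2.2.  This
represents a strongly changing-variability climate and is what makes
decadal stability genuinely drift across windows.  It is also a power
requirement: simulation shows that with stationary anomalies the
windowed-stability coupling of even a perfectly substrate-driven
respiration field tops out near a 70% significant-cell rate under the
calibrated test, because window-to-window variation is then mostly shared
sampling noise diluted by the moving-average index features.  Single-year
relative precipitation anomalies are clamped to [−85%, +100%].

**Coupling modes.**  In `coupled` mode respiration is driven by the actual
indices.  In `decoupled` mode the two time-varying indices entering the
respiration equation (Cli and Plant) are replaced by independent surrogate
series with the same per-cell mean and interannual SD.  Replacing only the
vegetation index would leave respiration correlated with NPP through their
shared climate driver; replacing both is what makes respiration stability
statistically independent of vegetation stability, which is the property
the null experiments need.

**Site sampling** draws cells without replacement, site-years without
replacement within the period, and supports per-record observation noise,
a per-site random offset (shared across a site's years — the leakage
structure site-blocked validation exists for), blanked metadata
(`missing_frac`) and injected outliers pushed ≥4 pooled SD from the mean
(`outlier_frac`).

**What the generator does not emulate**: real geography and spatial
autocorrelation beyond smooth gradients and Voronoi patches; sub-annual
structure; trends in mean climate (only variability trends); measurement
error correlated with covariates; land-cover change.  Passing tests
demonstrate that the estimators recover known structure under these ideal
conditions — not that real products satisfy the assumptions.

## Verification experiments and problem sizes

All experiments run on one CPU in about a minute total; sizes were chosen
as the smallest that make the statistical assertions stable.

* **Coefficient recovery**: 25 worlds, 30×30 grid, 2 ecosystem classes
  (~1,100 records each from 500 sites), observation noise 10% of the
  respiration SD applied at the record level, intercept lifted so the
  noiseless truth never touches the zero floor (truncated truth is
  misspecification, not noise, and verifiably corrupts support selection).
  Expected: exact support in ≥90% of seeds, median coefficient bias ≈2%.
* **Coupling discrimination**: three coupled and three decoupled 30×30
  worlds; coupled mean windowed r ≈ 0.94 with ≈95% of cells significant,
  decoupled significant-cell rate ≈5%.
* **Vegetation-free forest**: 500 trees (scaled down from 5,000; CV skill
  is insensitive to tree count well before that), 10-fold CV, and the
  coupling reconstructed from its predictions stays clearly positive
  (mean r ≈ 0.44) — the abiotic-only robustness check.
* **Leakage**: 20 replicate worlds with site-level noise (SD 150); blocked
  CV R ≈ 0.63 versus random-split R ≈ 0.96, blocked ≤ random in every
  replicate.

## Known limitations and caveats

* **Reconstruction-induced coupling.**  Coupling computed on a regression
  *product* inherits temporal structure from the product's own predictors:
  in the decoupled demo the truth-based coupling is ≈0 (5% significant)
  while the reconstruction-based figure is ≈0.75.  Any claim of
  above-belowground coupling measured on an upscaled product needs exactly
  this null comparison; the pipeline reports both numbers.
* The overlap-corrected significance test is slightly conservative for
  serially independent window series (≈3.5–4%) and pays its honesty in
  power at cells dominated by a single smooth trend.
* Stepwise selection with an index and its square remains fragile when one
  ecosystem class occupies a narrow one-sided band of an index (the two
  terms are then nearly affinely related); wide within-class spread avoids
  this in the generator, but real stratifications may not.
* The path model covers recursive (acyclic, observed-variable) topologies
  only; latent variables and feedback loops are out of scope.
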