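# Methods

This package reconstructs a long-term photosynthesis proxy from two-band
(red / near-infrared) satellite reflectance and validates every stage of the
chain on synthetic archives with known ground truth.  The scientific problem
it addresses: legacy wide-swath sensors provide the only multi-decadal daily
reflectance record, but that record is a patchwork of drifting platforms —
each with its own orbital decay (shifting solar zenith angle, SZA), its own
radiometric bias, and no on-board calibration — while the stable modern
benchmark sensor only covers the later decades.  The chain harmonizes the
drifting record against the benchmark, then emulates satellite
solar-induced chlorophyll fluorescence (SIF) from the harmonized
reflectance, producing a proxy that can be extended back across the whole
record.

## 1. The synthetic scene: what it emulates, and what it does not

All tests and headline numbers run on scenes from `lcspp.synthetic`.  A
scene consists of:

* **Surface truth** — per-pixel harmonic reflectance (mean, annual and
  semiannual cosine terms, linear interannual trend), red and NIR
  anti-phased so NDVI peaks in the growing season; vegetated means are
  red ≈ 0.05–0.12 and NIR ≈ 0.22–0.36 with NIR amplitudes 0.04–0.10.
  Pseudo-invariant calibration sites (PICS; bright desert targets,
  red ≈ 0.38–0.46, NIR ≈ 0.42–0.50) have zero amplitude and zero trend by
  construction.  Truth is clipped to [0.01, 0.95].
* **A drifting stream** observing the truth through a lineage of sensor
  epochs.  Injected artifacts, all retained for recovery tests: a
  piecewise-linear SZA drift ramping from 0 to up to +10° within each
  drifting epoch (reset at epoch changes); a per-degree reflectance
  response a1 (red 0.0012, NIR 0.0015 — so a full drift moves reflectance
  by ~0.012–0.015); per-epoch inter-sensor offsets |δ| ∈ [0.02, 0.04]
  (switch steps ≈ 5 % of the PICS mean); a small meteorology-driven
  response (aerosol and cloud-cover anomalies dominate, ± ~0.003, with
  minor temperature/precipitation/radiation terms); daily observation
  noise sd 0.005; independent cloud gaps with probability 0.35.
* **A reference stream** (the benchmark sensor): truth + noise only,
  available over the last 6 of the 16 years.
* **Covariates** — biweekly air temperature and radiation with
  hemisphere-aware seasonality, stochastic precipitation / aerosol optical
  depth / snow depth / cloud cover, static elevation and aridity.
* **SIF soundings** — a sparse swath sampler at a nominal 13:36 local
  overpass; each sounding is `SIF = s·cos(SZA)·NIRv` (s = 2.5, the
  APAR-dominated structure of satellite SIF; a purely affine law and an
  MLP law are available for stress tests) plus Gaussian noise
  (sd 0.1 mW m⁻² nm⁻¹ sr⁻¹ per sounding); a configurable fraction
  (default 25 %) fails the quality/mode/cloud screen.
* **Site GPP** — daily gross primary productivity at chosen pixels,
  `GPP = α(land cover) · SIF_true_daily + noise`, with a per-period data
  quality (QC) fraction drawn so ~20 % of biweekly periods fail the 0.7
  mean-QC screen.

The default sensor lineage switches after years 5 and 13, so the two
sensor *groups* used in cross-calibration (early drifting platforms vs the
stable late platform) each overlap the reference stream for three years —
mirroring real lineages in which both the legacy and the modern platform
family overlap the benchmark for several years.

The generator reproduces the *structure* of the real archives (drift,
steps, gaps, noise, sparse noisy soundings), not their radiative-transfer
physics: no BRDF effects remain in the synthetic streams (they are treated
as already normalized), no geolocation error, no spatially correlated
cloud fields, no atmospheric variability in the SIF law beyond cos(SZA).
Passing tests therefore demonstrate that the pipeline removes the artifact
classes it models, at the stated magnitudes — not that it would remove
every artifact of the real archives.

## 2. Compositing and preprocessing

Daily observations are composited to 24 half-month periods per year by
NDVI maximum-value compositing (MVC): per pixel and period the valid day
with the highest NDVI wins, and its red, NIR and SZA are carried as a
coherent triple (ties go to the earliest day; days with NIR + red = 0 are
invalid).  QC screening is a bitmask filter (cloud, snow, night, water,
polar, bad-BRDF, invalid), and instrument-malfunction windows are excluded
by date range with union semantics before compositing.

The kernel-driven BRDF model (isotropic + RossThick volumetric +
LiSparse-Reciprocal geometric, crown constants h/b = 2, b/r = 1) is
implemented for normalizing kernel-weight products to the standard
geometry (SZA 45°, nadir view, relative azimuth 0°) and verified against
straight-from-the-formula oracles; the synthetic streams themselves are
generated free of view-geometry effects.

One consequence of MVC worth knowing: with noisy observations the argmax
over days selects negatively-biased red and positively-biased NIR noise,
and the size of that selection bias depends on the band levels.  Constant
inter-sensor offsets therefore shift not only the composite level but also
(slightly) the selection bias, and can even change *which* day wins —
NDVI is not monotone under constant band offsets.  This is an artifact
interaction the calibration chain must absorb; it shaped the windowed
linear model's design (§4).

## 3. Harmonization (drift and inter-sensor bias removal)

The inter-sensor bias proxy is computed from the calibration PICS:
`δ_band(t) = PICS_mean(t) − MSC_ref(period-of-year)`, where the mean
seasonal cycle MSC_ref comes from the stable reference epoch of the same
(drifting) stream.  δ captures both the offsets and the drift response at
the bright targets.

Per pixel, per period-of-year and per band, reflectance anomalies
(relative to the pixel's own drifting-era climatology — the anomaly
baseline is a package choice) are regressed by OLS on
`[SZA anomaly, δ, Ta anomaly, P anomaly, Rad anomaly, 1]`, and only the
SZA and δ contributions are subtracted.  The meteorology terms are real
surface signal and are retained.  The correction applies to drifting
epochs only; the stable epoch passes through bit-identical.  Numerical
choices: at least 8 composites per fit (6 regressors need headroom;
unfitted cells pass through flagged); design columns are scaled to unit
RMS before the batched normal-equations solve (the raw units — degrees,
reflectance, W m⁻² — otherwise produce condition numbers that falsely
trigger the degeneracy fallback); genuinely rank-deficient designs are
refit without the δ column and counted.  On noiseless data generated
exactly by the linear model all six coefficients are recovered to 1e-8;
δ and the SZA anomaly are substantially collinear in realistic scenes
(δ *contains* the drift response at PICS), in which case the regression
splits the artifact between the two terms — harmless for removal, which
subtracts their sum.

## 4. Cross-calibration against the reference sensor

**Windowed linear stage.**  For each pixel, band and sensor group, an
affine map drifting → reference is fitted from the co-located pairs of
the 5×5 spatial neighborhood over the overlap era (clipped at grid
edges; groups fitted and applied separately).  Two numerical choices
depart from the naive all-raw-pairs OLS, both prompted by systematic
~0.4–0.6 % level steps at the sensor-group boundary that the naive fit
imprinted on held-out PICS:

1. *Year-aggregated pairs.*  Each pixel contributes its per-period-of-year
   mean over the overlap years rather than raw pairs.  Observation noise
   in the predictor attenuates an OLS slope by var(noise)/var(signal);
   because the harmonized early-group record carries stage-3 correction
   noise that the stable group does not, the attenuation differs between
   groups, and at a bright pixel far from the window mean the slope
   difference becomes a level step.  Averaging pairs before the fit
   divides the noise variance by the number of overlap years.
2. *Center-anchored intercept.*  The slope comes from the pooled window
   fit, but the intercept is re-anchored on the center pixel's own
   co-located means (`c = ȳ_c − m·x̄_c`, requiring ≥ 8 center pairs).
   The window exists to stabilize the gain; the level should be
   pixel-faithful.  This matters precisely at pixels unlike their
   neighborhood — bright calibration targets embedded in vegetation —
   where the vegetated majority's MVC selection response to the injected
   offsets (§2) otherwise poisons the extrapolation to the bright tail.

   Raw-pair and window-intercept modes remain available
   (`aggregate_years=False`, `center_anchor=False`), as does a
   per-period-of-year fitting mode (`per_period=True`; the pooled fit
   across periods is the pipeline default because per-period fits at
   aseasonal targets have noise-dominated predictor variance).

**Residual stage.**  The post-linear residual γ = reference − mapped
drifting is modeled by one small feedforward network per band
(one hidden layer of 32 units, adam, inputs *and targets* standardized —
the targets are a few 1e-3 in reflectance units, far below the unit scale
the optimizer expects) on the covariates (AOD, snow depth, cloud cover,
elevation, aridity) plus the linearly corrected red and NIR.  Geographic
coordinates are deliberately excluded.  The train/validation split is by
time-step blocks.  Both stages are then applied over the entire record,
including the pre-overlap era.  A per-sensor-group residual network was
tried and rejected: independently trained networks extrapolate
differently at the bright-feature tail and re-introduce group steps.

**Gap filling.**  Missing periods are first filled with the mean of the
same period-of-year in the adjacent years (one-sided at record edges),
then by HANTS — iterative least-squares fitting of mean + 3 annual-cycle
harmonics on the 24-period year, rejecting points with residuals below
−2.5 residual-sd per iteration (low-side rejection, because residual
cloud contamination biases reflectance-type composites low), at most 10
iterations, requiring 2·harmonics+1 points.  Valid retained observations
are never altered; fill provenance (observed / seasonal / harmonic /
missing) is recorded per cell.  An exact-fit guard stops the rejection
loop when the residual sd falls below 1e-10 of the data scale, which
otherwise devours points on noiseless series through floating-point
residuals.

## 5. SIF emulation

Screened soundings (best quality, clear sky, nadir) are aggregated to
daily cell means — averaging n soundings shrinks retrieval noise by
1/√n — and cells with fewer than 5 soundings are dropped.  Splits are by
calendar year with the test years *outside* the training years on both
sides, to avoid temporal-autocorrelation leakage; a seeded exact 20 % of
training cells forms the validation set.  The emulator maps standardized
(red, NIR, cos SZA) to SIF through a feedforward network; the
hyperparameter grid spans learning rates {1e-3, 5e-4}, 1–3 hidden layers
and widths {8, 32, 64}, each trained 40 epochs with no early stopping;
the best validation Nash–Sutcliffe efficiency (NSE) wins and is retrained
on train+validation.  Predictions at cos(SZA) ≤ 0 are defined as 0
(polar winter); out-of-range reflectance is clipped with a warning.
At the default sounding noise the held-out-year NSE against observed cell
means is ≈ 0.96 (the observation-noise ceiling is ≈ 0.98) and ≈ 0.997
against the noise-free truth; label permutation drives the test NSE to
≤ 0.

## 6. Product layers and solar geometry

Three layers: `clear_inst` (emulated SIF at the 13:36 overpass),
`clear_daily = clear_inst · cos(SZA)_daily / cos(SZA)_inst` with
`cos(SZA)_daily` the 24-h mean of max(cos SZA, 0) (midpoint rule, 2-min
step, converged to < 1e-6), and
`all_daily = clear_inst / PAR_clear-inst · PAR_daily` where
`PAR_clear-inst = S0 · E0(doy) · cosSZA · τ^(1/cosSZA) · f_PAR`
(S0 = 1361 W m⁻², broadband transmittance τ = 0.75, PAR fraction
f = 0.45 — a deliberately simple single-transmittance clear-sky
atmosphere, config-exposed) and `PAR_daily` is the covariate downward
radiation times f.  Declination uses the Spencer truncated-Fourier
series; the overpass local solar time is held at 13:36 for all latitudes
(a documented simplification of the true orbit).  Analytic anchors:
at the equator on the equinox the daily mean is 1/π and the daily/inst
ratio is (1/π)/cos 24°.  High-latitude winter cells (sun below horizon at
overpass) are 0 in all layers.

## 7. Validation machinery

* **Vegetation indices**: NDVI; kNDVI = tanh(((NIR−red)/2σ)²) with
  σ = 0.5(NIR+red) per pixel by default (reducing kNDVI to tanh(NDVI²);
  a fixed-σ mode exists); NIRv = NDVI·NIR; NIRvP = NIRv × downward
  radiation.
* **Metrics**: NSE, RMSE, squared Pearson correlation, with pairwise
  valid masking; NSE on zero-variance observations is an error, not ±inf.
* **PICS diagnostics**: annual PICS-mean series → linear detrend →
  divide by the series mean (percent anomalies); per sensor switch, the
  |12-month-after − 12-month-before| mean difference as percent of the
  series mean; optional correlation of the annual anomalies with a global
  product anomaly series.
* **Trends**: OLS slope (reported per decade) and the Theil–Sen slope
  with a modified Mann–Kendall test.  The variance correction follows
  the rank-autocorrelation inflation with per-lag significance screening
  (α = 0.05), with two calibration choices made after Monte-Carlo
  checking: the autocorrelation is estimated on the *raw* ranks (Sen
  detrending first absorbs the low-frequency power of strongly
  autocorrelated series and under-corrects — empirical rejection at
  AR(1) ρ = 0.6 was ~0.21 with detrending vs ~0.08 without), and the
  inflation factor is clamped at 1 (serial correlation cannot shrink the
  MK variance; unclamped, spurious negative screened lags push white-noise
  rejection to ~0.07).  With these defaults the empirical type-I error at
  n = 50 over 1000 replicates is 0.046 on white noise and 0.077 under
  AR(1) ρ = 0.6 (the unmodified test rejects at 0.28).  The trade-off:
  for series with a very strong genuine trend the raw-rank
  autocorrelation overestimates, making the test conservative; a
  noiseless linear trend remains clearly significant.
* **Masks and aggregation**: growing season = months with climatological
  temperature strictly above 5 °C; low-signal exclusion below
  0.03 mW m⁻² nm⁻¹ sr⁻¹ multi-year mean; spatial means weighted by
  cos(latitude); a common mask is applied across compared products.
* **Site comparison**: biweekly periods qualify only with mean QC > 0.7
  (strict); per-site R² of each proxy against GPP; paired t-tests across
  sites within a land-cover class (one-tailed for "A beats B",
  two-tailed for difference, α = 0.05); an era-split mode restricts to
  sites with ≥ 3 years of qualifying data on each side of the split year.

## 8. Problem sizes and defaults

The headline scene is 40×40 pixels × 16 years at biweekly cadence
(384 composites), 10 calibration + 10 held-out PICS; the emulator fixture
uses ~64 000 gridded cell-days from 4 years of soundings (≈ 700 000
soundings) with an 18-point hyperparameter grid.  These sizes exercise
every mechanism (pre-overlap extrapolation, per-group calibration, split
leakage control) while a full pipeline run completes in well under a
minute on one CPU.  All randomness flows from explicit integer seeds;
scene sub-seeds are drawn from one `numpy` generator so a single seed
reproduces the whole experiment.

## 9. Known limitations

* δ is a single global series per band; spatially varying sensor bias is
  outside the model, as in the source design.
* The clear-sky PAR model has no aerosol or water-vapor dependence; the
  all-sky layer inherits the covariate radiation's realism.
* The emulator sees only two bands and solar geometry; physiological
  (fluorescence-yield) variation is not represented in the synthetic SIF
  law and would not be recoverable if it were — the product is an
  APAR-weighted vegetation-activity proxy, not measured fluorescence.
* The modified Mann–Kendall defaults are calibrated for robustness at
  strong autocorrelation and are mildly conservative for strongly
  trending series.
* MVC selection bias under constant band offsets (§2) is absorbed, not
  modeled; at offset magnitudes far above the tested 5 % of the signal
  the center-anchored linear stage would need re-examination.
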