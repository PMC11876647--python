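# lcspp — a long-term continuous SIF-informed photosynthesis proxy

Satellite solar-induced chlorophyll fluorescence (SIF) is one of the best
space-based proxies for terrestrial photosynthesis, but direct SIF
records only begin in the mid-2010s.  Multi-decadal red/near-infrared
reflectance from legacy wide-swath sensors reaches back to the early
1980s — at the price of orbital drift (the overpass, and with it the
solar zenith angle SZA, slides over each platform's lifetime),
systematic steps between successive instruments, and no on-board
radiometric calibration.

This package implements, end to end and on fully synthetic archives with
known ground truth, the reconstruction chain that turns such a record
into a **L**ong-term **C**ontinuous **S**IF-informed **P**hotosynthesis
**P**roxy:

1. **Compositing** — daily two-band observations to half-month NDVI
   maximum-value composites (24 periods/year), with QC-bit screening and
   instrument-malfunction exclusion windows;
2. **Harmonization** — an inter-sensor bias proxy δ from bright
   pseudo-invariant calibration sites (PICS), then a per-pixel,
   per-period OLS of reflectance anomalies on
   [SZA anomaly, δ, Ta, P, Rad, 1], removing only the SZA and δ terms:
   ρ′ = ρ − a₁·SZA − a₂·δ;
3. **Cross-calibration** — per sensor group, a 5×5-window pixel-wise
   linear map onto a stable reference sensor over their overlap, plus a
   small neural network mapping environmental covariates (AOD, snow
   depth, cloud cover, elevation, aridity, corrected red/NIR) to the
   remaining residual γ = reference − mapped; both applied over the whole
   record, followed by seasonal-mean and HANTS harmonic gap-filling;
4. **Emulation** — a feedforward network from (red, NIR, cos SZA) to
   gridded SIF soundings (cells with < 5 soundings dropped; grid search
   over learning rate × depth × width, 40 epochs, NSE model selection);
5. **Products** — SIF_clear-inst at the 13:36 overpass,
   SIF_clear-daily = SIF_clear-inst · cos(SZA)_daily / cos(SZA)_inst with
   cos(SZA)_daily = (1/24h)∫ max(cos SZA(t), 0) dt, and an all-sky daily
   layer rescaled by downward radiation against a clear-sky PAR model;
6. **Validation** — PICS discontinuity/anomaly diagnostics, NSE/RMSE/R²,
   NDVI/kNDVI/NIRv/NIRvP baselines, site-level GPP comparison with QC
   screening and paired tests, and OLS / Theil–Sen trends with a
   variance-corrected Mann–Kendall test.

The synthetic-scene generator (`lcspp.synthetic`) is first-class code: it
injects SZA drift ramps, inter-sensor offsets, covariate responses, cloud
gaps and noise with every true parameter retained, so the calibration is
judged by *parameter recovery* rather than by eye.  See
`docs/methods.md` for the model details and design decisions.

## Worked example

The numbered scripts under `analysis/` run the whole study; each prints
what it found and writes tables under `results/`.

```bash
python analysis/01_simulate_scene.py
python analysis/02_calibrate_reflectance.py
python analysis/03_train_emulator.py
python analysis/04_produce_products.py
python analysis/05_validate_products.py
```

`02_calibrate_reflectance.py` prints, for the held-out PICS pixels
(never used in fitting):

```
held-out PICS diagnostics (worst over switches and bands):
  raw                    max discontinuity 6.922%  max |anomaly| 3.542%
  sza_bias_corrected     max discontinuity 0.106%  max |anomaly| 0.197%
  linear_calibrated      max discontinuity 0.195%  max |anomaly| 0.191%
  double_calibrated      max discontinuity 0.156%  max |anomaly| 0.171%
```

Reading: the injected sensor switches put ~7 % steps (red band) into the
raw record; after the full chain the 12-month before/after discontinuity
at every switch is 0.16 % of the series mean and the annual detrended
anomalies stay within 0.17 % — the bright stable targets are flat again,
so trends computed from the calibrated record are not sensor artifacts.

`03_train_emulator.py` reports the SIF emulator's held-out skill, overall
and per land-cover class:

```
selected architecture: 3 layer(s) x 64 units, lr 0.001  (validation NSE 0.958)
class     n   nse  rmse  nse_vs_truth
  ALL 31849 0.956 0.040         0.997
```

NSE 0.956 against the noisy gridded soundings is essentially the
observation-noise ceiling; against the noise-free generating law the NSE
is 0.997.  `04_produce_products.py` then prints the product-level
summary, e.g. an all-sky/clear-sky mean ratio of 0.80 with
normalized-anomaly correlation r = 0.983 (radiation variability barely
touches interannual anomalies), and growing-season trends
(≈ +0.0024 mW m⁻² nm⁻¹ sr⁻¹ per decade for the clear-sky daily layer,
agreeing between OLS and Theil–Sen).  `05_validate_products.py` shows the
emulated-SIF proxy explaining more site-GPP variance (mean R² 0.90) than
the reflectance-only indices (NDVI 0.76, kNDVI 0.77, NIRv 0.82) and the
held-out PICS anomalies uncorrelated with the global product (p > 0.29).

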