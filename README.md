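# terraflux

Terrain-controlled stability analysis of soil respiration surveys.

## The problem

Soil respiration (R<sub>s</sub>, µmol CO₂ m⁻² s⁻¹) in semi-arid grasslands is
highly variable in both space and time, driven by soil temperature, soil
water content (SWC) and soil organic carbon (SOC). Repeated chamber surveys
on a fixed grid of measuring positions raise a stability question: which
positions keep their place in the spatial activity pattern through droughts
and wet spells (a *resistant* response), and which swap places campaign by
campaign (a *resilient* response)? And does micro-topography — on a site
with barely 1.5 m of total relief — control which response a position shows?

`terraflux` is for ecologists and biogeochemists who run such repeated
spatial campaigns. It provides:

* **Rank-based stability proxies.** Within each campaign, positions are
  ranked by flux (1 = smallest). Per position, `rankRs` is the mean rank
  over campaigns (persistent activity level) and `rangeRs` is max − min rank
  (response amplitude). Both are invariant to monotone transforms of the
  flux, so campaigns made under wildly different conditions are comparable
  without detrending.
* **Multi-scale terrain attributes** by a "mixed scaling" DEM pyramid: the
  base DEM (0.2 m) is aggregated by factors of two (0.2 … 6.4 m) plus a
  level matched to the sampling grid (10 m); local mean elevation (mALT),
  elevation SD, topographic position index (TPI), slope (Sl), Northness and
  Easterness are computed at each level and disaggregated back to base
  resolution.
* **Geostatistics**: Matheron variograms, exponential/Gaussian/spherical
  model fits with Nash–Sutcliffe efficiency (E) and range screening,
  ordinary kriging (OK) and kriging with external drift (KED), and
  leave-one-out cross-validation (nRMSE, meanErr, MSDR).
* **The bell-curve stability model.** Response amplitude against activity:

  rangeR<sub>s</sub> = a · (σ√2π)⁻¹ · exp(−(rankR<sub>s</sub> − µ)² / 2σ²)

  with µ and σ fixed at the sample moments of rankRs, leaving the scale *a*
  as the single free parameter (closed-form least squares). Small and large
  rankRs with small rangeRs mark two *equilibrium states*: state I
  (persistently active positions, low elevations, high SOC/SWC) and
  state II (persistently inactive positions, local ridges); the middle
  ranks form a resilient pool with peak amplitude.
* **A synthetic-study generator** that emulates the study design the proxies
  were developed for: 78 positions on an 80 × 60 m grid, 15 campaigns over
  spring/drought/autumn regimes, SOC sampled in 6 campaigns, and terrain-
  driven SOC/SWC fields reproducing the observed correlation structure.

## Worked example

```python
import terraflux as tf

model = tf.SoilRespirationStability.from_synthetic(seed=1)
res = model.fit()
print(res.summary())
```

```
Soil respiration stability analysis
===================================================
positions: 78   campaigns: 15
rankRs  mean   39.50   SD  21.90
rangeRs mean   19.95   max  43.00

Bell-curve stability model (fixed moments, n = 78)
  a     =    1558.7706  (SE 57.9179, p = 1.34e-40)
  mu    =      39.5000
  sigma =      21.8987
  peak rangeRs at mode = 28.397
  F vs constant model  = 11.983 (p = 0.000884)

State occupancy:
  state intermediate  n = 44
  state I             n = 19
  state II            n = 15

Correlations at p < 0.05 (terrain levels 1-5):
  scale-independent pairs : 74
  less-smooth-only pairs  : 1
```

Reading the numbers: with 78 tie-free positions the mean rank is (78+1)/2 =
39.5 by construction; the interesting quantities are the spread (SD 21.9)
and the bell fit. The positive, highly significant scale *a* says response
amplitude peaks at intermediate activity (fitted peak ≈ 28 rank units at
rankRs ≈ 39.5) and falls off toward both rank extremes — the two resistant
equilibrium states, here holding 19 (state I) and 15 (state II) of the 78
positions. `res.plot_bell()` draws the scatter and fitted curve;
`res.correlations` and `res.scale_classes` hold the full correlation scan.

The same analysis runs from the shell:

```bash
terraflux run --simulate --seed 1 --out my_run     # full pipeline
terraflux simulate --seed 1 --out data             # just the generator
terraflux proxies --panel data/panel.csv --out proxies.csv
```

`terraflux run` writes the DEM, campaign panel, proxy and attribute tables,
variogram fits, OK/KED maps with kriging variances, cross-validation
metrics, correlation/scale-class tables, state assignments and a
`summary.json` + `manifest.json`, all deterministic for a fixed seed.

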