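# Methods

This note documents the models and procedures implemented in `terraflux`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## Stability proxies

Within each campaign the soil-respiration values of the n positions are
ranked ascending (1 = smallest). Ties receive the mean of the spanned ranks
by default; `min` and `ordinal` rules are available because field datasets
with instrument-resolution ties can need a different convention to be
reproduced exactly. Missing positions are excluded from a campaign's
ranking (ranks run 1..n_available), and per-position summaries average over
the campaigns actually observed. Consequences asserted by the tests: each
campaign's ranks sum to n(n+1)/2; with no ties or gaps the mean of `rankRs`
over positions is exactly (n+1)/2 (39.5 at n = 78); `rangeRs` ∈ [0, n−1],
zero iff a position's rank never moves.

Subgrouping: S/M/L cut `rankRs` at mean ± sample SD with a closed middle
interval (boundary values are M; with zero variance everything is M).
SOC quintiles C1..C5 use the ordinal-rank rule: after a stable sort by
(meanSOC, position order), sort index i of n maps to quintile
⌊5·i/n⌋ + 1. At n = 78 this splits as 16/16/15/16/15. The rule is invariant
under monotone transforms and makes tie handling deterministic; exact
duplicate meanSOC values below 5 distinct values raise an error naming the
duplicates rather than guessing.

## Terrain attributes and the mixed-scaling pyramid

The pyramid aggregates the base DEM (block mean over 2×2 cells per level,
i.e. a box blur followed by subsampling) through levels at 0.2, 0.4, 0.8,
1.6, 3.2 and 6.4 m, plus a final level built by direct block-mean
aggregation from the base to the 10 m field-sampling resolution (6.4 → 10
is not a doubling, so the last step does not continue the ×2 series). An
optional Gaussian pre-filter (σ = width/4) before subsampling is available
as `kernel="gaussian"`; the box kernel is the default used throughout.

At each level six attributes are computed on that level's own grid with a
3×3 cell window — the physical neighbourhood therefore grows with the
level, which is precisely how scale enters the analysis:

* mALT, SD: moving-window mean and standard deviation of elevation.
  Windowed moments are computed on elevations centred on the global mean,
  which keeps the variance formula exact for constant rasters.
* TPI: centre elevation minus the mean of the window *excluding* the
  centre. Under periodic boundaries its raster mean is exactly zero.
* Sl: slope angle from Horn's 3×3 finite differences, in degrees.
* North/East: cosine and sine of the downslope aspect measured clockwise
  from geographic north, i.e. North = −(∂z/∂y)/|∇z|, East = −(∂z/∂x)/|∇z|.
  Flat cells (|∇z| = 0) get North = East = 0 by convention, so
  North² + East² = 1 exactly where Sl > 0.

Edge handling renormalizes the window over available cells (no padding
values); missing cells are NaN-propagated for slope and excluded from
window statistics. Ragged grids are padded with missing cells at the
south/east margins during aggregation so the north-west corner stays
anchored; all-missing blocks stay missing, and block-mean aggregation of
evenly divisible grids preserves the global mean exactly.

Attribute rasters are disaggregated (nearest-neighbour replication) back to
base resolution and sampled at point positions by cell membership, with the
upper x/y edge inclusive so lattice endpoints on the extent boundary remain
valid.

## Geostatistics

Empirical variograms use the Matheron estimator on 10 equal-width distance
bins up to half the maximum pairwise distance (both configurable). Model
families — exponential, Gaussian, spherical, each parameterized by nugget,
partial sill and *practical* range — are fitted by least squares weighted
by the per-bin pair counts (scipy trust-region with non-negativity bounds).
`SSErr` is the weighted residual sum of squares; the Nash–Sutcliffe
efficiency E = 1 − SS_res/SS_tot is computed unweighted on the binned
semivariances. Selection keeps fits with E > 0.5 and range smaller than the
diagonal of the data bounding rectangle, then takes the minimal-SSErr
survivor; if nothing survives a rejection object is returned and the
mapping layer falls back to KED only (using the best-E fit purely as the
covariance model, since KED needs one). On default synthetic data the
`rangeRs` variogram is routinely rejected while the other three variables
map normally — amplitude is spatially much noisier than level.

Kriging solves the global semivariogram system (all data points; at n ≈ 78
no search neighbourhood is warranted): ordinary kriging with the constant-
mean constraint, KED with one exhaustively known covariate (default: the
coarsest-level mALT surface, the only exhaustive covariate in this setting)
added as a second unbiasedness constraint. An exactly constant drift is
algebraically degenerate and is solved with the OK system instead, to which
KED reduces in that limit. Kriging variances are wᵀγ₀ + Σλ·basis; tiny
negative values from floating-point roundoff (> −1e-8) are clipped to zero.
Exactness at data points with zero nugget, shift equivariance (weights sum
to 1) and agreement with dense hand-assembled solves are asserted in tests.

Leave-one-out cross-validation reports meanErr (bias), nRMSE (RMSE divided
by the observation span) and MSDR (mean of squared errors over kriging
variances), which sits near 1 when the variance model is well specified —
verified at n = 200 on simulated spherical fields (drawn by Cholesky
factorization of the model covariance).

## The bell-curve model and equilibrium states

`rangeRs = a · N(rankRs; µ, σ)` with N the Gaussian density. By default µ
and σ are *fixed* at the sample moments of rankRs — the model as used has a
single free parameter with the closed-form solution
a = Σyᵢgᵢ / Σgᵢ², gᵢ the unit density at rankRsᵢ; this estimator is linear
in y and hence unbiased, which the 200-replicate recovery simulation
confirms to within 2%. A full three-parameter nonlinear fit (initialized at
the moment solution) is available for sensitivity analysis. Because the
one-parameter model is not nested in the constant model in the usual way,
significance is reported two ways: an F-type test comparing residual sums
of squares against the mean-only model (1 and n−2 df for the fixed-moment
fit), and a Wald t-test on a. Degenerate inputs (constant rangeRs) are
flagged rather than rejected.

State classification operationalizes the two-equilibrium concept through
the rank groups: L → state I, S → state II, M → intermediate. The per-state
summary reports mean rankRs, rangeRs, meanSOC, meanSWC and any terrain
attribute columns supplied, which is how the "state I = low, carbon-rich,
wet positions; state II = ridge-top, carbon-poor positions" narrative is
checked quantitatively.

Correlation scans use Pearson correlation ("linear correlation") with
two-sided p-values at α = 0.05 and *no* multiplicity correction — matching
the per-test reporting convention of spatial-ecology field studies at this
sample size; a Benjamini–Hochberg option exists but is off by default.
Scale reach per (variable, attribute, subgroup): significant at all of
levels 1–5 with consistent sign → scale-independent; significant exactly at
{1,2} or {1,2,3} → valid at less-smoothed scales only; otherwise none.
Subgroups with fewer than 3 positions are skipped with a warning.

## The synthetic-study generator

The generator emulates the study conditions the proxies were designed for:
a 0.2 m DEM over 80 × 60 m with total relief rescaled to exactly 1.5 m,
78 positions (a 9 × 7 lattice at 10 m spacing plus 15 midpoint in-fills —
78 positions on an 80 × 60 m grid over-determine a pure 10 m lattice, so
the in-fill layout is our documented choice),
15 campaigns in spring/drought/autumn triplets and SOC observed in 6 evenly
spread campaigns.

Terrain is Gaussian-filtered white noise with a 10 m correlation length —
short enough that an 80 × 60 m site contains many independent aspect
patches, as on a wind-formed hummocky sand grassland. Static soil fields
follow the terrain with independent noise: SOC decreases with elevation,
elevation SD and slope and increases with Northness/Easterness
(standardized coefficients 0.8/0.5/0.5/0.8/0.8 — the aspect terms are
strong because wind exposure of south-west-facing slopes is a first-order
control on organic-matter accumulation at the emulated site); baseline SWC
decreases with elevation, SD and slope. With these defaults the expected
correlation sign structure holds at every pyramid level in 20/20 generator
seeds.

The flux model is the minimal mechanism reproducing the qualitative
behaviour of the field system, *not* a calibrated ecosystem model:
Rs = rs_ref · (1 + 0.45·z(SOC)) · Q10^((Ts−10)/10) · exp(−((SWC−25)/18)²)
with Q10 = 2, plus 0.35 µmol m⁻² s⁻¹ measurement noise, clipped at zero;
campaign regimes scale each position's baseline SWC by a site-wide wetness
multiplier (0.5–1.3) and set the campaign temperature (8–26 °C). SOC
anchors the persistent ranks; the non-monotone moisture response plus noise
reorders mid-rank positions between wet and dry campaigns, which is what
produces the bell-shaped rangeRs–rankRs relation downstream — rank extremes
are additionally stabilized by the order statistics themselves (an extreme
position needs a large perturbation to change rank, a middle one does not).

What the generator does **not** emulate: real spatial autocorrelation of
measurement error, drift in the position locations between campaigns,
vegetation/NDVI dynamics, precipitation history (campaign regimes are
exchangeable draws, not a weather sequence), or SOC change over the study
years (SOC is static plus sampling noise). Passing tests therefore show the
pipeline's statistics behave correctly under the design's assumed
structure, not that the flux model is an adequate ecosystem description.

The site-meteorology helper ships the annual temperature/precipitation/NEE
table of the emulated site; the anomaly helper rounds percent deviation
from the 585 mm long-term mean to the nearest integer, reproducing the
wettest year's +39% (813 mm). For the driest year (431 mm) this arithmetic
gives −26%, not the −27% sometimes quoted for the site — at these
magnitudes one percentage point hinges on the rounding convention, so only
the wettest-year figure is asserted.

## Problem sizes and numerical choices

Default problem sizes (full 400 × 300-cell DEM, 5 pyramid levels, 78
positions, 15 campaigns; 20-seed replication for the qualitative checks;
200 replicates for recovery simulations; n = 200 simulated fields for the
geostatistical calibration) were chosen so every property of interest is
measured with comfortable margin while the whole suite and the acceptance
script each run in well under a minute on a single CPU. Determinism: all
randomness flows from `numpy.random.default_rng` seeded per stage via
`SeedSequence.spawn`, so identical seeds give bit-identical panels and
byte-identical pipeline summaries.

Known limitations: isotropic variograms only (no anisotropy, co-kriging or
Bayesian variants); global kriging neighbourhoods (quadratic memory in n,
fine below a few thousand points); the level-7 attribute window covers
30 × 30 m at the 10 m resolution, so only sites larger than that support
the full pyramid; and GeoTIFF I/O writes plain ModelPixelScale/ModelTiepoint
tags without a CRS definition (coordinates are projected metres by
convention).
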