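# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind `zosrec`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Wave energy engine (`zosrec.waves`)

Relative wave energy (RWE, J per meter of wave crest) indexes hydrodynamic
disturbance. For a wind event of speed *U* (m/s) with fetch *F* (m) and
mean depth *d* (m) along the upwind ray, significant wave height and period
come from the shallow-water fetch-limited SMB growth forms

    H = 0.283 (U²/g) tanh(0.530 d*^0.75) tanh(0.00565 F*^0.5 / tanh(0.530 d*^0.75))
    T = 7.54  (U/g)  tanh(0.833 d*^0.375) tanh(0.0379 F*^{1/3} / tanh(0.833 d*^0.375))

with d\* = gd/U², F\* = gF/U²; the wavelength L solves the linear dispersion
relation L = (gT²/2π)·tanh(2πd/L) (fixed-point iteration, 100 iterations,
absolute/relative tolerance 1e-12), and RWE = (ρ g H²/16)·L with
ρ = 1025 kg/m³. This is a *relative* index: no swell, tides, currents,
refraction or breaking. RWE is zero at zero wind and monotone
non-decreasing in both speed and fetch (property-tested).

Conventions: wind directions are meteorological "from" bearings; the fetch
ray for a wind event is cast *upwind* (the open-water distance the wind
crossed before reaching the station); 32 sectors of 11.25°, centered on
compass bearings; rays marched at bathymetry cell resolution, terminated at
the first land (nodata) cell, capped at `max_fetch` (default: the grid
diagonal), with an open grid edge treated as unlimited fetch (capped). A
month's wave climate is the mean over its top-5% wind events (ties at the
quantile kept; calm/variable records excluded; months with fewer than 20
usable records flagged missing); the per-month standard deviation and
maximum over events are carried alongside, since the observed monthly
summaries include dispersion statistics (sdRWE, mxRWE).

Spatial summaries: distance annuli are half-open 2000-m bands of distance
from the *site boundary* (stations inside the site fall in the first band);
site zones come from UPGMA clustering of stations on Euclidean distance
over their monthly series, with k chosen by mean silhouette over a k-range
and an optional spatial-contiguity penalty (the fraction of stations whose
nearest spatial neighbor lies in another zone, weighted by a configurable
coefficient, default 0: the original zone drawing favored spatially
coherent clusters by judgment, which no index reproduces exactly). A
degenerate all-identical field falls back to a single zone.

## Temperature hindcast and summaries (`zosrec.climate`)

The bottom-water temperature offset (site minus oceanic SST) is regressed
on the air–sea differential (°C), wind chill (W/m²) and the mean wind speed
of the trailing 3-day window (today and the two previous days; the first
two days of any span are therefore undefined), with all interactions
through the three-way term (8 coefficients). Wind chill uses the
Siple–Passel heat-loss index, 1.163·(10√v + 10.45 − v)·(33 − Tₐ), the
classic W/m² formulation consistent with the stated units. Site series are
smoothed with a 7-point centered running mean before fitting (edges use the
available partial window; the smoother is idempotent on constants and
leaves linear ramps unchanged on the interior). Hindcast site temperature
is SST plus the predicted offset; predictor gaps longer than 7 days are
flagged, never interpolated. When validation observations are supplied the
report carries the fraction of days within 1 °C.

Monthly threshold exceedance uses six bands — <0, <5, <10 °C, the closed
optimal band [10, 20] °C, >20, >25 °C — so the central trio {<10, optimal,
>20} partitions the line and the outer bands nest monotonically (<0 ≤ <5 ≤
<10; >25 ≤ >20), both property-tested. Months with partial data use the
available-day denominator; wholly missing months are linearly interpolated
per band from adjacent months (interpolation on proportions, not on daily
temperatures — the raw days no longer exist at that point); missing months
at the series ends stay missing.

Monthly atmospheric summaries exclude calm/variable records from both the
speed mean and the direction components (eastness = mean sin θ, northness =
mean cos θ, so eastness² + northness² ≤ 1); rainfall is the monthly total
in tenths of mm.

## Recruit census (`zosrec.census`)

Recruits are connected components of a spring (March–May) map that do not
intersect the presence mask (union of all maps through the preceding
December) and lie wholly inside the site after shrinking its east and west
edges by 20 m (lateral naked-seed import control; the north–south extent
already brackets the meadow). Classification measures the minimum
boundary-to-boundary Euclidean distance to seagrass mapped two springs
prior: ≤ 6 m → NSD (the boundary value 6.0 is NSD, matching the inclusive
0–6 m class), otherwise RSD; an empty reference makes every recruit RSD.
First-observation patches ≥ 4 m² raise a warning (plausible missed-history
artifacts).

Standardization: the reference's 6-m band and its complement (within the
east-west-buffered site) are the NSD and RSD distance classes; bare space
is each class's area minus seagrass at the *dehiscence epoch* (latest map
on or before July 1 of the previous year, consistent with June fruit
maturation); the NSD rate divides by bare space × source area (source =
seagrass inside a 14-m east-west-buffered site at seed production, i.e. the
6-m dispersal range applied to both edges of the 20-m detection buffer),
and the RSD rate divides by its bare space alone. The two NSD divisors are
applied multiplicatively (units recruits·m⁻²·m⁻²). Reference or dehiscence
maps missing for a year fall back one further year, flagged. Counts (not
areas) are the census currency. All geometry is planar meters in a single
projected frame; maps are exchanged as GeoJSON FeatureCollections with a
`date` property.

## Lagged predictors (`zosrec.lagfeat`)

The census anchor is May. Four window families per monthly variable (58
canonical windows after duplicate removal): 12 single months (offsets
1–12), expanding windows anchored at offset 1 out to the previous May, the
24- and 36-month means, and all 34 contiguous 3-month windows with start
offset ≤ 36. Labels follow the grammar `<var>_p(<Mon> | <Mon>To<Mon> |
<N>mo | <k>y<backward month initials>)`; the twelve backward initial
triples (JDN, FJD, MFJ, AMF, MAM, JMA, JJM, AJJ, SAJ, OSA, NOS, DNO) are
distinct, and the year index k (calendar years between the census and the
window's oldest month) pins the repeat, so parse/format is bijective on the
canonical windows (hypothesis-tested). Windows are arithmetic means; any
missing month voids the window (no partial means). Features constant across
census years are dropped before screening. Expanding windows anchor at
offset 1 (April backward); anchoring at the previous May instead is a
documented alternative that was not adopted because the published
`pAprToNov` label resolves to the offset-1 anchoring.

## Wave regimes (`zosrec.regimes`)

A census year's wave climate is the station × station Euclidean distance
matrix over its 34-month recruitment period (May back through the third
previous August). Second-stage analysis computes Spearman ρ between the
vectorized lower triangles of every pair of per-year matrices; the derived
dissimilarity is 1 − ρ (the conversion is a package choice; any strictly
decreasing transform gives identical rank-based downstream results).
ANOSIM uses R = (r̄_between − r̄_within)/(M/2) on average-ranked
dissimilarities with seeded label permutations (the observed labelling
counts toward P); the Spearman Mantel test (RELATE) permutes one matrix's
row/column order. Both are cross-checked against scikit-bio in the test
suite. nMDS minimizes Kruskal stress-1 via SMACOF with one classical-scaling
initialization plus seeded random restarts (default 100), recomputing
stress-1 from the winning embedding by isotonic regression. UPGMA is
scipy's average linkage (deterministic, index-order ties), rendered to
Newick when a tree is exchanged. SIMPER is adapted to squared-Euclidean
decomposition (the underlying resemblance is Euclidean, not Bray–Curtis):
a variable's contribution is its mean squared difference over between-group
pairs, normalized to 100%.

## Model search (`zosrec.modelsearch`)

Screening: Pearson correlation of each lagged feature with the
log-transformed response; retain P < 0.05; then a stability filter drops
predictors whose significance or sign flips when any single year is left
out, or whose dispersion is concentrated in one year (a single observation
carrying more than half of Σ(x−x̄)²) — the mechanized version of visual
outlier/abscissa-dispersion assessment. No multiple-testing correction is
applied at screening; the stability filter is the guard.

Collinearity: UPGMA on 1 − |r| cut at 0.30 (i.e. within-group |r| ≥ 0.70),
with same-variable windows that overlap in time forced into one group
(temporal redundancy) regardless of sample correlation; groups are culled
to their 4 members most correlated with the response, preferring location
statistics over dispersion statistics (sdRWE/mxRWE).

REVS: for every combination of one predictor per group, exhaustive
all-subsets OLS ranks predictors by how often they appear in the best model
of each size (ties by mean |standardized coefficient|), and the nested
sequence adding predictors in importance order yields the candidates,
pooled and deduplicated across combinations. Tractability guards, both
deterministic: only the 6 most response-relevant groups enter (ranked by
their best member's |r|), and group memberships are truncated toward their
top member if the combination count would exceed 256 — the original
procedure operated on 3–4 groups, so these caps bind only in
automated-screening regimes with many spurious groups.

Diagnostics (defaults, all configurable): VIF < 10; |Cp − (p+1)| ≤ 2 with
σ̂² from the combination's full model; Shapiro–Wilk P > 0.05 on internally
studentized residuals; Breusch–Pagan P > 0.05; Durbin–Watson in [1, 3];
max Cook's D < 1. AICc counts k = p + 2 parameters (slopes + intercept +
error variance); with n = 7 the correction explodes for k ≥ 5, which is why
the published setting leaned on LOOCV as well. AICc weights are
exp(−Δᵢ/2)/Σexp(−Δⱼ/2). LOOCV uses the hat-matrix identity
Σ(eᵢ/(1−hᵢᵢ))²/n, verified against explicit refits at every invocation
where `check_identity` is set (and once per test run).

Selection: among diagnostics passers, lowest LOOCV RMSE under the
one-standard-error rule — candidates within one SE (delta-method SE of the
best model's cross-validated RMSE) are ties, resolved by parsimony (fewest
predictors), then AICc, then a preference for all-location-statistic
predictor sets. No passers is an error listing every candidate's failure
modes. Ensemble averaging over candidates is deliberately out of scope;
the audit table supports it downstream.

## Forecasting (`zosrec.forecast`)

`ForecastModel` is a linear model of a log recruitment rate; the published
NSD and RSD instances carry the printed coefficients. **Logs are natural
logarithms throughout** — the base is a convention with large consequences
on the natural scale, so it is fixed and stated here. Prediction intervals
use the standard linear-model forms (t quantiles when n is known); the
printed instances carry no estimate covariance, so they give point
predictions only. Inputs outside the observed monthly ranges (the validity
envelope; a windowed feature is compared against the loosest bound over its
window's calendar months) are flagged, never refused. NSD:RSD relative
importance de-standardizes both predictions to counts at fixed reference
areas (defaults: the fitted data's time-series means; the ratio is
invariant to a common rescaling of the NSD product and the RSD area), with
var(log ratio) = var(logNSD) + var(logRSD) to first order.

## Synthetic study system (`zosrec.synth`)

The generator emulates a shallow temperate backbarrier lagoon:

- **Wind**: hourly Weibull speeds (shape 2, scale 5 m/s, mild seasonal
  modulation: winter ×1.10–1.15, summer ×0.80) with von Mises directions
  (κ = 1) swinging from NNW (330°) in winter through W to SSW (210°) in
  summer — a westerly-dominated climate whose monthly eastness/northness
  and mean speeds fall in the observed ranges; 5% of records flagged
  calm/variable.
- **Temperature**: air sinusoid 12 ± 10 °C peaking around day 205 with
  AR(1) noise (σ = 1 °C, ρ = 0.8) and N(0, 1 °C) yearly anomalies shared
  (damped ×0.8) by the SST series, which also has 80% amplitude and a
  two-week lag — the ocean integrates. Bottom-temperature exceedances are
  computed from the daily SST series.
- **Rainfall**: monthly gamma totals (shape 2, scale 400 tenths-mm) spread
  over 10 wet days.
- **Bathymetry**: a linear south–north shoaling ramp (0.25–4 m) inside a
  land rim, as an ESRI ASCII-style grid.
- **Landscape**: founders dilate radially by `patch_growth` (default
  30 cm/yr, admissible 13–46); yearly recruit counts are Poisson with
  log-intensity `truth_beta · x` plus lognormal environmental noise
  (σ = 0.25) — overdispersion is ubiquitous in recruitment data, and
  without it the log-scale Poisson noise is heteroscedastic across a
  100-fold intensity range, which the generative regression model would
  then genuinely violate. NSD discs are placed with exponential boundary
  offsets (scale 2 m, capped at 5 m) from seagrass mapped two springs
  prior; RSD discs fall uniformly over bare space beyond 6.5 m of it; all
  discs (radius 0.35–0.8 m, first-observation area < 2 m²) stay disjoint
  from prior coverage, so a census of the generated maps recovers the
  generated counts and classes exactly. All recruits appear at one annual
  epoch (the spring map): within-season emergence timing is not resolved by
  annual spring photography, so the generator does not model it.
- **Default truth**: log NSD intensity = 5.0 + 0.002·rain_p2yJDN +
  9·eastness_pFeb; log RSD intensity = 11.0 − 1.6·mWindSpd_pMay. Effects
  are 2–3× the residual noise so they are identifiable at the study's
  problem sizes, and the truth windows are anchored on serially
  uncorrelated variables (rain, direction noise, wind-speed noise) so that
  overlapping sibling windows correlate below the 0.70 clustering
  threshold — window families overlapping in ⅓ of their months correlate
  at ≈ 0.58 for independent monthly values, making the truth window
  distinguishable in principle. One seeded `numpy.random.Generator` is
  passed explicitly everywhere; histories are bit-for-bit reproducible.

What passing tests on this system do **not** show about real data: the
generator has no spatial autocorrelation in climate, no observation error
in the maps (real photo-interpretation misses small or deep patches), no
within-year phenology, and its monthly fast path draws atmospheric
monthlies directly from the seasonal regimes rather than aggregating hourly
records (the hourly route is exercised separately at smaller spans).

## Problem sizes

Simulations are sized for single-CPU runs: the recovery study uses 30
census years, a 5-variable battery (290 lagged features), and 100
replicates; wave fields use grids of a few hundred cells and a few dozen
stations; regime analyses use 11 census years and ~24 stations; the
full-geometry census demonstration uses 7 census years with tens of
recruits per year. These sizes are stated here so results can be read at
the scale they were computed.

## Known limitations

- The wave engine is a documented approximation; no parity with any
  external wave-exposure executable is claimed, and exact regime statistics
  from the original station series require those raw tables.
- The end-to-end recovery study has a statistical ceiling below a
  90% joint success rate: (i) even oracle selection leaves each true
  coefficient only ~95% likely to lie within 2 standard errors, so two
  coefficients cap near 0.90; (ii) Mallows' Cp computed against a full
  model that automated screening has padded with spurious predictors is
  biased against the parsimonious true model; (iii) co-selected spurious
  predictors attenuate true-coefficient estimates (post-selection bias),
  which the one-SE rule mitigates but cannot remove. The acceptance run
  reports the measured rate (~65–80% of model runs, seed-dependent) rather than tuning any
  of the screening, diagnostic or selection defaults to manufacture a pass.
- The "spatially coherent" zone drawing and the "parsimony of biological
  explanation" selection criterion are human judgments; only their
  mechanizable proxies (contiguity penalty, predictor-count parsimony,
  location-statistic preference) are implemented.
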