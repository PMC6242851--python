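# Methods

This note documents the models implemented in `pinnitrack`, the choices
made where the design was genuinely open, and what the synthetic study
conditions do and do not establish about real tag data.

## Scope and data model

The package analyses satellite-relay tag data from bearded seals: GPS
fixes, per-dive records (depth, duration, depth profile), 6-hour activity
summaries, haul-out events and CTD upcasts, against an environment of
bathymetry, coastline and tidal-glacier-front polylines and dated sea-ice
fields. All geometry is computed in a local azimuthal-equidistant
projection (spherical Earth, R = 6371 km) centred on the dataset, in km;
this preserves distances from the centre exactly and keeps fjord-scale
distortion negligible relative to GPS error. Depths are metres, positive
down, for dives and bathymetry alike; timestamps are naive UTC.

## Body mass and geodesy

Body mass is the allometric power law `B = exp(-8.7167) L^1.0135 G^1.7686`
(L standard length, G girth, both cm; B kg). Girth enters with an exponent
near 2, as expected for a roughly cylindrical body of fixed density.
Great-circle distances use the haversine formula on the R = 6371 km
sphere, which reproduces the reference 306 km north–south displacement to
the printed kilometre.

## Track model (CTCRW)

Positions are interpolated with a continuous-time correlated random walk:
per planar axis, velocity is an Ornstein–Uhlenbeck process
(`dv = -beta v dt + sigma dW`) and position its integral, observed with
Gaussian GPS error (36 m default). The discrete transition is exact, so
the likelihood is computed by a Kalman filter and positions at arbitrary
times by the RTS smoother. Numerical notes:

* the process-noise term `q11` suffers catastrophic cancellation for small
  `beta * dt`; a series expansion takes over below `beta*dt = 1e-3`;
* measurement updates use the Joseph form, which stays positive
  semi-definite even with near-zero measurement noise;
* optimisation is Nelder–Mead on `(log beta, log sigma)` with 5 restarts
  (deterministic seed), tolerance 1e-6; the moment-based start uses the
  median empirical speed.

Reported haul-out intervals act as a *stopping model*: transitions inside
an interval pin velocity to zero and hold position constant. This is a
hard-constraint simplification of the continuous stopping process used in
the movement literature — justified here because haul-out events are
directly observed by the tag rather than inferred — and it makes the
contract testable (positions inside an interval are exactly constant).

Simulation-based calibration: at 15 fixes/day over 60 days the median
relative error of both parameters across 20 replicates is well under 25%
(typically ~4%).

## Home ranges (dynamic Brownian bridge)

The utilization distribution integrates, over each inter-location bridge,
a Gaussian of variance `T a(1-a) sigma2_m + ((1-a)^2 + a^2) delta^2`
(`delta` = 50 m location error, grid cell 500 m). The Brownian motion
variance `sigma2_m` is estimated on a sliding window of 35 locations with
margin 11 by leave-one-out likelihood of every odd interior location under
the bridge between its neighbours; the leave-one-out variance additionally
includes the left-out point's own location error. Within a window at most
one breakpoint (candidates outside the margins) may split the variance
into two regimes; the split is kept only if BIC prefers it. Locations
covered by several windows take the mean. Windows advance one location at
a time.

Home-range areas are highest-density regions: cells ranked by density and
accumulated to 50% / 95% mass, so areas are multiples of one cell
(0.25 km²) and nestedness holds by construction. The grid is the track
bounding box padded by three bridge standard deviations. Months with fewer
than 20 distinct transmission days are excluded from monthly ranges (20
days inclusive). The stationary-point UD reproduces the Gaussian
closed-form 95% area `pi s^2 chi2_2(0.95)` within 5% at 100-m cells.

## Habitat use

Distances to coastline/glacier fronts are planar point-to-segment minima
(shapely); bathymetry is bilinear; ice fields are matched by nearest date.
Monthly summaries are percentile bootstrap means (10,000 replicates,
seeded). Seasonal trends are OLS on the day-of-tracking index
(statsmodels); strictly positive responses with skewness > 1 are
log-transformed ("transformed as necessary"), and slope p-values are
two-sided. Cook's-distance screening is reported by the OLS machinery but
never auto-removes points.

The environmental-space UD is a product-Gaussian kernel density over
(distance to coast, distance to glacier, depth) on a 32³ lattice spanning
the data range ± one bandwidth, with per-dimension Silverman bandwidths.
"Top 25%" is read as the top quartile of evaluated density *values* (mask
at the 75th percentile), not a 25% probability region; the alternative
reading would produce a smaller, strictly nested region.

## Specialization

A 3-state HMM (travelling / foraging / hauled out) runs on 2-hourly
positions: gamma step lengths with per-state zero-inflation (haul-out
steps are exactly zero after the stopping model), von Mises turning angles
(undefined angles at zero steps are dropped from the likelihood), and
multinomial-logit transition probabilities driven by the standardized
proportions of time diving and hauled out. The likelihood is maximised
directly (scaled forward algorithm, numba-compiled) from multiple seeded
restarts; states are labelled after decoding: highest mean hauled-out
covariate → haul-out, smaller mean step of the rest → foraging.

Foraging areas: Viterbi-decoded foraging positions are grouped in 3-day
intervals; per interval, DBSCAN (min_pts = 5) with epsilon at the Gaussian
mean-change changepoint of the sorted (min_pts−1)-NN mean distances
(median fallback when no significant change) yields clusters; the largest
cluster's member nearest its centroid is the interval's foraging area.

Similarity index: for each unordered pair of a seal's foraging areas with
difference `d` in an environmental value, the index is the proportion of
*cross*-differences (focal areas × other seals' areas) strictly smaller
than `d`; ties are excluded from the numerator, making a zero-difference
pair index exactly 0. The within-other-seal pair variant is available by
flag but not the default; the cross-difference reading keeps the index a
per-seal quantity. Indices are invariant to shifting or positively
rescaling the variable for all seals.

## Dives and activity

Benthic classification uses the single inequality
`max_depth >= bathymetry - 25 m`, the branch-free union of the two printed
clauses (within 25 m of the bottom, or deeper than the chart). The bottom
phase is the interval from first entry to last exit of the 80%-of-max
depth level (linear interpolation), so descent/bottom/ascent partition the
dive exactly and brief mid-dive excursions above the threshold still count
as bottom time. Activity budgets are time-weighted means of the 6-h
summary percentages; haul-out durations are per-event minutes and
inter-haul-out intervals the gaps in hours. The monthly-mean PCA
standardizes variables, decomposes by SVD, drops constant columns with a
warning, and fixes signs so each component's largest-magnitude loading is
positive.

## Water masses

T and S are assigned to 1.5 m and the maximum dive depth by a three-way
weighted average over the seal's own CTD casts within ±10 days: each cast
is linearly interpolated in depth (targets up to 3·zeta below a cast's
deepest sample reuse that sample, with the gap penalised; deeper targets
exclude the cast), weighted by Gaussian kernels
`exp(-dt²/2tau²)·exp(-dx²/2rho²)·exp(-dz²/2zeta²)` with defaults tau = 48 h,
rho = 25 km, zeta = 10 m, and averaged over the K = 10 highest-weight
casts. The reference only requires weight to decrease in all three gaps;
the Gaussian kernels and the four scales are this package's declared
convention, all config-exposed. Classes: WCW (T < −0.5), LW
(−0.5 ≤ T < 1), then for T ≥ 1: GW (S < 34), IntW (34 ≤ S < 34.65),
TransAW (S ≥ 34.65, T < 3), AW (S ≥ 34.65, T ≥ 3). The printed
"1 ≤ temp > 3" style bounds are read as half-open upper bounds — the only
reading that partitions the plane, which the tests verify on 10⁶ random
pairs and at ±1e−9 around every threshold.

## Synthetic study conditions

The generator produces a fjord: a wiggly coastline with a 300-m zero-depth
shore shelf, depth increasing monotonically offshore at ~6 m/km, two
glacier fronts on the coast, and monthly ice fields peaking in late winter
with a near-shore land-fast band. Seals move on an hourly grid by a
3-state semi-Markov process (exponential dwells; defaults 8 h travelling,
36 h foraging, 6 h hauled out) with state-specific gamma steps and von
Mises headings. Foraging bouts target points drawn around the seal's
preference centre — an along-coast distance from its home glacier and a
preferred bottom depth, mapped to the map through the depth ramp — with a
per-seal spread: 0.6 km for specialists, 9 km for generalists (the
labelled contrast the specialization stage must recover). Dives mix
benthic (max depth within 15 m above, or up to 10 m below, local
bathymetry) and pelagic (well clear of the bottom) according to the
seal's benthic fraction; profiles are U/V-shaped. CTD casts follow a
two-layer seasonal T/S table that traverses all six water-mass classes
over the year (pycnocline at 40 m). Default rates are the tag's observed
ones: 15 fixes, 18 dives and 2 casts per day; default population 4 seals
for 60 days. All draws flow from per-seal PCG64 generators derived from
the master seed, so datasets are bit-reproducible.

What the generator does *not* emulate: Argos-class location error, duty
cycling and transmission dropouts beyond Poisson thinning, tidal currents,
real Svalbard geography, and movement that is genuinely CTCRW or
per-step-Markov (dwells are semi-Markov exponential by design, so the HMM
and CTCRW fits are misspecified-but-close, as with real data). Passing
tests therefore demonstrate that the estimators recover structure of the
kind assumed, at realistic data rates — not that they are unbiased for any
real seal.

## Problem sizes used in the checks

Calibration suites were sized to be decisive yet quick: CTCRW recovery
uses 20 replicates of 60-day tracks; the HMM oracle uses exhaustive
enumeration at T = 8 and decoding at T = 2000; the specialization
end-to-end check runs 5 replicate populations at the default study
conditions; bootstrap coverage and trend type-I error use 1000 Monte Carlo
repetitions. The similarity hand case (focal {10, 12} vs others
{10, 11, 30} → 0.5) was verified by exhaustive enumeration.

## Known limitations

* The CTCRW stopping model assumes haul-out intervals are exact; noisy
  event boundaries in real data would leak into the velocity estimate.
* The dBBMM breakpoint search considers at most one change per window.
* DBSCAN epsilon selection assumes the sorted kNN curve has a single mean
  change; multi-scale clutter can shift epsilon.
* The water-mass weighting is a declared convention; with sparse casts the
  assignment degrades to nearest-cast values.
* HMM fitting uses finite-difference gradients on a 33-parameter surface;
  with very short series (< ~200 intervals) restarts may disagree.
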