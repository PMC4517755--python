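# Methods

## Monitoring indices and the reduction estimator

A chewcard survey lays cards at 50 m spacing along lines at least 200 m
apart and scores each card as interfered/not-interfered by species after
a fixed number of nights (default six). The line-level index is
CCI = 100 · interfered / n_cards. Interference probability saturates as
density rises (a card only needs one visit), so reductions are estimated
on the arcsine-square-root scale, tCCI = arcsin √(CCI/100), reported in
degrees (0–90°). The per-line reduction 100 · (tCCI_pre − tCCI_post) /
tCCI_pre is scale-invariant, so the degree convention is purely
presentational.

Block-level reductions are per-line reductions averaged with weights
equal to the pre-session card count of each line (lines vary in length).
The SE of the weighted mean uses the effective-sample-size form
SE² = Σw(x−m)² / (Σw · (n′−1)) with n′ = (Σw)²/Σw², which reduces to the
ordinary SE under equal weights. Display bounds are produced from the
weighted mean pre- and post-control tCCI levels ± 1 SE: the upper
reduction bound pairs the upper pre level with the lower post level and
vice versa, and back-transforming the levels (sin² of the bound) for
reporting makes the errors asymmetric about the mean. Variation is
measured across lines, not across cards; a line whose pre-control tCCI is
zero has no defined reduction and is excluded from the block mean but
reported in the output for QA. At least two usable lines are required.

The trapping index is RTCI = 100 · possum captures / (trap-nights −
0.5 · penalized events), where a penalized event is a sprung trap or a
non-target capture; a corrected denominator ≤ 0 is an error rather than a
silent value. Bait QA reports round(100 · (assay − spec)/spec) as a
signed whole percent, rounded half away from zero with a 1e-9 guard so
exact halves (a 7.5% deviation) are stable against floating-point
representation.

## The statistical layer

The ANOVA layer is self-contained. One-way ANOVA uses the classical
between/within decomposition; the F tail is the regularized incomplete
beta function I_{d2/(d2+d1 F)}(d2/2, d1/2). The two-way trial × treatment
ANOVA is fitted by least squares on drop-first dummy codings and uses
Type-II sums of squares — each main effect is the residual-sum-of-squares
improvement over the additive model with that effect dropped, and the
interaction is the further improvement of the full cell-means model.
Type-II is the conventional default for factorial designs without an
effect ordering and reduces to the classical decomposition when the
design is balanced. With the interaction included the error degrees of
freedom are N − (number of non-empty cells); an empty cell with an
interaction requested is an error. Zero error variance with non-zero
effect variance is reported as F = ∞, p = 0 with a degeneracy flag and a
warning, never silently.

Fisher's LSD is the set of unadjusted pairwise t tests on the pooled
error variance (with two groups it is exactly the pooled two-sample
t test). Tukey's HSD uses the Tukey–Kramer statistic
q = |diff| / √(MSE/2 · (1/n_a + 1/n_b)) referred to the studentized-range
distribution, whose CDF is computed by numeric quadrature of the scale
mixture P(Q ≤ q) = ∫ f_s(s) · k∫ φ(z)[Φ(z) − Φ(z − qs)]^{k−1} dz ds with
s = √(χ²_ν/ν); this supports arbitrary (k, ν) and reproduces table
values (q_{0.05;3,6} = 4.339) to three significant figures. Critical
values are obtained by bracketing the tail function with Brent's method.
The significance threshold defaults to 0.05 and is configurable.

## Trackwork

Coordinates are planar metres throughout; longitude/latitude appear only
at the I/O boundary via a local equirectangular projection (x =
Δlon · cos lat₀ · 111320, y = Δlat · 110540), invertible and accurate to
well under a metre at single-block extents (< 10 km). Point-to-track
distance is the minimum Euclidean distance to the track polyline
(delegated to shapely; an independent dense-sampling oracle in the tests
bounds the agreement at 2 cm). Plots are matched to tracks by declared
line id with a nearest-track fallback that is flagged in the per-event
table.

Per-line timing treats the elapsed time between the first and last plot
waypoint as (n − 1) inter-plot intervals, matching the field definition
of "time to bait a plot and move to the next"; line speed divides the
path length through consecutive plots by the same elapsed time. Grouped
summaries report means ± SEs over lines, and the combined row is the
line-count-weighted mean of the group means — with groups partitioning
lines this equals the grand per-line mean. Note the deliberate
non-reconciliation: a constant 1.67 min per 20 m plot implies 0.72 km/h,
while observed line speeds average higher because inter-plot intervals
and line-level speeds are different statistics; both are computed and
reported separately.

Layout arithmetic: baited-area fraction 100 · πr²/(spacing · FPS)
(clusters must not overlap, r < spacing/2) and realized application rate
(mass/1000) · 10000/(spacing · FPS) kg/ha.

## The synthetic operation generator

The generator emulates the statistical structure the analysis assumes,
not animal behaviour. Blocks are rectangles: with area A and flight-path
spacing FPS, the builder uses n = round(√A/FPS) parallel lines, width
exactly n · FPS and length A/width, so strips tile the block and total
line length is exactly A/FPS (100 ha at 100 m → 10 km of line). Real
block shapes enter the analysis only through line length per hectare.
Flights traverse lines serpentine-fashion at 110 km/h with fixes every
2 s and isotropic Gaussian jitter; canopy-induced autocorrelated GPS
error is not modelled.

Populations have Poisson(density · area) animals per species with
activity centres uniform over the block expanded by the home-range
radius (so edge devices see a slightly diluted but ratio-preserving
density). Control kills each animal independently with its species'
probability; the input population is never mutated.

Detection at a card works through the local density D — alive animals
with centres within the home-range radius (default 60 m, within the
known attraction distance of prefeed lines), per neighbourhood area, in
animals/ha. Two per-night interference models:

* hazard: p = 1 − exp(−θD), θ default 0.25 ha/animal so that typical
  densities (~2–8/ha) give near-saturated six-night sessions like real
  pre-control surveys;
* transform_linear: p = sin²(min(cD, π/2)), a constructed model whose
  arcsine transform is proportional to D below the ceiling, used to
  validate the reduction estimator against a known truth.

A card is interfered over the session if interfered on any night,
independently per species. Trap surveys (8 lines × 10 traps × 3 nights by
default, lines placed between card lines) give each still-free possum in
range an independent capture chance per night, remove captured animals
for the remainder of the survey, and generate non-target/sprung events at
0.005 per trap-night (well under 1% of records), with capture taking
precedence. Ground baiting lays plots every 20 m of arc length along
each track, drops one contiguous segment of relative length
skip_fraction (waterlogged ground), perturbs waypoints with 5 m GPS
noise, and accumulates lognormal per-plot times (default mean 1.67 min,
sd 0.5 — positive and right-skewed; only the mean and SE are known from
timing tables).

What passing tests on these data do not show: real movement, bait
consumption kinetics, behavioural aggregation along strips, or
terrain-driven heterogeneity. The generator validates the estimators and
the pipeline plumbing, not the field efficacy of any bait.

## Estimator validation and its limits

The transform-linear validation scenario uses a 576-ha block (12 card
lines × 48 cards), one species at 8 animals/ha (a rat-plague-level
density), a 250 m detection neighbourhood so local counts are
well-resolved (λ ≈ 100 animals per neighbourhood), c chosen so expected
pre-control interference is ≈ 0.9 (tCCI ≈ 72°, near-saturated like real
pre-control surveys but below the transform ceiling), and single-night
sessions — OR-aggregation over nights is itself a saturating
nonlinearity, so the multi-night construction cannot be linear even in
principle.

Two structural biases remain, and the 200-replicate Monte-Carlo
experiments quantify them honestly:

* Moderate kill (47%): the sin² link is quadratic near zero, so Poisson
  discreteness of local counts inflates E[p] by a factor (1 + 1/λ),
  giving an O(1/λ) downward bias in the estimated reduction — about
  −0.4 to −0.5 points at λ ≈ 100.
* High kills (93–95%): post-control interference is ~0.5%, so with any
  field-realistic number of cards most lines record zero interfered
  cards; the per-line index truncates at zero and the block reduction
  compresses toward 100%, a bias of about +2.5 to +3 points. This is
  intrinsic to index-based reduction estimation: whenever the
  pre-control level is below saturation, the post level under a 95% kill
  is at most sin²(0.05 · π/2) ≈ 0.006, and E[arcsin √p̂] ≪ arcsin √p once
  n·p ≪ 1.

Both biases are small in absolute terms (the estimator lands within
~3 points of truth) but are real, systematic, and larger than the
Monte-Carlo standard error of the replicate mean, so the strict
recovery checks in `tests/test_acceptance.py` report them as failures by
design rather than hiding them behind a widened tolerance. The same
mechanism explains why near-complete kills are reported as 96–100%
reductions in saturated field surveys. The hazard-mode companion
property — raw-CCI change badly understating a 95% kill when θD ≥ 5 —
is asserted in the same file and holds.

## Cost model

Costs decompose per hectare into bait (rate × price), flying
(10000/FPS metres of line per hectare at 110 km/h, plus a 10% reload
overhead, times the helicopter rate, one sortie per sowing pass) and
labour (day rate divided by the daily coverage speed · hours · FPS/10).
The aerial benchmark uses 2 + 2 kg/ha at 180 m spacing and two sorties;
the hybrid method costs aerial prefeed at the 100 m ground-operation
spacing plus a toxic labour pass; the all-ground baseline replaces the
prefeed sortie with a second labour pass at the same speed; the
bait-station variant adds amortized station hardware
(unit cost × stations/ha, default 5/ha from the 20 m × 100 m grid) and
one removal pass to both arms it compares. Components are additive,
totals are homogeneous of degree one in prices, and ground costs are
strictly decreasing in speed and hours — these structural properties,
the coverage arithmetic (70 ha/person-day at 1 km/h × 7 h; 8 and 16
crew-days for 5000 and 10 000 ha at 0.88 km/h with 10 staff,
nearest-day rounding), and the direction of the bait-station effect are
the tested content. Dollar levels are placeholders. Mobilization,
positioning, consenting and management costs are excluded by
construction, which is why small blocks (1000 ha) complete in fewer
model days (1.6) than a field campaign would schedule.

## Numerical choices

Quadrature tolerances are scipy defaults with the studentized-range
outer integral split at 1 + 12/√ν to capture the χ density mass;
critical-value bracketing uses [1e-10, 1e8] for F and [1e-3, 200] for q.
Degenerate inputs (zero variances, empty lines, single values) raise or
flag explicitly. All simulation randomness flows through
numpy SeedSequence spawning, so identical (config, seed) pairs give
byte-identical outputs and no two pipeline stages share a stream.
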