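# Methods

This note documents the models behind `xylokin`, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical choices that matter when reading the outputs.

## Data model and time axis

A census record is one tree × sampling day × radial file with integer
counts of cambial, enlarging, wall-thickening and mature cells. Counting
along three radial files and averaging them is the standard protocol;
all downstream computation therefore runs on fractional per-tree means.
Time is the *season day*: days since January 1 of the season's start
year, extended past 365 so that a season observed from February to the
following March lives on one monotone axis (roughly days 60–430).

## Seasonal smoothing

Each treatment group × phase is fitted independently as

y_ij = f(t_ij) + b_i + ε_ij,  b_i ~ N(0, σ_b²),  ε_ij ~ N(0, σ²),

where f is a penalized cubic regression spline and b_i a random
intercept for tree i. The fit uses the ridge representation of the
mixed model: B-spline coefficients carry an order-2 difference penalty
λ_s, tree dummies a ridge penalty λ_t (which plays σ²/σ_b²), and both
weights are selected by generalized cross-validation, minimized on a
coarse log-grid and polished with Nelder–Mead. The response is Gaussian:
averaging three files makes counts continuous, and no count family is
forced by the data at these magnitudes (family is a config field and
only `gaussian` is implemented).

Defaults: `basis_dim` = 10 basis functions per curve, penalty order 2,
95% pointwise Wald bands from the posterior covariance of the penalized
fit, population prediction at the mean tree effect, daily prediction
grid. With an order-2 penalty the infinite-smoothing limit is the
least-squares straight line (the penalty null space), which collapses to
the group mean for trend-free data.

Negative fitted values are clipped to zero only in reports and in the
kinetics inversion, never inside the optimizer, where clipping would
bias the standard errors. Two groups are declared different wherever
their pointwise bands are disjoint; window endpoints are refined by
linear interpolation of the band gap between grid points. Pointwise
(not simultaneous) bands are used deliberately — the comparison rule is
defined on them — so the windows carry no family-wise error control.

Degenerate inputs: a constant response yields an exact flat fit (zero
residuals put no pressure on either penalty); fewer than
`max(6, basis_dim)` distinct predictor values raises an
insufficient-data error; a single tree drops the random-intercept block.

## Kinetics inversion

A cell observed in a later phase has passed through the earlier ones, so
the fitted means stack into cumulative entry curves C_E = Ê + L̂ + M̂,
C_L = L̂ + M̂, C_M = M̂. Each curve is clipped at zero and monotonized
by running maximum — running maximum rather than isotonic regression
because it preserves the crossing times of the increasing envelope and
never moves a crossing earlier. Cell i's entrance date into a phase is
the first time its cumulative curve crosses level i, located by linear
interpolation between grid points (with a daily grid the interpolation
error is negligible). Cells are integer crossing levels; a fractional
final level is dropped — a cell either forms or it does not. Cells whose
curve starts at or above level i get the grid start (left-censoring);
cells never reaching a level get NaN, which propagates into durations.

Durations are d_E = t_thick − t_enl and d_T = t_mature − t_thick. When a
group-mean tracheidogram is attached, cell i is matched to the i-th
tracheid of the group profile (resampled by formation quantile to the
recovered cell count) and r_enl = LD/d_E, r_wall = CWT/d_T in µm/day.
Kinetics are computed on group-average curves, not per tree.

Rates are centered finite differences of the monotonized cumulative
curves, floored at zero. The cambial production rate rC is the
derivative of C_E plus the net growth of the cambial pool above its
season-start size — cells produced are cells exported to enlargement
plus pool growth. This is a documented operational choice (`rc_mode`
can reduce it to plain dC_E/dt); a per-cell cambial residence time is
*not* computed, because there is no operational definition of when an
uncommitted derivative stops being cambial.

The inversion can also run *fit-free*, straight from observed counts
(`invert_observed_counts`), which is how it is validated against
simulator ground truth without conflating smoothing bias with inversion
error. Census counts are interval-censored — a count increment observed
at day t happened somewhere since the previous visit — so the fit-free
path attributes, by default, the count at t to t − step/2. This midpoint
correction centers the recovery error: with a sampling interval Δ and at
most one entry per interval, every recovered entrance date is within Δ/2
of truth, whereas the uncorrected convention is biased late by up to Δ.
A conservation diagnostic (max |C_E − C_L − clipped Ê| over the grid) is
reported with every pipeline run; it is exactly zero wherever no
clipping or monotonization fired.

## Tracheidograms

Tracheid i's center sits at the summed radial diameters of the earlier
cells plus half its own; dividing by ring width gives relative positions
strictly inside (0,1), invariant under uniform scaling. Profiles are
linearly interpolated onto an even grid in (0,1] with constant
extrapolation beyond the first/last center. Group comparison reuses the
seasonal smoother with relative position as predictor and the same
band-overlap rule; per-group curves are regridded onto the common
position range before comparison. Note that band overlap applied to a
*step-like* group difference rings slightly: narrow side-lobe windows
can appear next to the dominant detection window.

Earlywood/latewood uses Mork's index — latewood iff twice the double
wall (4·CWT) is at least the lumen diameter. The classification rule in
monitoring studies is often left unstated; Mork is the field default and
is isolated in one function for substitution.

## Phenology

Onset/cessation of a phase is the first up-/last down-crossing of a
threshold on the fitted (clipped) curve, default 0.5 cells — the natural
half-cell rule; there is no community-standard numeric definition, so
the threshold is configurable. Modality is operationalized as peak
counting: local maxima with prominence at least 20% of the curve
maximum and pairwise separation of at least 60 days (so that spring and
autumn activity count as two waves but a jagged single wave does not);
two or more qualifying peaks make the curve bimodal. Both defaults are
config fields. The classification is invariant under positive rescaling
of the curve.

## The simulator

The generator emulates a three-treatment manipulation experiment on a
Mediterranean pine stand: control (41 tracheids/tree, bimodal
production), irrigation (30, bimodal), rain exclusion (26, unimodal),
five trees per group, censuses every 10 days over season days 60–430,
three radial files.

Cell i of N occupies formation quantile q = (i−0.5)/N; its enlargement
entrance is the inverse CDF of a Gaussian-mixture production season
(spring wave near day 88, sd ≈ 28 d, weight 0.8; autumn wave near day
258, sd 18 d, weight 0.2 where bimodal). Residence durations are linear
in q: enlargement 20 → 8 days across the ring (25 → 12 under
exclusion), wall deposition 40 → 80 days (control; → 60 irrigation,
→ 120 exclusion). Lumen diameter plateaus at 40 µm over the first 40%
of the ring, declining to 10 µm; wall thickness rises linearly from
2 µm to 8 µm (6 µm under exclusion). The cambial pool is a Gaussian
bump peaking at 10 cells (control) or 8 (others) in March over a ~5-cell
baseline. Per-tree totals get Gaussian dispersion with sd 3 cells
(~7–11% CV, a realistic spread for co-dominant trees of one stand);
an optional per-tree shift of the whole season defaults to zero.

Deterministic quantile placement (not Poisson arrivals) is the default
because it makes exact recovery tests possible; observation noise, when
enabled, is independent per-file detection (thinning), which keeps
counts integer and non-negative. Everything is reproducible bit-for-bit
from the config seed.

What the simulator does **not** emulate — and hence what passing
recovery tests do not establish for field data: within-tree
circumferential variability beyond iid file thinning, measurement error
in anatomy, climate-driven year-to-year variation, missed or damaged
cores, phase-classification ambiguity at the microscope, and any
dependence between a cell's timing and its dimensions beyond the shared
quantile index.

## Group-level inference

The production ANOVA is the classical between/within decomposition with
Tukey HSD adjusted pairwise p-values from the studentized range
distribution; Shapiro–Wilk (residual normality) and Levene (variance
homogeneity) p-values are attached as diagnostics and never gate the
test. Trait–duration relations use a linear mixed model with fixed
slope and a random intercept per tree, fitted by REML (standard for
variance components at five trees), Wald CI on the slope; a single tree
collapses to OLS. Random slopes are deliberately out of scope.

## Problem sizes and runtime

Validation uses the study-scale scenario throughout: 15 trees, ~40
cells/tree, 38 censuses (daily censuses, ~430, for the inversion oracle
tests), 100 replicate seasons for the ANOVA power check and 200
replicates for mixed-model slope recovery. The full test suite runs in
well under a minute on one CPU; `scripts/acceptance.py` in a few
seconds.

## Known limitations

- Kinetics inherit no uncertainty from the smoother; bands on entrance
  dates and durations would require a posterior simulation layer.
- Left-censoring at the grid start: cells that entered a phase before
  the first census get the first grid day as their entrance date.
- The Gaussian response can produce negative fitted counts near zero;
  they are clipped in reports, and a count family (Poisson/quasi) is a
  natural extension behind the `family` config field.
- Group comparison by pointwise band overlap is a descriptive rule, not
  a calibrated test; its windows should be read the way the monitoring
  literature reads them.
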