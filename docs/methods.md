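# Methods

## The problem

Visual crowding — the failure to identify a letter when neighboring
letters are close to it — is usually summarized by the *critical
spacing*: the target–flanker distance below which flankers impair
identification, by some stated criterion. Laboratories measure it in
incompatible ways: proportion correct versus flanker spacing at a fixed
letter size, size thresholds at a fixed *nominal* spacing (flanked
acuity, the clinical chart-like paradigm), or contrast thresholds
versus spacing summarized by a two-line fit. `crowdkit` implements one
generative model under which all of these are views of a single
performance surface, together with every estimator needed to analyze
real or simulated data from each paradigm.

All spatial quantities are degrees of visual angle; all logarithms are
base 10; the canonical spacing convention is center-to-center (an
edge-to-edge gap differs by exactly one letter size, and a nominal
multiple m corresponds to m × letter size). Unflanked conditions are a
reserved infinite-spacing sentinel.

## The crowding function and its fit

A crowding function is modeled as

    p(x) = g + (A − g) · F(β(x − μ)),

with `x` the log10 center-to-center spacing (or log10 letter size in
the flanked-acuity paradigm), `g` the guess rate fixed at
1/n_alternatives, `A` the asymptote (free, ≤ 1, absorbing lapses; or
fixed), `μ` the location and `β > 0` the slope per log10 unit, and `F`
the logistic (default) or standard normal CDF. Unflanked cells enter
the binomial likelihood at `A` — the spacing → ∞ limit — so isolated-
letter data anchor the asymptote.

Estimation is maximum likelihood (L-BFGS-B in a bounded box, 5
jittered restarts seeded deterministically, likelihood ties broken
toward the shallower slope). Uncertainty comes from a parametric
bootstrap (199 resamples by default, refit from the MLE), chosen over
MCMC as the default for speed and determinism; an `emcee` sampler with
flat priors over the same box is available via `fit_mcmc`. Degenerate
data are fitted anyway and flagged `unconstrained` when parameters hit
bounds, the location leaves the sampled range by more than a decade, or
all observations sit in the top or bottom tenth of the amplitude —
mirroring the practice of dropping conditions whose functions the data
do not constrain.

Joint fits share one `β` across conditions with per-condition `μ_j`
(and `A_j` when free), and report the deviance against independently
fitted slopes with its degrees of freedom — the quantitative version of
the observation that crowding functions are parallel on a log abscissa.

Critical spacing is read off a fit by converting a criterion to a raw
proportion-correct level and inverting the sigmoid in closed form.
Criterion families: `absolute` level; `proportion_of_asymptote` (level
q gives g + q(A − g)); `amplitude_fraction_drop` (A − f(A − g), with
f = 1/e the classic variant, applied to the guessing-corrected
amplitude); and `z_drop` (the guessing-corrected asymptote lowered by a
fixed probit distance). Levels at or above the fitted asymptote return
an explicit `unattainable` status rather than an extrapolated number.
A z-score normalization (probit of guessing-corrected proportions,
clamped at a documented epsilon of 1e-3) supports collapsing curves
with different asymptotes onto one template.

## The flanked-acuity landscape

The landscape predicts proportion correct over the whole
(letter size, spacing) plane from two ingredients:

1. a base psychometric function over log10 size with one shared slope
   `β`;
2. a hinged line giving that function's location as a function of
   flanker separation: below the hinge the location rises with slope
   `crowded_slope` (default −0.8) as separation shrinks; at and beyond
   it the branch is flat and equals the unflanked location exactly.
   Continuity at the hinge holds by construction.

The hinge abscissa is a named, swappable transform of (size, spacing).
The default is log10 *nominal* spacing (spacing/size), under which a
crowded slope of −1 produces exactly right-angle iso-performance
contours — the classic flanked-acuity geometry — and −0.8 slants the
crowded edge slightly. We adopt the nominal transform as the default
because it is the only choice consistent with the model's own
`hinge_location` being a critical *nominal* spacing and with the
empirically flat dependence of critical spacing on letter size: under
the nominal transform with slope −0.8, a fixed-size slice's critical
spacing scales as size^(1 − 1/0.8) = size^−0.25, i.e. ≈19% variation
over the conventional 1.5×–3× size range, whereas a hinge on absolute
spacing would make it scale as size^(−1/0.8) and vary ~2.4× over the
same range, contradicting the observed flatness. An absolute-spacing
transform (`"log_c2c"`) remains selectable for sensitivity analyses.

Calibration: `unflanked_threshold_size` is the isolated-letter size
identified at `reference_level` (default 75% correct; 79% is common in
staircase studies and is configurable), which pins the unflanked
location. The physically overlapping region (spacing < size) is out of
domain and raises an explicit error.

Derived quantities, each analyzed exactly as an experimenter would:

- **threshold_size(m, level)** — bisection along the fixed-nominal-
  spacing diagonal (relative tolerance 1e-6); equals the unflanked
  threshold for multiples beyond the hinge.
- **critical_spacing_at_size(size, criterion)** — a horizontal slice
  treated like a measured crowding function, with `floor` (level
  unattainable: letters too small) and `ceiling` (already above the
  level at the minimum non-overlapping spacing: letters too large)
  statuses.
- **valid_size_window(criterion)** — the floor and ceiling transitions
  located by bisection on log size (60 halvings after a 256-point
  scan).
- **iso_performance_contour(level, sizes)** — closed-form inversion of
  the hinged location function per size.

Setting the hinge at nominal spacing 1 removes crowding from the whole
non-overlap domain, collapsing the landscape to a single acuity
function — a useful degenerate check.

## Threshold-versus-spacing curves

The clipped-line estimator fits log10 threshold versus log10 spacing
with a sloped crowded branch and (by default) a flat wide-spacing
branch joined continuously; the hinge abscissa is the critical spacing.
The hinge is profiled on a 50-candidate grid between the 2nd and
penultimate data abscissae (which keeps both regimes populated and
avoids degenerate boundary hinges), then polished by bounded
minimization; RSS ties break toward the larger hinge (the more
conservative critical spacing). Weighting by 1/SE² engages when every
point carries a standard error; both weighted and unweighted fits are
exposed because published practice varies. Exactly flat data are
flagged `no_crowding_detected` with the hinge pinned at the smallest
spacing. Two cruder estimators are provided: threshold doubling
(log-log interpolated crossing of 2× the unflanked baseline — with a
crowded slope of −1 the doubling point sits exactly one octave inside
the hinge) and divergence by k baseline standard errors (default 2).

## Duration meta-regression

Study-level Bouma fractions (critical spacing / eccentricity) are
regressed on log10 duration, on semilog (default) or log-log axes,
with ordinary least squares, or SE-weighted least squares when every
point carries an SE. Multiple eccentricities within a study-condition
are averaged to a single point first; a-priori exclusions (outlier
studies) are applied before anything else. The iterative exclusion rule
drops 0, 1, 2, … of the shortest-duration levels (never interior
points) and keeps the fit minimizing reduced χ² = χ²/(N − 2), requiring
a strict improvement so that noise-free linear data exclude nothing.
Without per-point SEs, the score normalizes each candidate's residuals
by the no-exclusion fit's mean squared error, making it a plain
model-selection score on a fixed scale.

Known limitation: with unweighted noisy data and small N, minimizing
reduced χ² is unstable as the candidate fits approach the minimum of
three points (the statistic's variance grows as degrees of freedom
shrink), so the rule can over-exclude; with per-point SEs or a clear
short-duration elevation it behaves as intended. The exposed
`exclusion="none"` option is recommended when no upturn is visible.

## Synthetic observer

Every generator is a pure function of (parameters, seed): each cell's
responses are binomial draws with probability given by the landscape,
from a substream derived deterministically from the run seed and cell
index (adding cells never perturbs existing ones).

- Constant-stimuli designs over spacing (fixed size) or over size
  (fixed nominal spacing).
- A 3-down-1-up size staircase along the nominal-spacing diagonal
  (convergence level 0.5^(1/3) ≈ 79.4%, matching the common 79%
  size-threshold criterion), step 0.05 log10 units, terminating at 16
  reversals with the threshold taken as the mean of the last 6 reversal
  sizes; the rule (steps, up/down counts, reversal counts) is fully
  configurable, and non-convergence within a trial cap is flagged.
  With these defaults the staircase estimate agrees with the analytic
  diagonal threshold to a median |error| of ~0.04 log10 units over 100
  runs of ~100 trials.
- A constant-size letter-identification fixture in the style of the
  classic peripheral crowding experiment: 0.23° lowercase letters
  (≈14 arcmin x-height), flanker gaps of {0, 2, 5, 8, 11, 15} empty
  0.29° letter slots plus an unflanked point, 100 trials per point,
  25-alternative identification, at several eccentricities. Slot width
  and letter size are independent parameters. Acuity declines across
  eccentricity as S0(ecc) = S0_fovea(1 + ecc/E2) with S0_fovea = 0.05°
  and E2 = 1.5°, so fixed-size letters yield declining asymptotes. The
  hinge of each eccentricity's landscape is calibrated by bisection so
  that the *analytic* slice critical spacing at the analysis criterion
  (0.9 of asymptote) equals a stated generating Bouma fraction (0.4 by
  default) times the eccentricity; end-to-end recovery tests then ask
  whether fitting the simulated tables returns that fraction.
- A study-level (duration, Bouma fraction) table generator on a
  semilog line with Gaussian noise (σ = 0.02 by default) and an
  optional planted elevation of the shortest-duration prefix,
  emulating the upturn seen at very brief exposures.

## What the simulations do and do not show

The synthetic observer is an idealized stationary Bernoulli observer:
no learning, no sequential dependencies, no response bias, no
target–flanker similarity structure, and flanker effects that depend
only on separation, not direction (no radial–tangential anisotropy
within a landscape). Passing recovery tests therefore demonstrates
that the estimators are consistent and correctly coupled to the
generative model at realistic trial counts — not that real observers
satisfy the model. Conversely, the recovery experiments do expose real
analysis-pipeline biases: fitting a plain sigmoid to a landscape slice
whose true shape is a clipped sigmoid, with the sparse constant-size
spacing grid and a conservative 0.9-of-asymptote criterion, inflates
recovered Bouma fractions by ~7% at 3° up to ~23% at 7° eccentricity
(where declining asymptotes leave few informative points) even with
noiseless data — the same inflation expected when such criteria are
applied to classic constant-size datasets.

## Numerical choices and problem sizes

Optimizer boxes: μ within the sampled abscissa range ±3 decades, β in
[0.05, 50] per decade, A in (g + 1e-4, 1]. Likelihood probabilities
are clipped at 1e-9 for stability. Bootstrap intervals are percentile
intervals; 199 resamples by default. Simulation scales used by the test
suite — 200 replicates for interval-calibration checks (coverage
asserted in the 90–98% band), 100 seeded runs for staircase/hinge
recovery medians, 100 trials per point throughout — were chosen as the
standard desk scale for these designs; empirical coverage at these
scales is 94% (shared slope) and 95.5% (single-fit location).

## Reproducibility

Seeds are explicit everywhere (models take a `seed`, generators require
one); identical seeds give byte-identical tables and fits. The CLI logs
the seed and a hash of the effective configuration with every run.
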