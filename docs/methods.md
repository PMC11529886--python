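# Methods note

This note records the statistical procedures, the synthetic-data model, the
numerical choices, and the limits of what a green test establishes.

## Conventions

All public angles are degrees, counterclockwise positive viewed from above,
wrapped to the half-open interval (−180, 180]. A clockwise-rotating stimulus
therefore has *negative* azimuth increments. Circular variance is defined as
`V = 1 − R` (not the angular variance `2(1 − R)`), so it lies on [0, 1] and
pairs directly with the vector strength `R`. The mean direction is reported
as undefined when `R < 1e−12` (e.g. exactly antipodal samples); downstream
code must handle the undefined case explicitly — undefined means are dropped
and logged, never zeroed.

## Descriptive statistics and the confidence interval

`circ_mean_R` is the plain resultant-vector computation. The 95% CI for the
mean direction uses the large-sample circular-dispersion form (Fisher 1993):
`δ̂ = (1 − ρ̂₂)/(2R̄²)` with `ρ̂₂` the mean cosine of twice the deviations
from the sample mean, and half-width `asin(z₀.₉₇₅ √(δ̂/n))`. The CI is
reported as undefined when the circular variance exceeds 0.8 (too dispersed
for a meaningful interval — the same rule used for reporting below) or when
the arcsine argument leaves [−1, 1]. Monte-Carlo coverage at κ = 4, n = 50
is 95% ± 2% (tested). Which exact CI formula the original MATLAB toolchain
used is unknowable from the outside; only the variance-0.8 rule is treated
as normative, so half-widths on real data may differ from previously
published figures.

## Hypothesis tests

* **Rayleigh**: `z = nR²`, p from the standard small-sample-corrected
  exponential approximation `exp(√(1+4n+4(n²−Rₙ²)) − (1+2n))`. Requires
  n ≥ 4; smaller samples are refused rather than silently approximated.
* **Watson–Williams** (two groups): F statistic with the `1 + 3/(8κ̂)`
  correction, κ̂ estimated from the pooled within-group resultant. The test
  assumes reasonably concentrated von Mises samples; below a pooled mean
  resultant of 0.45 a warning (not an error) is emitted, because heading
  data are routinely analyzed in this regime anyway.
* **Watson U²** (two samples): ECDF-difference formulation, invariant to a
  joint rotation of both samples; ties processed block-wise (midrank
  equivalent). The p-value is by seeded random permutation of group labels
  (default 10,000; add-one estimator, so p ∈ (0, 1]). A large-sample
  approximation `p = 2exp(−2π²U²)` is available but not the default: the
  table-interpolation dialect of legacy toolboxes is unspecified, while
  permutation is exact in distribution.
* **Benjamini–Hochberg**: classic step-up with monotonicity enforcement
  (delegated to statsmodels), input order preserved.

## von Mises regression (Fisher–Lee)

Responses follow a von Mises distribution with common concentration κ and
mean direction `μᵢ = β₀ + 2·atan(xᵢᵀβ)` (tan-half-angle link). The likelihood
is maximized by BFGS over (β₀, β, log κ) from a closed-form location-only
start, with two jittered restarts and a Nelder–Mead polish when BFGS stops on
precision loss; the `converged` flag is honest. Per-covariate p-values are
likelihood-ratio tests against the model refit without that covariate
(χ², 1 df). An identically-zero covariate column is a legal degenerate input
(coefficient 0, p = 1); genuinely collinear designs are rejected. The
intercept's 95% CI comes from a central-difference observed-information
Hessian. Measured calibration: LRT type-I error 5% ± 2% (500 null
replicates), intercept CI coverage ≥ 90% under the model. No claim is made
of estimator-level equivalence with any legacy R implementation; agreement
is at the level of sign and significance of strong effects.

The all-orders robustness sweep refits the model adding factors sequentially
in every permutation of the covariates and reports each factor's min/max
sequential-LRT p. With likelihood-ratio tests the simultaneous (drop-one)
p-values are order-free; the sweep exists to demonstrate that conclusions do
not depend on factor ordering.

### Response coding for heading-maintenance GLMs

The GLM response defaults to the *signed* heading difference. For questions
about heading *maintenance*, a factor can disrupt maintenance without
shifting the mean direction — e.g. flies redrawing arbitrary new headings
after a large LED move produce near-uniform signed differences, which a
location model detects in only ~half of cohorts. The documented switch
`glm_response="absolute"` regresses |difference| instead, which is sensitive
to exactly this dispersion-type effect (measured detection ~100% on
reset-policy cohorts, ~5% false-positive rate on static-LED cohorts) and is
the coding used for the maintenance-detection property test.

## Segmentation and exclusions

Epoch intervals are half-open `[start, end)` at frame resolution, so every
frame belongs to at most one segment and binned segmentation is a partition.
Epochs with no stimuli (dark tether checks, rest periods out of the arena)
and intertrial epochs are never analyzed for heading. Stopped frames are
excluded from heading samples by default — a stopped tethered fly's body
angle is not an orientation choice — but the switch is exposed
(`include_stopped`) because original practice is unrecorded. Stop episodes
are maximal runs of stopped frames; an episode spanning a segment boundary
counts once in each flight period it touches, matching a per-flight-period
exclusion rule. Exclusions: more than 2 stop episodes per flight period, or
vector strength strictly below 0.2 (a segment at exactly 0.2 is retained).
Exclusion never alters retained flies' statistics (tested:
filter-then-compute equals compute-then-filter).

## The reshuffling null

The observed statistic is the mean over flies of |wrap(second − first)| of
per-period mean headings; the null shuffles the second-period list without
replacement (default 10,000 seeded iterations); p is the raw strict-less
proportion, with no continuity correction, so perfectly maintained cohorts
report p = 0.0 exactly. Whether the original procedure used arena-frame or
stimulus-relative means is ambiguous ("absolute mean headings"); the frame
is a parameter (`frame=`) and both are first-class — arena is nothing but
stimulus-relative under a static stimulus.

## Time-compensation hypotheses

For a stimulus rotated `T` degrees total, the three predictions for the
stimulus-relative heading change are: 0° (track the stimulus), `−T` for
clockwise / `+T` for counterclockwise rotation (time-compensated compass),
or uniform (new heading). Each point hypothesis is scored by the mean cosine
of deviations from its target (a V-style concentration in [−1, 1]); the
uniform hypothesis by the Rayleigh p. Labeling rule: a point hypothesis wins
when its score beats the other's by ≥ 0.1 *and* Rayleigh rejects uniformity
at α = 0.05; a Rayleigh non-rejection labels `new_heading`; a rejection
without a clear score winner abstains; n < 8 refuses a label (scores still
reported). The 0.1 margin is configurable; it was chosen a priori as a
visually meaningful concentration gap, and cohorts of n = 40 at κ = 4
generated under each hypothesis are labeled correctly in ≥ 90% of replicates
(tested end-to-end through the generator and pipeline).

## The synthetic generator

The generator emulates 25 Hz heading traces of flies holding von
Mises-concentrated headings around a policy-defined reference:

* `maintain_relative` locks to the weight-dominant stimulus azimuth and
  tracks it (sun orientation). Cue weights default to UV 2 : green 1,
  encoding the observed UV preference with paired cues; exact weight ties
  resolve to green (arbitrary, documented).
* `reset_on_move` redraws a fresh uniform offset when the stimulus jumps by
  ≥ 30° (default threshold) — so 5° gradual steps never trigger a reset and
  90°/180° jumps always do, reproducing the qualitative dissociation between
  gradual and large cue movements.
* `real_world_keeper` holds a fixed arena direction regardless of the cue.
* `time_compensated` drifts its stimulus-relative heading at 15° h⁻¹
  against the stimulus rotation sign, implemented directly in the stimulus
  frame so that a clockwise 6 h schedule yields exactly the −90° signature
  the compass hypothesis predicts.
* `uniform_random` redraws an offset every flight epoch (no memory).

Per-frame noise is an AR(1) latent Gaussian pushed through the Gaussian
copula onto the von Mises quantile function, giving an *exactly* von Mises
stationary marginal with temporal persistence. Defaults: κ = 2.9 (stationary
R ≈ 0.8, inside the 0.64–0.87 range of reported population vector
strengths) and AR coefficient 0.8 (≈ 0.2 s relaxation at 25 Hz — smooth at
the frame scale without freezing the trace). Both knobs have no counterpart
in published data; no claim is made that they reproduce real within-flight
dynamics. Dark epochs emit rapid rotation at 120° s⁻¹ (tether-check
behavior; never analyzed downstream, so only its presence matters). Stops
arrive as a Poisson process (default 0.05 min⁻¹, 5 s each, keeping expected
stops per 5 min period well under the exclusion threshold). Cohort child
seeds derive deterministically from one master seed; identical seeds give
byte-identical outputs.

What a green test does **not** establish: real flies show drift,
satiation/fatigue trends, wingbeat-coupled oscillations, heading-dependent
stop probabilities and idiosyncratic cue weightings, none of which the
generator models. Green tests establish that the *statistics* behave
correctly on data whose ground truth is known, not that the generator is a
behavioral model of Drosophila.

## Numerical and degenerate-input choices

* Wrapping maps to (−180, 180] with `wrap(−180) = 180`.
* κ from R by the standard piecewise series refined with a bracketed root
  solve of `I₁(κ)/I₀(κ) = R`; R below 1e−9 gives κ = 0, above 1 − 1e−9 gives
  κ = ∞.
* Permutation p-values use add-one estimators except the reshuffle test,
  which reports the raw proportion by design (see above).
* All stochastic procedures take explicit seeds; per-experiment randomness
  flows from one master seed recorded in the output manifest.

## Known limitations

* The Watson–Williams F approximation degrades for widely dispersed groups;
  the implementation warns but does not refuse, matching field practice.
* The Fisher–Lee link compresses mean-direction effects to (β₀ − 180°,
  β₀ + 180°); covariate configurations implying shifts near ±180° sit at
  the link's asymptote and converge slowly.
* Heading traces are assumed body-axis-resolved upstream; 180° tracking
  flips are out of scope.
* No wrapped-Cauchy models, multivariate circular tests, or Bayesian
  estimation.
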