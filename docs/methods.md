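# Methods

## Setting and estimand

One row per subject: baseline covariates X, first-event time `w` with type
`delta_w` (1 = treatment initiation, 2 = recovery without treatment, 0 =
censored), and observed recovery time/status `(r, delta_r)`.  The process is an
irreversible illness–death model: starting state → treatment → recovery, with
no return transitions, no competing terminal events, and no time-varying
covariates.  The estimand is the marginal recovery probability
P(Rᵍ < ℓ) under the strategy "treat at t_g if not yet recovered", including
t_g = ∞ (never treat within the study window).  Identification requires
consistency, positivity, conditional exchangeability given X, and
conditionally independent censoring; none of these are testable from the data
and the package only provides an *empirical* positivity diagnostic
(`check_positivity`: at-risk and initiator counts per strategy window, overall
and per covariate quartile).

## Estimators

**Multistate g-computation (primary).**  Two proportional-hazards transition
models are fitted: untreated recovery (1→3) on the study clock, and
post-treatment recovery (2→3) on the clock reset at initiation.  The delay
enters the 2→3 model either linearly through a configurable transform
(continuous variant; identity by default, log/log1p available for
applications whose delay effect is curved) or as a baseline stratum
(categorical variant).  Curves are computed per subject from the Breslow step
baselines — survival is taken as exp(−Λ) as in the estimator's definition; a
product-limit form is available behind `survival_form="product-limit"` and is
what makes the no-covariate never-treat curve coincide exactly with a
Kaplan–Meier that censors treatment — and averaged over the sample's empirical
covariate distribution.  Confidence intervals are subject-level pairs
bootstrap percentile intervals (B = 500 by default); replicates that fail to
converge are redrawn, erroring out beyond 10% failures.

**Clone–censor–reweight comparator.**  Each subject is cloned into every
strategy compatible with their time-zero data (subjects treated at exactly 0
belong only to arms whose window contains 0).  Clones are censored at the
first deviation: initiation before the window, or reaching the window's end
`[a, b)` still untreated and at risk.  Adherence weights come from a single
time-to-treatment Cox model on the study clock; a point mass of initiation at
time 0 is simply a Breslow jump at 0, so one proportional coefficient governs
all decision times (a separate logistic time-0 model is available via
`variant="logistic"` in `fit_treatment_model`).  A clone's weight at time s is
the inverse of P(still adherent at s | X): the probability of remaining
untreated through every decision time before the window, times — once the
clone initiates — the probability of initiating inside the window.  Weights
are time-varying until the window closes (the initiation itself, for point
strategies) and frozen afterwards.  Probabilities use the proper survival form
exp(−ΔΛ·e^{βx}) by default; `hazard_form="discrete"` switches to product-limit
factors (1 − ΔΛ·e^{βx}), which can produce non-finite weights when a discrete
hazard reaches 1.  When any weight is non-finite, all weights above the 97.5th
percentile of the finite weights are set to that percentile (`always_trim`
forces this).  Outcomes per arm are estimated by a weighted Kaplan–Meier
(categorical variant) or a single weighted Cox model on the stacked clones
with the baseline stratified by treatment status, the clock reset at
initiation, and the assigned delay (the window's target value) entering
linearly in the treated stratum (continuous variant).

**Cox engine.**  Transition models are fitted by an in-package vectorized
Newton solver for the stratified, case-weighted partial likelihood with Efron
(default) or Breslow tie handling, delayed entry, convergence tolerance 1e−9
on the coefficient step, step-halving for monotonicity, and tie-consistent
baseline increments (Breslow form at untied event times).  Rows are at risk on
`[entry, exit]` with entry inclusive so that event masses at time 0 see the
full cohort.  Agreement with an independent implementation (lifelines) is part
of the test suite, to 1e−6 on coefficients and standard errors.  At Table-1
resolution (two decimals) the Efron/Breslow choice is immaterial; it matters
only in the heavily tied treatment frames.

## Synthetic scenarios

The generator emulates an observational cohort of 2500 initially untreated
subjects with one standard-normal confounder X affecting treatment timing and
recovery in opposite directions:

| parameter | value | meaning |
|---|---|---|
| λ₁₃ | 0.4·exp(−0.25X) | untreated recovery hazard (per study-time unit) |
| P(T=0) | 1−exp(−0.05·exp(0.25X)) | treatment mass at baseline (~4.9% at X=0) |
| discrete hazard | 0.1·exp(0.25X) at s ∈ {0.25, 0.5, 0.75, 1} | later initiation opportunities |
| λ₂₃ | 0.8·exp(−0.15X−0.25T) | post-treatment recovery hazard, reset clock |
| censoring | 0.2·exp(0.1X) | random right censoring |
| horizon | 1.5 | evaluation time ℓ |

Scenario 2 replaces the discrete treatment law with an exponential hazard
0.4·exp(0.25X) (continuous times); scenario 3 replaces the post-treatment law
with a Weibull of shape α_T = 0.75 + 0.5T/1.5 and hazard
0.8·α_T(s−T)^{α_T−1}·exp(−0.15X), breaking delay-proportionality; scenario 4
replaces the constant confounder effect on initiation with
β₁₂(s) = 6(s−0.5)² − 1 at every decision time including the baseline mass
(β₁₂(0) = 0.5), breaking the weight model.  The baseline-mass expression is
deliberately the *hazard-style* reading (complement of the exponent); a
`mass0_literal` switch generates the alternative reading, under which ~95% of
subjects would start treated and the whole precision profile of the study
(e.g. the delay-stratified variant's inflated RMSE at t_g = 0) would be
impossible.  Ties between the continuous recovery time and a discrete
treatment time have probability zero; numerically, recovery wins.

What the generator does **not** emulate: time-varying confounding, competing
terminal events, covariate-dependent administrative censoring, measurement
error, or multi-dimensional confounders (the application-shaped synthetic
cohort in the test suite exercises six covariates, but the study scenarios use
one).  Passing tests therefore certify the estimators under exactly these
generative assumptions, not robustness beyond them.

**Truth oracle.**  P(Rᵍ < ℓ) is computed by plugging the *true* conditional
hazards into the identification formula and integrating over the
standard-normal confounder with a 128-node Gauss–Hermite rule; an adaptive
quadrature (absolute tolerance 1e−10 on [−9, 9]) serves as an independent
cross-check and agrees to below 1e−8, negligible against Monte-Carlo noise.
The oracle is additionally validated against forced-strategy simulation
(10⁵ subjects made to follow each strategy) within three binomial standard
errors.

## Replicated study and problem sizes

The ADEMP harness runs replications with seeds `base_seed + r` so any cell can
be recomputed in isolation, computes truth once per (scenario, strategy),
records bias, RMSE and the Monte-Carlo SE of the bias at the horizon (the
identity RMSE² = SD² + bias² holds by construction and is regression-tested),
and tracks per-replication flags (non-finite weights, trimming, method
failures — a failed method yields an NA cell, never an aborted study).
`scripts/acceptance.py` uses 200 replications of n = 2500 per scenario; the
test suite's session fixtures use 200 (scenarios 1 and 2) and 150
(scenarios 3 and 4) replications, sizes at which the Monte-Carlo SE of a bias
estimate is ≈ RMSE/√reps ≈ 0.002–0.003, comfortably inside the ±0.01 bands
being checked.  The bootstrap coverage check is scaled down (20 outer
replications × B = 60 at n = 800) and asserts only a loose binomial bound.

## Numerical and design choices

* **Follow-up used in fitting:** all generated follow-up enters the fits; no
  administrative censoring is imposed by the generator or the estimators.
  Coefficients of correctly-specified models are unaffected; for
  *misspecified* models (scenarios 3–4) the fitting window genuinely changes
  the bias, so `truncate_follow_up` is provided for sensitivity analysis.
  Under horizon truncation the scenario-3 continuous-variant biases at
  t_g = 1 largely vanish (the misfit concentrates where it is evaluated).
* **Evaluation grid:** by default the union of {0, horizon}, the 1→3 jump
  times and the delay-shifted 2→3 jump times, so curves are exact step
  functions of the Breslow baselines; any user grid is accepted.
* **Baseline extrapolation:** flat beyond the last event time, with a warning
  in the public prediction API.
* **Window conventions:** grace windows are `[t_g − h, t_g + h) ∩ [0, ∞)`;
  initiating exactly at the window's end is a deviation.  Adherence
  probabilities are decision-time right-inclusive ("untreated through s"
  includes a decision at s).  The weighted-KM arm under grace estimates the
  window strategy ("start between a and b") — a slightly different estimand
  from the point rule it is compared against; the weighted-Cox variant keeps
  the point estimand by construction.
* **Weight trimming percentile** is computed over the finite end-of-follow-up
  weights pooled across arms (non-finite values cannot define a percentile).
* **Degenerate inputs:** strategies beyond the horizon are rejected; empty
  delay strata raise an estimation error naming the stratum (surfacing the
  positivity failure); event-free strata get a baseline identically zero and
  a warning; datasets with a constant covariate are rejected by the fitter.

## Known limitations

Baseline confounding only (no time-varying confounders or treatment-confounder
feedback); no competing terminal events; proportional-hazards transition
models with time-constant coefficients (non-proportionality exists only in the
generators, to study misspecification); the CCR weight construction follows
one defensible convention among several — time-varying up to the window end,
single pooled treatment model — and misspecified-model bias values are
sensitive to such conventions in ways correctly-specified results are not.
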