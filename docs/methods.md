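# Methods

## The two-stage model

A detection trial is a single pass of a body-size proxy through a
camera's field of view at a known distance, scored 1 if the camera
triggered and 0 otherwise. Trials are modelled as independent Bernoulli
outcomes throughout; there is no random-effect or autocorrelation
structure, which matches a protocol in which trials are separated in time
and conducted on a standardized plot.

**Stage 1** fits the marginal distance response. Three monotone
detection-function families are supported — exponential
`exp(-y/α)`, half-normal `exp(-y²/2α²)` and hazard-rate
`1 - exp(-(y/α)^(-γ))` — with `α` a scale in metres and `γ` a
dimensionless hazard shape. The hazard value at `y = 0` is taken as its
`y → 0+` limit, 1. Each family may be multiplied by a logistic-in-distance
term

```
w(y) = 1 / (1 + exp(-(y - loc) · steep))
```

with `loc` (metres) the midpoint and `steep` (per metre) the slope of a
near-camera dip: an animal directly beneath the lens can pass under the
PIR detection cone. The logistic acts multiplicatively on the base
function, which keeps `p_mix(y) ≤ p_base(y)` pointwise and adds exactly
two parameters, so the parameter counts are K = 1 (exponential,
half-normal), 2 (hazard), and +2 with the mixture. Alternative
published parameterizations exist (e.g. the logistic as a mixing weight);
the multiplicative form was chosen because it preserves monotone
dominance and the K = 3/K = 4 bookkeeping of the standard selection
table.

Candidates are ranked by AIC = 2K − 2LL (not AICc; at thousands of
trials the small-sample correction is negligible and plain AIC matches
the selection-table convention). ΔAIC is reported against the minimum;
ties keep input order.

**Stage 2** regresses outcomes on deployment covariates with a
logit-link binomial GLM. The selected stage-1 model enters as a single
covariate — the fitted probability `p̂(y)` at each trial's distance, on
the raw [0, 1] scale. The probability scale (rather than its logit or the
linear predictor) keeps the covariate unit-range, which is consistent
with coefficients of order 5–7 on this term in fitted models. Stage-1
parameters are frozen at their MLEs; stage-2 standard errors do not
propagate stage-1 uncertainty. Categorical covariates use treatment
contrasts with the largest proxy (`large_ungulate`) and the HP2X camera
as baselines; interactions are elementwise products of contrast columns.
Because the vertical camera angle is strongly rank-correlated with lens
height and aiming distance (both follow from how the camera is aimed),
the package defines two model suites — `ANGLE_SUITE_TERMS` and
`HEIGHT_SUITE_TERMS` — rather than one model containing all three;
`collinearity_check` (Spearman, midrank ties) is the supporting
diagnostic.

## Fitting and numerical choices

* Stage-1 likelihoods are maximized over log-transformed positive
  parameters with a deterministic multi-start grid over the scale,
  α ∈ {2, 5, 10, 15, 25} m (γ, `loc`, `steep` start at 2, 1, 2). Each
  start runs Nelder–Mead (`xatol` 1e-6, `fatol` 1e-9), and the best
  optimum gets a BFGS polish (`gtol` 1e-5). The multi-start guards
  against the local maxima that mixture likelihoods exhibit.
* Detection probabilities are clamped to [1e-12, 1 − 1e-12] inside the
  Bernoulli likelihood; the hazard family reaches p → 1 at y → 0, where
  log(1 − p) would otherwise diverge.
* All-detected or all-missed inputs push the scale to a boundary; the
  fit is returned with `converged_ = False` and a boundary diagnostic
  instead of a spurious interior optimum.
* Stage-2 fitting is IRLS via statsmodels' binomial GLM. Rank-deficient
  designs raise an error naming the collinear columns (QR with
  pivoting); complete separation is detected from saturated fitted
  probabilities and flagged on the result, not raised.
* Backwards stepwise selection removes, one at a time, the
  least-significant eligible term with p > α (default α = 0.05,
  two-sided Wald). Multi-column blocks — categorical contrasts and
  interactions involving them — are tested jointly with a Wald
  chi-square and removed as a block, so a factor is kept or dropped as a
  whole even when individual contrasts differ in significance. A main
  effect is ineligible while any interaction containing it remains
  (marginality).
* Marginal effects use the average-of-predictions convention: the focal
  covariate is set counterfactually to each grid value in every observed
  row and predictions are averaged; standard errors come from the delta
  method on the coefficient covariance. Setting the trial distance
  recomputes the `distance_model` covariate through stage 1.
* ROC curves use all distinct thresholds; AUC is the trapezoidal area,
  which equals the Mann–Whitney probability with ties counted one half.
* The first-detection position density is an isotropic Gaussian KDE
  (default bandwidth 1.5 m — the kernel family is this package's choice)
  on a 0.1 m grid over the staked plot frame, x ∈ [−8, 8] m by
  y ∈ [0, 15] m.

## The simulator

The simulator emulates the balanced factorial experiment: 3 body-size
proxies × 2 camera models × 3 lens heights (86/116/146 cm) × 3 aiming
distances (5/10/15 m) × 7 distances (2–15 m) × 10 replicates = 3780
trials. Two generation modes share one config:

* **Detection mode** (`coefficients=None`): each trial succeeds with
  probability `p(y)` from a known detection function — by default the
  half-normal–logistic mixture with α = 6 m, `loc` = 1.5 m,
  `steep` = 3 /m. This is the parametric-bootstrap setting in which
  stage-1 family recovery is well posed, and the six-candidate selection
  recovers the generating family essentially always at n = 3780.
* **Covariate mode** (default): each trial succeeds with probability
  `invlogit(β₀ + Σ βx + β_d · p(y))`, built with exactly the stage-2
  design-matrix construction. Default true effects: intercept −2.5,
  `body_size[large]` −0.4, `body_size[medium]` −2.5,
  `camera_model[PC900]` −1.0, `distance_model` 6.5, `speed` −1.0,
  `sun_azimuth` −0.3, `body_size[medium]:distance_model` 2.5,
  `camera_model[PC900]:distance_model` 1.5 — magnitudes that give an
  overall trigger rate near 0.5 at 2–6 m falling below 0.1 by 15 m, a
  strong medium-proxy penalty that relaxes at close range, and moderate
  camera/speed/sun effects.

An important structural fact documented here because tests rely on it:
the covariate-mode marginal distance curve, `invlogit(a + b·p(y))`
averaged over covariates, is *not itself* a member of any
detection-function family. Its squashed sigmoid shoulder is
systematically better matched by the flexible 4-parameter hazard-rate
mixture (by ≈20–55 expected AIC units across realistic effect sizes), and
a stage-1 curve refit to such data estimates the pooled marginal, not the
generating function. Consequently family recovery is checked on
detection-mode data, and stage-2 coefficient recovery on covariate-mode
data with stage 2 conditioned on the generating detection function —
each clause in the setting where it is well posed. Two-stage inference on
real data inherits the same caveat: the fitted detection function is an
empirical summary of the marginal distance response, not a separable
physical truth.

Other simulator details: trial speed is truncated normal (mean 1.0,
sd 0.3 m/s, resampled below zero); the vertical camera angle follows
geometrically from lens height and aiming distance
(`atan((h − 0.8 m)/aim)`, the camera being tilted to centre a gauge of
fixed height) plus 0.5° of jitter, which reproduces the strong
angle–height rank correlation; sun covariates are drawn uniform over
daytime ranges (altitude 0.1–1.2 rad, azimuth 0.7–2.6 rad) or, given a
site and time window, from the built-in ephemeris. Every random quantity
in a trial comes from a substream keyed on (seed, row index), so a fixed
seed reproduces trials byte-for-byte and row order never changes
outcomes.

`solar_position` implements the standard truncated-series low-precision
solar ephemeris (geometric mean longitude/anomaly, equation of center,
apparent longitude, corrected obliquity, equation of time), valid
1900–2100 and accurate to a few hundredths of a degree; refraction is not
applied. The test suite checks it against an independently coded
approximate ephemeris that uses a different longitude series and sidereal
time, with 0.01 rad agreement.

## What the tests show, and problem sizes

Stochastic checks run at the experiment's own scale (n = 3780): family
recovery over 50 seeded replicates and stage-2 95% Wald coverage over
200 seeded replicates (the larger replication keeps the Monte-Carlo
error of the coverage proportion itself small relative to the 90%
acceptance bar; measured per-coefficient coverage is 93–96.5%).
Oracle checks compare the logit fit to direct likelihood maximization
(1e-6), the AUC to exhaustive pair counting (1e-12), the Bernoulli NLL to
brute-force summation (1e-10), and small-sample stage-1 fits to a dense
grid search. The acceptance script re-runs the pipeline at reduced
replication (10 selection seeds, 50 coverage seeds) to stay fast while
exercising every stage.

Passing tests demonstrate internal consistency and recovery under the
simulator's assumptions — independent Bernoulli trials, a stationary
detection function, covariate effects that are exactly linear on the
log-odds scale. Real trials add observer error in distance and scoring,
heterogeneous proxies, wind/vegetation/temperature effects and serial
dependence, none of which the generator emulates.

## Known limitations

* Proxy-based trials measure `r_t` given an encounter; the encounter
  process (`r_e`) and image identifiability (`r_p`) are out of scope,
  entering only through the closed-form repeat-visit probability.
* Covariates do not enter the stage-1 detection function; the two-stage
  conditioning avoids a high-dimensional multimodal likelihood at the
  cost of ignoring stage-1 uncertainty in stage-2 standard errors.
* Sun angles enter linearly in radians; no circular/harmonic encoding.
* The stepwise procedure inherits the usual caveats of significance-based
  selection (post-selection inference is not corrected).
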