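# Methods

`calfplay` implements a complete pipeline for measuring locomotor play in
group-housed dairy calves from indoor ultra-wideband (UWB) location data:
simulation of realistic input data, positional cleaning, trajectory
features, imbalanced classification, misclassification-corrected
quantification, and mixed-model analysis of the resulting daily play
measures. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot show.

## The measurement problem

Locomotor play — rapid forward movement lasting at least 3 s, possibly
with jumping or bucking — is a candidate indicator of positive welfare,
but it is rare: on the order of 0.16% of 3-s observation windows. At that
prevalence a classifier with excellent sensitivity and specificity still
returns mostly false positives (precision of a few percent), and the raw
"classify and count" estimate of daily play overestimates badly whenever
the false-positive rate is non-zero. The pipeline therefore separates two
roles: a *classifier* that ranks windows, and a *quantifier* that converts
raw positive fractions into unbiased prevalence estimates.

## Adjusted-count quantification

For a classifier with true-positive rate `tpr` and false-positive rate
`fpr`, the expected raw positive fraction on a sample with true prevalence
`q` is `p0 = q*tpr + (1-q)*fpr`. The adjusted count inverts this map:

    p' = (p0' - fpr) / (tpr - fpr)

clipped to [0, 1] (the same algebra as the Rogan–Gladen corrected
prevalence). The correction requires `tpr > fpr`; the implementation
rejects rate gaps below 1e-6. `tpr` and `fpr` are estimated by pooled
out-of-fold predictions from stratified fivefold cross-validation at a
*training condition* — a fixed number of play windows paired with a large
non-play sample — chosen over a grid (default 10, 80, ..., 2180 play
windows with 250,000 non-play) to maximise `tpr - fpr`, i.e. the
denominator of the correction; ties break toward the larger play count.

Because the downstream models need per calf-day play measures, the
correction is applied per calf-day, and a concrete corrected positive set
is formed by keeping the `round(p'*n)` highest-scoring windows of the day
(rounding half away from zero). An *instance* of play is a maximal run of
consecutive retained 3-s windows; daily play duration is 3 s times the
number of retained windows. Overestimation is reported as
`100*(predicted - observed)/observed`, and predicted-vs-observed counts
per unit are compared with a Spearman rank correlation (t-approximation
p-value) — the non-parametric default for count pairs of this size.

## Features and windows

Cleaned trajectories are cut into non-overlapping 3-s windows aligned to
the absolute 3-s grid. Each window carries the four 1 Hz positions
[t, t+3] inclusive (boundary samples shared with the neighbouring window),
giving three speeds and two turning angles per window — chosen so no
window statistic is ever computed from a single value. Per window, three
measures — speed (Euclidean displacement over elapsed time), turning angle
(arccos of the normalized dot product of successive displacements, in
[0, pi], defined 0 when a displacement is shorter than 1e-9 m) and
turning-angle speed (speed times the cosine of the angle) — are summarised
by mean, population standard deviation, sum, maximum and minimum: 15
features. A window is labelled play when at least half of it overlaps a
labelled play interval; windows missing any expected 1 Hz sample are
dropped.

## Cleaning

The order is fixed: exclusion intervals (human interaction, first day,
power cuts), then removal of fixes outside the 6 m x 10 m pen rectangle,
then a centered 10-s moving-average smoother, truncated at edges, which
never bridges gaps longer than 2 s (power cuts are not interpolated
across). Centered smoothing preserves linear motion exactly in the
interior; whether the original processing smoothed before or after the
out-of-pen filter is not documented anywhere we know of, so the order
above is a package decision. Label streams can be shifted by a constant
per-recording clock offset; estimating that offset from feeder-entry
events is out of scope.

## Classification

Whole calves are assigned to the training or test side (seeded greedy
assignment targeting a 30% test-side *window* share) so that no calf
contributes windows to both sides. Training data are balanced by randomly
undersampling the non-play majority to the play count. The classifier is
an AdaBoost ensemble of depth-limited trees (`max_leaf_nodes =
max_splits + 1`); the shipped default hyperparameters are 10 splits, 494
cycles, learning rate 0.001016. A seeded random search with fivefold-CV
misclassification replaces black-box Bayesian optimisation; with the
defaults shipped, tuning is optional. Note that at a learning rate of
~1e-3 the boosting weights barely move, so the ensemble behaves close to
an averaged single tree; this is faithful to the stated optimum and
performs indistinguishably from stronger boosting on the synthetic cohort.

## Mixed models

Daily outcomes are modelled on the log link with a calf random intercept:

    log E[y_ij] = x_ij' beta + u_i,   u_i ~ N(0, sigma_u^2)

with fixed effects age (days), cohort, weaning stage (pre-weaned days
1–35, step-down 36–60, weaned afterwards), health status (Wisconsin score
0–2 healthy, 3–4 moderate, >=5 sick), sex-breed and daily mean ambient
temperature; reference levels are cohort 1, pre-weaned, healthy, female
Holstein. The instance-count response is negative binomial (NB2, variance
`mu + alpha*mu^2`). The duration response (integer seconds, zeros occur,
so a Gamma family is unsuitable) starts as Poisson and upgrades to NB2
when the marginal Pearson dispersion exceeds 1.5 — in practice it always
upgrades, since durations are 3-s multiples of an overdispersed process.

No pre-installed Python library fits an NB2 GLMM, so the marginal
likelihood is maximised directly: the per-calf integral over the random
intercept uses adaptive Gauss–Hermite quadrature centred at the
conditional mode (default one node — the Laplace approximation, accurate
because each calf contributes tens to hundreds of days; a 9-node rule
changes the log-likelihood by < 0.05 on such data). Optimisation is
L-BFGS-B over `(beta, log sigma_u, log alpha)` with Poisson-GLM starting
values and a method-of-moments start for `alpha`; standard errors come
from the numerical Hessian of the marginal log-likelihood. On a shared
simulated dataset the fit agrees with R's `glmmTMB` (nbinom2) to ~5e-3 on
coefficients and ~0.5 log-likelihood units (verified in the test suite).

Wald statistics are referred to a t distribution with *between-within*
degrees of freedom: a covariate constant within every calf (cohort,
sex-breed) is tested against `n_calves - q_between` degrees of freedom
rather than a normal reference, which is anticonservative for
between-cluster contrasts when calves number a few dozen. Within-calf
terms carry `N - n_calves - q_within` degrees of freedom and are
effectively z-tests.

Exponentiated coefficients are rate ratios (`100*(exp(beta)-1)` percent
change). The share of variance attributable to calf identity is the
latent-scale intraclass proportion `sigma_u^2 / (sigma_u^2 + sigma_eps^2)`
where the observation-level latent variance uses the trigamma method:
`psi_1(nu)` with `nu = (1/mu_bar + alpha)^(-1)` for NB2 (`psi_1(mu_bar)`
for Poisson), evaluated at the mean fitted value.

## The synthetic cohort

The generator emulates the data-collection conditions: 1 Hz (x, y) fixes
in a 6 m x 10 m pen; isotropic Gaussian localization noise with
`sigma = CEP/1.1774` so the median radial error equals the 0.15 m CEP;
contiguous dropped blocks (power cuts) and a small fraction of fixes
displaced outside the pen (to exercise cleaning); a constant label clock
offset. Behaviour is a semi-Markov chain (rest / walk / feeder visit,
exponential dwells) onto which play bouts (renewal process, duration
3 + Exp(4) s, target 0.16% of time) and sub-3-s "dashes" — rapid movement
that fails the minimum-duration play definition and is therefore labelled
non-play — are superimposed.

Kinematic ranges are generator choices, not measurements: the ethogram
defines play only as rapid forward movement of at least 3 s. Two
constraints shaped the defaults. First, geometry: an 11-sample centered
moving average inside a 6 m x 10 m pen caps *every* smoothed speed at
roughly pen-diagonal/11 ≈ 1.06 m/s, however fast the raw motion. Play is
therefore modelled as near-ballistic dashes at 2–4 m/s (heading SD 0.15
rad/s, discrete bucking heading-jumps at 0.10/s), and non-play locomotion
as a slow amble at 0.15–0.5 m/s with more meander — giving the separation
in the smoothed feature space that the classifier needs, while bout-edge
windows, dashes and localization noise keep play precision at a few
percent. Second, the daily-outcome generator draws instance counts
negative-binomially (alpha 0.5) with log-mean given by the Table of
covariate effects used as defaults (age -0.02/day, step-down +0.10,
weaned +0.42, sick -0.12, male -0.18, temperature -0.008/°C, cohort
-0.09/+0.49, intercept 4.04) and a calf random-intercept SD of 0.3;
durations are 3 s times a shifted-geometric window count per instance
(mean 2 windows).

What the synthetic cohort does *not* contain: social interaction between
calves (play is independent per calf), radio propagation artefacts beyond
isotropic noise, observer disagreement in labels, and any vertical
movement — "jumping or bucking" appears only as heading discontinuities.
Passing tests therefore demonstrate that the algorithms are correct and
well-calibrated under these stated conditions, not that a real herd would
yield the same operating numbers.

## Problem sizes and numerical choices

The test suite runs cohorts scaled for a single CPU: the classification
check uses 10 calves x 14 days with a 4-hour daily observation window
(~620k windows, ~1000 play windows at 0.16% prevalence); quantification
calibration uses 201 simulated test sets of 20,000 windows; mixed-model
effect recovery uses 100 cohorts of 30 calves x 120 days and the
type-I-error calibration 200 null cohorts of 20 calves x 75 days (with
balanced sexes so every model term is identifiable in every replicate).
Tie-breaks and degenerate cases are fixed throughout: turning angle 0 for
sub-1e-9 m displacements, counts rounded half away from zero, corrected
positive sets chosen by score rank with stable ordering, condition-grid
ties toward more play data, tuning ties toward fewer cycles then fewer
splits.

## Known limitations

- The Laplace approximation slightly biases variance components downward
  with few clusters (as does maximum likelihood generally); with 15–20
  calves the estimated calf-variance share can sit 2–4 points below the
  generator's target, shrinking as calves increase.
- With very short study windows some model levels (e.g. "weaned" before
  day 61) do not exist; such terms are dropped from the design and
  recorded on the result rather than estimated.
- The quantifier assumes the confusion rates estimated on the training
  condition transfer to the prediction sample; covariate shift between
  calves can leave residual bias, which the per-calf-day application
  bounds but does not remove.
- Smoothing before windowing (the fixed order) attenuates bouts shorter
  than the 10-s window; sensitivity of window counts to the 50% labelling
  rule is untested against alternatives.
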