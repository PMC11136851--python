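# Methods

## Model and estimands

The response process is a longitudinal logistic regression on the per-visit
binary renal-response status. The logit of the responder probability rises
from `RR_SS − Δ_RR` at first dose toward the steady-state `RR_SS` with rate
constant `K_RR` (1/day), plus an additive treatment effect `θ_BEL` on the
logit scale for the active arm. There are no random effects: per-visit
responses are conditionally independent given the covariates. This is a
deliberate simplification — with binary data at 26 visits a subject-level
random intercept is weakly identified, and the marginal quantities the model
is used for (responder rates over time, covariate effects on them) do not
require one — but it means the model understates within-subject correlation
and should not be used for subject-level prediction.

Two estimand strategies are implemented:

- **Composite ("dropout = non-responder")**: every scheduled visit after a
  subject's last on-treatment visit is imputed as a non-response and the
  likelihood is purely Bernoulli. Simple, but conflates leaving the study with
  failing treatment.
- **While-on-treatment (joint efficacy–dropout)**: only observed on-treatment
  visits contribute Bernoulli terms; the dropout process contributes a
  survival likelihood with a piecewise-constant hazard equal to `HZ_R` while
  the last observed status is responder and `HZ_NR` while non-responder
  (a "random dropout" model in the Hu–Sale sense: the hazard depends on the
  observed history only).

Covariates enter structural parameters additively as coefficient ×
log(value/reference) with natural logs. References: baseline proteinuria
2.5 g/g (the population median), 12-week average concentration 90 µg/ml,
4-week 95 µg/ml. The exposure term applies only to the treatment effect and
only for treated subjects. `K_RR` is *not* floored: for extreme baseline
proteinuria the effective rate constant can go negative (a logit that drifts
down over time). That is the model as parameterized; the package emits a
`RuntimeWarning` rather than silently truncating.

## Likelihood details and conventions

- **Baseline carried status** before the first visit is non-responder.
  Patients enter these trials with active disease; under the default
  parameters the modeled baseline response probability is ≈ 0.01, so
  non-responder is the only defensible initial state.
- **Completers** contribute `P_SURV(study_end)` (right-censoring at day 728),
  with the final observed status carried to the end of the study. The
  dropout-probability factor applies only to dropouts. This censored-survival
  convention is required for the hazards to be identified.
- **Dropout times** are strictly later than the last attended visit; the
  generator enforces this by counting an event on a visit day as that visit
  missed.
- **Clipping**: Bernoulli probabilities are clipped to
  `[1e-12, 1 − 1e-12]` (configurable) before logs, with a logged warning;
  the objective is exactly −2·log-likelihood with no additive constants, so
  OBJ differences between nested fits are likelihood-ratio statistics.
- The per-subject likelihood has a readable record-at-a-time implementation
  (`renresp.likelihood`) and a vectorized compiled-arrays implementation used
  by the optimizer (`renresp._design`); the test suite checks they agree to
  1e-8 and checks both against a brute-force day-grid enumeration oracle to
  1e-9.

## Estimation

Fits minimize OBJ with L-BFGS-B using an analytic gradient. The two
rate-constant parameters are rescaled internally (characteristic scale
0.01/day) so the gradient is well conditioned. The default initialization is
a two-stage warm start: a Bernoulli-only pre-fit of the structural parameters
from a neutral start, then hazards at the crude event rate
(events / person-time) with a zero log hazard ratio. `n_starts` (default 5)
adds jittered restarts (relative sd 0.3) and keeps the best objective; fits
are deterministic given data, options, and `random_state`. Convergence uses
a relative function tolerance of 1e-12 with a 1e-6 projected-gradient
threshold in the scaled space.

The covariance of the estimates is `2 · H⁻¹`, where `H` is the Hessian of OBJ
obtained by central finite differences of the analytic gradient (relative
step 1e-5, symmetrized). If `H` is not positive definite the covariance is
reported absent and the fit flagged. %RSE is `|SE / estimate| × 100` (the
absolute value keeps RSEs positive for negative estimates).

Covariate selection uses likelihood-ratio tests at α = 0.001 (≈ 10.8-point
OBJ drop per added parameter). Exposure metrics do not exist for treated
subjects who dropped out before the averaging window closed (day 28 for the
4-week metric, day 84 for the 12-week metric), so exposure models are
compared on the reduced dataset of subjects with the metric. The parent OBJ
on that subset can be obtained two ways, both exposed: refitting the parent
on the reduced dataset (`parent_mode="refit"`, the default, the cleaner
comparison) or summing the full-data parent fit's stored per-subject OBJ
contributions over the reduced subjects (`parent_mode="subset"`, the cheaper
shortcut). The choice is logged; `subset` can only raise the parent OBJ
relative to `refit`, making the test slightly anti-conservative.

## Simulation

Simulated all-comers response is `P_RESP(t) · P_SURV(t)` with the
response-weighted marginal hazard
`HZ(t) = HZ_R·P_RESP(t) + HZ_NR·(1 − P_RESP(t))`. The hazard integral uses
trapezoidal quadrature on a 1-day grid (hazards are ~1e-4–1e-3/day, so the
quadrature error is far below any band width; the step is configurable, and a
test checks halving it changes the result by < 1e-6). Note the weighted
hazard treats the response probability, not the realized status path, as the
mixing weight — a marginal approximation that the generator-agreement test
shows holds to well within binomial noise at trial size.

Parameter uncertainty is propagated by sampling the asymptotic multivariate
normal of the fit (default 500 draws; seeds are mandatory in the public
interface; a non-PSD covariance is repaired by eigenvalue clipping with a
warning). Bootstrap resampling would be a natural extension but is not
implemented. Per draw, the per-subject curves are summarized within strata by
the across-subject median and 2.5/97.5 percentiles (the 95% prediction
interval); across draws the 2.5/97.5 percentiles of each summary curve give
its 95% confidence band, and the reported central curves are medians across
draws. Percentiles use numpy's linear interpolation between order statistics,
so bands are bit-reproducible given the seed. Default strata cut baseline
proteinuria at 2.5 g/g within each arm, adding an exposure split at the
metric reference when the fitted model carries one.

Observed responder rates carry exact Clopper–Pearson intervals by
beta-quantile inversion, under either counting convention: all randomized
subjects with off-treatment visits as non-response, or on-treatment subjects
only (time points with nobody on treatment are omitted).

## Synthetic-trial generator

The generator emulates the study conditions the analysis was designed for:
224 + 224 subjects under 1:1 allocation, visits every 28 days through day
728 (26 visits), baseline proteinuria log-normal with median 2.5 g/g and
log-sd 0.9 truncated to [0.1, 40] g/g, and early exposure negatively linked
to proteinuria (power exponent −0.25) around medians of 90 µg/ml (12-week)
and 95 µg/ml (4-week), with the two metrics sharing the proteinuria term and
having residuals correlated at 0.8. The exposure residual is a two-piece
(asymmetric) scaled normal: a symmetric log-normal centered at 90 cannot
reproduce the intended 95% range of 41–159 µg/ml (its geometric midpoint is
80.7, not 90). The low/high residual log-sds (0.36/0.16) were calibrated once
against those quantiles, and a median-anchoring offset — the negated median
of the residual-plus-proteinuria-term convolution, computed by a fixed-seed
Monte-Carlo draw and cached — keeps the marginal median exactly on the
reference (and is exactly zero in symmetric or zero-residual configurations).

Trials are simulated by walking the visit schedule per subject: between
status-determining times an exponential dropout clock runs at the
carried-status hazard (baseline status non-responder); if it fires before the
next visit the subject drops out there, otherwise the visit response is an
independent Bernoulli draw from the structural model. Default generating
parameters are the published joint-model estimates for each endpoint
(`PERR_JOINT_PARAMS`, `CRR_JOINT_PARAMS` and their exposure-covariate
variants). Treated subjects dropping out before day 28 / 84 have the 4- /
12-week exposure metric set missing, reproducing the reduced-dataset
mechanism for exposure comparisons.

Because the generator uses exactly the fitted model's assumptions
(conditional independence across visits, constant status-dependent hazards,
no random effects, no visit nonattendance while on treatment), parameter
recovery against it is a clean oracle for the estimation machinery — and for
exactly the same reason, passing those tests says nothing about model
misspecification on real data (within-subject correlation, time-varying
hazards, intermittent missed visits, rescue-therapy dynamics are all absent).
The PK process behind the exposure metrics is not simulated; the metrics are
drawn directly from their calibrated marginal model.

## Problem sizes used in the checks

The recovery checks fit 20 replicate trials of 448 subjects per endpoint and
compare replicate means to the generating values within twice the
Monte-Carlo standard error implied by the published relative standard
errors. Null calibration of the exposure LRT uses 2,000 trials at half scale
(112 + 112), warm-started at the generating values, asserting the exact
binomial 99.9% envelope for a 0.1% rejection rate plus a χ²(1)-location check
on the statistic's median. The standard-error calibration check accepts a
median empirical-SD/reported-SE ratio in [0.7, 1.3] across parameters with
per-parameter ratios in [0.5, 2]: per-parameter SD estimates from 20
replicates carry ~16% sampling error, so a hard per-parameter 30% band would
reject a correctly calibrated fit too often. Predictive-band self-consistency
averages coverage of observed imputed rates by the 95% prediction band over
10 self-generated trials with 200 parameter draws per band.

## Known limitations

- No random effects; no within-subject response correlation beyond what the
  shared covariates induce.
- Hazards are constant in time within responder status; no frailty, no
  interval censoring of the dropout time; treatment discontinuation,
  treatment failure, and withdrawal are pooled as one event.
- The exposure–response parameterization is anchored to the studied dose
  range; nothing here supports extrapolation to unstudied doses.
- The asymptotic-normal parameter sampling understates uncertainty when the
  likelihood is markedly non-quadratic (e.g., very few dropout events).
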