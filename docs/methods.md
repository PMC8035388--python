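# Methods

## The task environment and what the simulator emulates

The primary task is a multiple-asset management game: K UAVs (3, 5, or 7,
the difficulty manipulation) fly across a 1920x1080 screen at 75 px/s,
reflecting at the edges.  Each UAV's fuel drains at 5% of a full tank per
second, so an unattended tank empties in 20 s.  Hovering the mouse over a
UAV for at least 0.3 s reveals its gauge; clicking refuels it only when the
level is strictly below 25% of the gauge.  Five scored events follow:
checking fuel in the critical zone (HHO, +50) or too early (FAHO, -50),
refuelling in the zone (HR, +2000) or out of it (FAR, -500), and letting a
UAV crash (MR, -1000; a fresh UAV with 70-100% fuel immediately replaces
it, so fleet size is invariant).  Sessions have 21 two-minute blocks whose
difficulties form balanced easy/medium/hard triples.  Throughout, a
detection response task (DRT) presents a stimulus with onset-to-onset gaps
drawn uniformly from [3, 5] s; the interval between two prompts defines a
trial, and the response (RT in ms, or an omission) is the workload probe.

The simulator is headless and event-driven: between operator actions and
crash times all dynamics are closed-form (fuel is piecewise-linear, crash
times are exact), so blocks are simulated without a tick loop; event
timestamps are reported on a 0.1 s grid.  A tick-level kinematic API
(`step_dynamics`) implements the movement/reflection/crash rules for
completeness and testing; the study driver tracks only fuel and interaction
state because no logged output depends on UAV positions.

## The operator agent

Human operators are replaced by a noisy-memory heuristic
(`OperatorPolicy`).  The agent keeps an internal estimate of each UAV's
fuel, exact at the moment of observation and degrading with staleness: at a
check, perceived fuel = true fuel + Normal(0, `memory_noise` *
sqrt(staleness) * `load_scaling`^(K-3)).  Checks arrive as a Poisson
process (`check_rate`, default 0.8/s -- roughly one check per 1.3 s, busy
but sustainable for a 7-UAV fleet whose refuel windows open every ~3 s).
The agent hovers over the UAV with the lowest perceived fuel (each
critically-low UAV is independently neglected with probability
`lapse_prob` per check, producing occasional crashes even at high check
rates) and clicks when the revealed level is below `refuel_trigger`
(default 0.30).  Setting the trigger above the 25% task threshold is what
generates false-alarm refuels, as impatient human operators do.  The
initial free gauge look is folded into the estimate initialisation (the
agent knows spawn levels approximately), so every logged hover is scored;
the analysis pipeline never depends on these policy internals.

Default event yields per 2-minute block are in the plausible range for a
demanding version of this task: tens of hovers, a handful of false refuels,
and a few crashes per block, increasing with K.

## The generative workload model

DRT outcomes are generated from a two-part model that mirrors the analysis
model, so recovery is a meaningful check:

* omission ~ Bernoulli(logit^-1(gamma_0 + gamma' x + gamma_miss *
  prev_omission + b_o)), with b_o ~ Normal(0, 0.5) per participant;
* RT (ms) = exp(beta_0 + beta' x + b_r + eps), b_r ~ Normal(0, 0.15),
  eps ~ Normal(0, 0.35), i.e. log-normal RTs.

The covariates x are the difficulty dummies (+2UAVs, +4UAVs against the
3-UAV reference), the block number (1..21), and the standardized
WeightFuel, #HHO3s, and #FAR3s.  Because the per-SD coefficients are only
meaningful on the standardized scale, the generator computes the realized
predictor values for a participant-day, z-standardizes them within that
participant-day (sample SD), and then applies the coefficients.  Default
magnitudes translate to a ~450 ms baseline with roughly +45/+65 ms for
5/7 UAVs, about -40 ms per SD of WeightFuel and +40 ms per SD of the count
predictors, a ~75 ms cumulative time-on-task drift, a 10-30% omission
band rising with difficulty, and a substantial previous-omission effect on
the logit scale.  An RT draw exceeding the 2.5 s response window is
recorded as an omission (censoring, not resampling); under the defaults
this affects a negligible fraction of trials.  `WorkloadModel.null_effects()`
zeroes every event/refined coefficient for null-calibration studies.

Deliberate non-realism: the agent does not learn (no day effects arise
unless two days are generated with different parameters), RT and omission
random intercepts are independent, omissions are conditionally independent
of the RT residual, and fuel state is the only latent driver of workload.
Passing recovery tests therefore shows the *pipeline* is consistent -- it
cannot show that human data meet these assumptions.

## Trials, exclusions, predictors

One trial per prompt; `prev_omission` chains within a block and is
undefined for trial 1.  Two filters run before modelling: participant-days
whose omission rate exceeds 45% (strictly) in two or more difficulty
conditions are dropped day-wise, and the first trial of each block plus
trials whose most recent interaction is absent or more than 100 s old are
dropped, with removal counts audited at each step.  The filters touch
disjoint criteria, so their order does not matter on typical data.

Event windows are half-open, (prompt - w, prompt]: an event coincident
with the prompt precedes the response and counts.  WeightFuel is the power
mean of order p (default 1/4) of the on-screen fuel fractions; for
simulated studies it is evaluated from the simulator's ground-truth
snapshot at prompt time, and for interaction-only logs it is reconstructed
by linear drain extrapolation from each UAV's last observation (hover and
FAR observations are direct; HR is imputed at the observed level plus the
expected 75% gain, capped; a crash removes the UAV until its replacement
is first seen; observations older than 100 s are discarded and the mean
runs over the currently-known UAVs).  Both paths share one interface; on
simulated data the reconstruction correlates about 0.8 with ground truth.
OrdFuel uses fuels at the hover instant, not at prompt time, and is coded
missing when no hover falls in the 3-s window.  Standardization uses the
sample (n-1) SD within participant-day; a zero-variance group is set to 0
with a warning.

## Model estimation

All models are fitted by maximum likelihood (never REML) so that AIC/BIC
are comparable across fixed-effect sets; k counts fixed effects plus
estimated variance components.

* Linear mixed model (log RT): exact profiled ML.  For a single random
  intercept, the GLS estimate at a fixed variance ratio lambda =
  sigma_b^2/sigma_e^2 has a closed form after the within-group shrinkage
  transform y_i - c_g ybar_g with c_g = 1 - (1 + lambda n_g)^(-1/2), and
  the residual variance profiles out analytically; a bounded 1-D search
  over log lambda (with an explicit check of the lambda = 0 boundary)
  maximizes the remaining smooth function.  This is exact, fast enough for
  thousands of cross-validation refits, and free of the convergence
  pathologies general-purpose mixed-model optimizers can exhibit on small
  training folds; statsmodels' MixedLM serves as an independent
  cross-check in the test suite.
* Binomial and Poisson mixed models: adaptive Gauss-Hermite quadrature
  (default 9 nodes; 1 node = Laplace).  Per-group posterior modes of the
  random intercept are found by a Newton iteration vectorized across
  groups; the outer optimization is BFGS on (beta, log sigma_b), started
  from the fixed-effects-only GLM.  Standard errors come from the
  numerically differentiated Hessian.  A tiny final gradient after a
  line-search "precision loss" is treated as converged.  lme4's `glmer`
  (nAGQ = 9) reproduces the estimates to ~1e-3 on test fixtures.
* Two-part log-normal model: logistic occurrence part (omission) plus
  log-normal intensity part (log RT on responded trials) with independent
  random intercepts, so the joint log-likelihood is exactly the sum of the
  parts; out-of-sample prediction is defined for the intensity variable
  only.
* Zero-inflated Poisson (crash counts in the 5 s after a prompt):
  structural-zero logit and count part share covariates; the random
  intercept sits in the count part and is integrated by the same AGQ
  machinery.  An all-zero response is flagged degenerate rather than
  fitted.

Predictions for unseen participants use fixed effects only (random
intercepts at their population mean of zero); binomial predictions are
probabilities, linear ones log-RT.  Unseen factor levels are an error.

## Cross-validated model selection

Participants are permuted (seeded) into k = 5 folds whose sizes differ by
at most one.  The default split is deliberately inverted: one fold trains
(~20% of participants) and the other four, pooled, are predicted -- a
demanding test of between-subject generalization; a conventional 80/20
mode exists behind a switch.  The candidate set is every subset of the
optional predictors, each with difficulty and block always included, plus
four baselines (difficulty+block, block, difficulty, intercept-only);
interactions are excluded from enumeration and appear only in the
descriptive ladders.  Each (training fold, model) cell is scored by the
mean squared deviation (MSD) between observed and predicted log RT (or
omission indicator vs predicted probability).  NMSD subtracts a single
grand-mean MSD over all cells of the analysis; the phrase "average across
folds" could also be read per-model (which would zero every model's mean)
or per-fold, so the grand-mean centring -- which preserves the nonzero
per-model means that make ranking displays informative -- is the default
and the per-fold variant is available behind a switch.  Rankings are
identical under MSD and NMSD either way.  Before scoring, one
complete-case restriction over the union of all candidate predictors is
applied (OrdFuel is missing on trials without an in-window hover), so all
models are trained and scored on identical trials and MSDs are comparable.
Failed fits leave a missing cell with a warning rather than aborting the
analysis.  Standardization is within-participant, so it is identical
whether computed before or after fold splitting -- no cross-participant
statistic can leak between training and test sets.

## Reporting conventions

The descriptive ladders fit {difficulty, +day, +difficulty x day} or
{difficulty+day, +block, +day x block} per response and report AIC/BIC
with minima marked and deltas annotated against the 2-7 support guideline.
Effect reports fit the two-part, linear, and binomial models per day with
the standardized refined predictors; the block entry is also shown as the
cumulative effect of completing the session, coefficient x 20 increments
(block 1 to block 21), and log-RT effects get an approximate ms
translation delta_ms = exp(intercept + delta) - exp(intercept) at the
baseline profile -- a convention, since log-scale effects have no unique ms
equivalent.  The exponent sweep rebuilds the features and reruns the
refined CV once per p in {1/8, 1/4, 2, 4}, labelling each WeightFuel
variant; the overload comparison fits event-based
{HHO, FAHO, FAR, HR flags} vs refined {WeightFuel, #HHO3s, #FAR3s}
zero-inflated Poisson models (both with difficulty and block) for the
post-prompt crash count and reports the AIC/BIC winner per day.

## Problem sizes and numerical choices

Repeated end-to-end validation uses a reduced study: 40 participants x 2
days x 21 blocks of 60 s (about 15 trials per block), the package's chosen
size for 20-replicate recovery experiments; null-calibration and sweep
studies use 20 participants x 1 day at the same block length.  Simulation
randomness is keyed per participant (and day) from the study seed, so
adding participants never perturbs earlier ones.  CSVs are read with
round-trip float parsing so write-read-write is byte-stable.  Fuel ties at
the 25% threshold are resolved strictly ("below" wins nothing): ties have
probability zero in continuous simulation but the rule is fixed for
reproducibility.  After an omission the next prompt onset is still drawn
uniform [3, 5] s from the previous onset, and an omission is "no response
within the 2.5 s window" (the ISO DRT convention); both are conventions
chosen here, not facts of the task.

## Limitations

Agent realism is intentionally minimal; effects of learning, strategy
shifts, and correlated RT/omission processes are absent from the generator
and therefore untested.  The GLMM path supports a single random intercept
only (no random slopes), matching the analysis models, and the two-part
model's sub-models are independent by construction.  OrdFuel's missingness
forces a complete-case restriction in CV; with hover-sparse policies this
can discard a nontrivial share of trials.
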