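# Methods

## The problem

Autonomous recording units (ARUs) paired with automated detection
algorithms make it cheap to survey sound-producing wildlife at many
sites over many seasons, but the detector's output stream contains
event-level mistakes: false alarms (soundscape events that fool the
detector) and missed calls. When those event-level mistakes are
aggregated into survey-level detection/non-detection data, the
resulting encounter histories contain survey-level false positives and
false negatives — and dynamic occupancy estimates of colonization and
extinction are notoriously sensitive to unmodelled false positives.

`acoustocc` simulates this whole chain for a hypothetical species and
fits a false-positive-aware dynamic occupancy model to the result, so
that the bias induced by different encounter-history construction
choices can be measured directly.

## Generative model

**Latent dynamics.** Each of `N` sites is occupied in season 1 with
probability ψ. Between consecutive seasons an occupied site goes
extinct with probability ε and an empty site is colonized with
probability γ (first-order Markov, sites independent, no covariates,
no spatial structure). Four canonical settings are built in:
high/low initial occupancy (ψ = 0.60 / 0.20) crossed with high/low
turnover (γ = ε = 0.25 / 0.05), labelled HH, HL, LH, LL.

**Soundscape.** Recording follows a fixed schedule: 5 min of audio per
day for two 30-day seasons (all defaults configurable). Within
recorded minutes, species calls arrive as a Poisson process with
hourly rate λ_c (20 or 100 calls/h in the study design) at occupied
site-seasons only; false alarms arrive at every site in every recorded
minute at rate λ_f = 48/h (0.8/min). Hourly rates convert to
per-minute Poisson means by division by 60, minutes independent.
The simulator draws the detector's *captured* event stream directly:
an event-level miss is simply a call that is never drawn, so a
separate event-level false-negative rate is not parameterised — λ_c is
the rate of calls the automated system captures.

**Classifier scores.** Each event receives a "target signal
probability" drawn from a beta distribution conditioned on its latent
truth. The *good* classifier uses Beta(4, 1) for true calls and
Beta(1, 4) for false alarms (means 0.8 / 0.2); the *bad* classifier
uses Beta(3, 3) for both (mean 0.5, no discrimination).

**Aggregation.** Surveys are consecutive blocks of 1 or 3 recording
days within a season (blocks never span seasons; the block length must
divide the season length). Within a survey with event scores
`s_1..s_J`, the probability that at least one event is a true call is

    q = 1 − ∏_j (1 − s_j),

the capture-recapture "at least one" rule. An unconfirmed survey is
coded 1 (uncertain detection) when `q ≥ T` (threshold T = 0.80 or
0.95; the boundary counts as a detection) and 0 otherwise. A fraction
(2.5% or 5%) of all site-surveys, selected uniformly at random without
replacement and rounded down to the budget, is designated for manual
confirmation: those surveys are coded 2 (certain detection) exactly
when they contain at least one true target event, else 0 — manual
review of the flagged events reveals the truth and cannot be fooled by
false alarms, and a confirmed survey consumes its slot even if it
contains no events (the selection emulates a fixed listening-hours
budget). Confirmation is pooled over all site-surveys, not stratified
by site or season.

## The estimation model

The three-state dynamic occupancy model with false positives uses the
observation probabilities, conditional on the latent state of the
site-season:

| code | occupied | unoccupied |
|------|----------------|-------------|
| 0 | 1 − p11 | 1 − p10 |
| 1 | p11 (1 − b) | p10 |
| 2 | p11 b | 0 |

`p10` is the survey-level false positive probability, `p11` the
survey-level detection probability given presence, and `b` the
probability that a detection at an occupied site lands in the certain
state. The factorisation P(2|occ) = p11·b follows the standard
multiple-detection-states parameterisation; users preferring the
"probability of a certain detection" reading can report `p̂11·b̂`.
Certain detections are impossible where the species is absent, which
is what anchors the model against false positives.

The site likelihood marginalises the latent occupancy sequence:

    L_i = Σ_{z_1..z_S} P(z_1) ∏_s P(z_{s+1}|z_s) ∏_{j∈s} P(y_ij | z_s),

computed by a forward recursion over seasons in log space (closure —
no state change — is assumed within a season, so each season
contributes only its per-code counts). The joint NLL is the sum over
independent sites. Intercept-only models are fit: no covariates, and
the confirmed-survey designations are *not* told to the model — `b` is
estimated freely rather than fixed at the design proportion.

### Fitting and convergence

`fit_miller_model` minimises the NLL over the six parameters on the
logit scale with L-BFGS-B (finite-difference gradients, pgtol 1e-5,
ftol ~1e-10, maxiter 1000). During the search, probabilities are kept
in [1e-12, 1 − 1e-12] and per-site log-likelihoods are floored at
−1e6, so a transiently impossible configuration (e.g. a certain
detection while p11·b underflows) yields a large finite penalty
instead of killing the optimiser; the *reported* NLL is recomputed
without the floor, so genuinely impossible data report `inf`.

The convergence flag requires (i) optimizer success, (ii) a finite
reported NLL, and (iii) a projected-gradient sup-norm ≤ 1e-5 per site
(the joint NLL and its gradient scale linearly with the number of
sites; at the study's 100 sites this is an absolute 1e-3 on the logit
scale). Estimates within 1e-3 of 0 or 1 are flagged as boundary
estimates; a history matrix containing a single repeated code is
degenerate (no information separates the parameters) and is reported
non-converged. Estimates drifting to a boundary typically terminate
via the function-change criterion with a non-small gradient and are
therefore flagged non-converged — mirroring how boundary fits are
excluded from converged-only summaries in occupancy software
generally. No ordering constraint (such as p10 < p11) is imposed;
users should check boundary flags when interpreting single fits.

## Truth values for the detection parameters

ψ, γ, ε are set directly, but p10, p11, b are *induced* by the
soundscape, classifier and aggregation settings. With per-survey event
means μ_c = λ_c/60 × (minutes per survey window) for calls and μ_f
likewise for false alarms, and confirmation proportion c:

- `p10 = (1 − c) · P(q ≥ T | false alarms only)` — confirmed
  unoccupied surveys are always coded 0;
- `p11 = c · (1 − e^{−μ_c}) + (1 − c) · P(q ≥ T | calls + alarms)`;
- `b = c · (1 − e^{−μ_c}) / p11`.

The threshold-exceedance probabilities have no closed form (they are
tail probabilities of sums of log-transformed beta variables with a
Poisson number of terms) and are computed by a 200,000-survey Monte
Carlo with a fixed internal seed, so the same scenario always reports
the same truth (Monte-Carlo SE ≲ 0.001). These truths serve two
roles: raw bias for the detection parameters, and informed starting
values — fits are initialised at the generating values, which the
original study found necessary for reliable convergence.

## Scenario grid and bias experiment

`reference_scenario_grid` enumerates the full factorial design: 4 dynamics
× 2 call rates × 2 classifiers × 2 aggregation windows × 2 thresholds
× 2 confirmation levels = 128 scenarios. Replicate RNG streams derive
from `(scenario seed, replicate index)` via `SeedSequence`, so any
sub-grid reproduces independently; scenario seeds derive from a single
base seed. `summarize_bias` reports, per scenario and parameter, the
mean and SD of raw bias (estimate − truth) over *converged* replicates
only, plus the convergence counts.

**Problem sizes.** The package's reference experiment uses 100 sites
and 100 replicates per scenario for the recovery benchmark (the
16-scenario slice at 1-day aggregation, 0.95 threshold, 5%
confirmation), and ≥ 12,000 unoccupied site-surveys for the
false-positive-rate summaries; at these sizes the Monte-Carlo SE of a
per-scenario mean bias is roughly 0.005–0.01 (larger in
low-convergence cells), which is why the recovery check allows a 1%
margin beyond the 3% bias envelope. Anyone wanting tighter numbers
can raise `n_reps`.

## What the simulation does and does not capture

The generator reproduces the statistical skeleton of an acoustic
monitoring program: occupancy dynamics, Poisson call and false-alarm
streams, classifier score distributions, schedule-limited sampling and
budget-limited confirmation. It deliberately omits: real audio and
template matching; time-of-day and weather effects on calling;
between-individual and abundance-driven call-rate heterogeneity;
spatial autocorrelation; classifier drift between seasons; imperfect
manual verification. Passing recovery tests therefore show that the
estimation machinery is unbiased *under the stated generative model*,
not that any particular field program will achieve these error rates.

## Numerical notes

- `survey_detection_probability` computes `1 − ∏(1−s)` via
  `expm1`/`log1p` for accuracy with many small scores; an empty survey
  returns 0.
- The survey threshold comparison is `q ≥ T`, so `T = 1` can only be
  met by a score of exactly 1 (measure-zero under beta scores).
- Sufficient statistics: with intercept-only parameters, a season's
  contribution depends only on its code counts, so the likelihood is
  evaluated from per-site-season count matrices rather than the raw
  code strings.
- Forward recursion in log space with `logaddexp` guards underflow for
  long histories or extreme parameters.
- All randomness flows through `numpy.random.Generator`; every
  simulation function takes an explicit generator or seed.
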