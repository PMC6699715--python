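# Methods

## Task environment

The environment is a two-armed bandit with ±1 outcomes, played in six
20-trial blocks: each of the three information conditions (Private,
Social-Choice, Social-Choice+Outcome) appears once with stable reciprocal
30/70% contingencies and once with 20/80% contingencies that invert
between the options at a reversal trial drawn uniformly from {9, 10, 11}
(0-based; the reversal applies from that trial onward).  Block order is a
uniform random permutation.  Internally, option 0 is always the
initially-better option; trial indices are 0-based within blocks.
Display-side randomization (symbols, screen position, keys) has no effect
on learning dynamics and is not modeled.  The points-to-money conversion
(40 points per dollar) is carried as configuration metadata only.

The participant and the demonstrator draw their outcomes independently
from the same contingency schedule.  Whether the original task yoked the
two players to a common outcome stream is not determinable from the
available description; independence is the weaker assumption and does not
affect any per-subject statistic used here.

## Agents

The demonstrator is a plain Q-learner (softmax temperature β = 10,
learning rate α = 0.5 by default) that learns from its own outcomes only
and resets its values to (0, 0) at each block start.  These defaults make
the demonstrator a competent but fallible player (correct-choice rates
around 0.8 late in stable blocks), so its performance varies across
sessions — which is what makes demonstrator-performance correlations
informative.

The participant model extends Q-learning with two social channels and
context-specific private parameters (β_P, α_P, β_S, α_S, κ, α_O), as
described in the README.  Two indexing conventions matter:

* **Turn order.**  Within a trial the participant chooses first; the
  demonstrator's choice (and outcome, where displayed) is shown
  afterwards and influences the participant from the *next* trial onward.
  The first trial of each block therefore carries no social bias.
* **Channel gating.**  The imitation bias (κ) operates only in
  Social-Choice blocks, and the vicarious update (α_O) only in
  Social-Choice+Outcome blocks.  The bias is applied in probability
  space, after the softmax, to the demonstrator's most recently displayed
  choice, and lasts a single trial.  Whether imitation also operated in
  Social-Choice+Outcome in the original task is ambiguous; the gated
  variant is the default here because the two channels are then
  identified by disjoint trial sets, which is what the recovery analyses
  exploit.

The softmax is implemented as the standard logistic
P(a) = σ(β (Q(a) − Q(b))), i.e. higher-valued options are preferred.  One
compiled kernel implements both simulation and likelihood evaluation, so
the probability a simulated choice was drawn from and the probability the
likelihood assigns to it are bit-identical; with κ = α_O = 0 and shared
private parameters the kernel reduces exactly (not approximately) to
plain Q-learning, which is also how the two-parameter model is evaluated.

## Model fitting

Parameters are estimated per subject by maximizing
LPP = log P(data | θ) + Σ log P(θ_k), with gamma(shape 1.2, scale 5)
priors on temperatures and beta(1.1, 1.1) priors on all rates (log
densities computed analytically).  Optimization runs in transformed space
(log temperatures, logit rates) with L-BFGS-B, 10 restarts drawn from the
priors, gradient tolerance 1e-6, and deterministic seeding.  Numerical
guards: choice probabilities are floored at 1e-9 inside the likelihood
(floored trials are counted and reported on the fit result), and
temperatures are capped at 100 despite their nominally unbounded support
— the likelihood is flat in β well below that cap for 20-trial blocks.

The LPP at the optimum is used directly as the per-subject log-evidence
entering model selection.  An optional Laplace correction (½k·log 2π −
½log|H|, finite-difference Hessian) can be switched on, but is off by
default: with identical priors across subjects and models of different
dimension, the LPP already penalizes the social model by its four extra
prior terms (≈1.87 log-units per subject when the extra parameters are
unidentified), which is the behavior the model-recovery analysis checks.

Group-level comparison uses the variational Dirichlet scheme for
random-effects model selection: posterior model probabilities are the
Dirichlet mean, and exceedance probabilities are estimated from 10^5
Dirichlet draws with a fixed default seed.

When demonstrators themselves are fit (model recovery), their sessions
are recorded as all-Private: a demonstrator sees no social information,
so under the social model its four social-context parameters are
unidentified and shrink to their prior modes (κ, α_O → 0.5) — the
expected signature of an over-parameterized fit.

## Synthetic cohort

The generator emulates a two-sample general-population study (default
2 × 50 subjects, independent draws from one population):

* **Questionnaire scores.**  Depression and anxiety subscale scores are
  integers on 0–21.  Margins are negative-binomial distributions
  truncated to the scale and moment-matched to mean 5.2 / SD 4.5
  (depression) and 6.35 / 4.4 (anxiety) — right-skewed, as community
  samples are.  Dependence is a Gaussian copula with correlation 0.6,
  between the two reported sample estimates (.44 and .74).
* **Parameters.**  Rates follow logit-normal population laws and
  temperatures truncated normals, moment-matched (rates) to the
  population means/SDs reported for this task: β_P 2.20/2.40, α_P
  0.58/0.26, β_S 1.83/1.74, α_S 0.60/0.31, κ 0.13/0.10, α_O 0.46/0.31.
  (Truncation shifts the realized temperature means upward slightly;
  temperatures enter no calibrated quantity.)
* **Depression coupling.**  Only α_S is coupled to depression by default:
  logit(α_S) = μ − b·z_dep + √(σ² − b²)·ε, which preserves the marginal
  law of α_S while shifting it conditionally.  The loading b is
  calibrated by root-finding on a fixed large deterministic sample so the
  realized Pearson correlation between the integer depression score and
  α_S equals the requested value (default −0.25) — targets beyond the
  attainable range raise an error.  A hook allows coupling any rate
  parameter instead, for power studies.
* **Sessions.**  Each subject plays one full schedule against a fresh
  simulated demonstrator.
* **Trust covariate** (optional): a 1–9 rating generated with correlation
  0.3 to κ, as a stand-in for post-test face evaluations.  This is an
  emulation device, not a mechanistic claim.

### What the generator implies for effect sizes

The coupling target is defined on the *generative* α_S.  Propagated
through the task, a −0.25 coupling yields a depression–performance
correlation of only about −0.09 in Social-Choice (the α_S → performance
relation has r ≈ 0.3 and saturates above α_S ≈ 0.4), about −0.05 in
Social-Choice+Outcome (the demonstrator's outcomes partially compensate
a low learning rate), and 0 in Private.  The *sign pattern* —
Social-Choice deficit, attenuated with outcome information, absent in
private learning — is therefore systematic and is what the end-to-end
tests assert at adequate sample sizes.  Individual 2 × 50 studies detect
it unreliably; empirically only about half of seeded replicates show a
Social-Choice correlation that is both negative and larger in magnitude
than the Private one.  Observed studies reporting performance
correlations near −0.33 alongside fitted-parameter correlations near
−0.25 are consistent with a stronger latent coupling (fitted parameters
are attenuated copies of true ones, here r ≈ 0.75), not with a
generative coupling of −0.25; users wanting larger behavioral effects
should raise `coupling_r`.

For the same reason, correlations between observed and model-predicted
correct rates (posterior predictive check) plateau around 0.5–0.7 per
condition under these population SDs: a 40-trial condition estimate
carries binomial noise of about 0.075, comparable to the true
between-subject spread of expected rates.  The check is asserted as
clearly positive and significant, not at any particular magnitude.

## Recovery analyses

**Parameter recovery.**  For each manipulated parameter, datasets of 100
subjects are generated in which that parameter is a deterministic
increasing linear map of a questionnaire-score covariate onto the
parameter's "fitted range", while all other parameters are drawn
uniformly within their ranges.  Fitted ranges default to the central 95%
interval of the population laws above.  The generative covariate–
parameter correlation is therefore 1 by default (a `coupling_strength`
knob interpolates down to 0, which serves as the null calibration), so
the recovered diagonal correlation measures pure estimation attenuation.
After simulation and MAP refitting, every recovered parameter is
Pearson-tested against the covariate at p < .05.

Validation runs use 10 datasets per parameter (6 × 10 × 100 = 6,000
fits); the full-scale design of 100 datasets per parameter changes only
the Monte-Carlo error of the rates.  Sensitivity is summarized by the
diagonal detection rate and the mean diagonal correlation (≈ 0.73).
Specificity is summarized by the *aggregate* false-alarm fraction across
all non-manipulated (dataset, parameter) tests, excluding the known
α_P/β_P trade-off pair.  A per-cell false-alarm bound cannot be
meaningful at 10 datasets per cell: each null cell is an exact 5%-level
test, so with 28 cells of 10 datasets the probability that some cell
shows ≥ 2/10 hits exceeds 0.9 by construction.  The aggregate fraction
(expected ≈ 5–6%, standard error ≈ 1.4% over 280 tests) is the stable
statistic; the per-row dominance of the diagonal over every off-diagonal
entry is asserted in addition.

**Model recovery.**  100 demonstrators are simulated and fit by both
models; random-effects selection should award plain Q-learning
essentially all posterior mass (the social model costs ≈ 1.87 log-units
of prior per subject with nothing to explain).  The reverse direction is
also tested: data simulated with strongly non-neutral κ and α_O are won
by the social model.

**Model simulation.**  `simulate_from_fits` re-simulates each subject
from their fitted parameters with fresh schedules and fresh
demonstrators (so simulated data are independent of experienced
contingencies), averaging correct rates over repetitions, and returns a
table in the same format as observed-data summaries so identical
statistics can run on both.

## Statistics

Per-condition correlations are standard Pearson r with the exact t-test.
The meta-analytic combination of per-sample correlations Fisher-z
transforms each r (variance 1/(n−3)) and pools with DerSimonian–Laird
random-effects weights, with the between-sample variance τ² clipped at
zero — the standard convention, cross-checked against R's metafor in the
test suite.  (The pooling is implemented in-module because the available
Python combiner leaves τ² unclipped, which changes pooled standard
errors for k = 2.)  Means are pooled with 1/SEM² weights through the
same machinery.

The symptom classifier dichotomizes subjects at a depression score ≥ 8
and evaluates a single feature cut-off out-of-sample: per repeat, a
random half-split; candidate cut-offs are midpoints of adjacent sorted
unique training values; the cut-off and direction maximizing
sensitivity + specificity (Youden's J) is chosen, ties resolved to the
median best candidate; evaluation on the held-out half; 100 repeats by
default, reporting mean and s.e.m.  Classifier comparisons use the
pooled-variance two-sample t-test across repeats (df = 2·repeats − 2),
with the degenerate zero-variance case (perfect separation) defined as
t = 0 for equal means.

Mixed-effects logistic regressions and structural equation models are
deliberately not re-implemented: `export_long_table` writes a tidy
per-trial table (subject, condition, trial, correct, scores) for
off-the-shelf mixed-model/SEM software.

## Known limitations

* The generator emulates summary statistics (margins, moments,
  couplings), not item-level questionnaire responses, demographics, or
  attention/engagement failures of online cohorts; real-data effect
  sizes and classifier accuracies need not transfer.
* Temperatures' population law is specified by location/scale before
  truncation; realized means are slightly higher than nominal.
* The likelihood assumes single-trial imitation persistence and gated
  social channels (see above); both are configuration-level modeling
  choices, not established facts about the original task.
* Eligibility traces, forgetting, valence-dependent learning rates and
  reputation dynamics are out of scope.
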