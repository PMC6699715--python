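# socialrl

Social reinforcement learning in a three-context bandit task: simulation,
model fitting, model selection, recovery analyses and cohort-level
statistics.

## The problem

How do depressive symptoms interact with reward learning when another
person is present?  A way to ask this quantitatively is a probabilistic
two-armed bandit played in three information contexts: **Private** (the
subject sees only their own outcomes), **Social-Choice** (the choices of a
demonstrator — another player, here simulated by a Q-learner — are
displayed), and **Social-Choice+Outcome** (the demonstrator's choices *and*
outcomes are displayed).  Each context is played once with stable
reciprocal 30/70% reward contingencies and once with 20/80% contingencies
that reverse mid-block; outcomes are ±1 points.

This package implements the complete computational pipeline for such a
study — task environment, generative agents, maximum-a-posteriori model
fitting, random-effects Bayesian model selection, parameter/model
recovery, and the correlation / meta-analysis / classification stages —
together with a synthetic-cohort generator that emulates a two-sample
(discovery + replication) study, including questionnaire scores and a
negative coupling between depression scores and social-context learning.

## The model

Private learning is classical Q-learning with softmax choice,

    P(a) = 1 / (1 + exp(-β (Q(a) − Q(b))))
    Q(a) ← Q(a) + α (R − Q(a))

with separate (α_P, β_P) in the Private context and (α_S, β_S) in the two
social contexts.  Social information enters through two channels:

* **Imitation** (Social-Choice): the demonstrator's displayed choice
  produces an action prediction error APE = 1 − P(a_dem), which biases the
  next trial's choice probability, P'(a_dem) = P(a_dem) + κ·APE, with
  imitation rate κ ∈ [0, 1].
* **Vicarious learning** (Social-Choice+Outcome): the demonstrator's
  displayed outcome produces an observational prediction error
  OPE = R_dem − Q(a_dem), which updates the value of the demonstrator's
  option with rate α_O.

Subjects are fit by maximizing the log posterior probability
LPP = log P(data | θ) + Σ_k log P(θ_k) with gamma(1.2, 5) priors on
temperatures and beta(1.1, 1.1) priors on rates; LPP serves as the
per-subject evidence in random-effects Bayesian model selection
(variational Dirichlet scheme with Monte-Carlo exceedance probabilities).

## Worked example

```python
import numpy as np
import socialrl as srl

rng = np.random.default_rng(0)

# one synthetic two-sample study (50 + 50 subjects)
cohort = srl.generate_cohort(srl.CohortSpec(), rng)

# model-free analysis: depression vs correct-choice rate, meta-analyzed
report = srl.depression_performance_meta(cohort)
for cond, res in report.items():
    meta = res["meta"]
    print(f"{cond.name:<22} r_meta = {meta.effect:+.3f}  z = {meta.z_stat:+.2f}  p = {meta.p_value:.3f}")

# MAP fit of one subject under the social RL model
fit = srl.fit_subject(cohort.sessions[0])
print({k: round(v, 3) for k, v in fit.params.items()}, round(fit.lpp, 2))
```

prints

```
PRIVATE                r_meta = +0.115  z = +1.02  p = 0.308
SOCIAL_CHOICE          r_meta = -0.069  z = -0.37  p = 0.708
SOCIAL_CHOICE_OUTCOME  r_meta = +0.042  z = +0.41  p = 0.680
{'beta_p': 1.621, 'alpha_p': 0.078, 'beta_s': 1.312, 'alpha_s': 0.968, 'kappa': 0.371, 'alpha_o': 0.57} -63.3
```

The per-subject fit reports the six MAP parameters and the log posterior.
The meta-analytic correlations of a *single* 2 × 50 study are noisy: the
generator's default depression→α_S coupling (r = −0.25) propagates to a
population-level depression–performance correlation of only about −0.09
in Social-Choice, so individual studies of this size frequently miss it.
The systematic pattern is visible at scale — with 1,500 subjects the same
pipeline gives a clearly negative Social-Choice correlation
(r = −0.086, p < .001), a null Private correlation (r = +0.014) and an
attenuated Social-Choice+Outcome correlation (r = −0.008): a deficit
specific to the context where only the demonstrator's choices are shown.

A command-line interface mirrors the library:

```bash
socialrl cohort --n-subjects 50 --n-samples 2 --seed 1 --out out/
socialrl fit --data out/trials.csv --model social --out fits.json
socialrl analyze --trials out/trials.csv --scores out/scores.csv --out report.json
socialrl recover-model --n 100 --seed 1
```

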