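import math

import numpy as np
import pytest
from scipy import stats

import socialrl as s
from socialrl import FitOptions, Model, PriorSpec, SocialRLParams, bms
from socialrl.fitting import log_priors, predictive_check
from socialrl.task import Condition, Contingency, SessionData


def _private_session(n_trials=20, beta=2.0, alpha=0.5, seed=0):
    """A single-block private session from a plain Q-learner."""
    rng = np.random.default_rng(seed)
    q = np.zeros(2)
    choice = np.zeros(n_trials, dtype=int)
    outcome = np.zeros(n_trials)
    for t in range(n_trials):
        p = s.choice_prob(q, beta)
        choice[t] = 0 if rng.random() < p[0] else 1
        outcome[t] = 1.0 if rng.random() < (0.7 if choice[t] == 0 else 0.3) else -1.0
        q = s.q_update(q, choice[t], outcome[t], alpha)
    n = n_trials
    return SessionData(
        block_id=np.zeros(n, dtype=int),
        trial=np.arange(n),
        condition=np.zeros(n, dtype=int),
        contingency=np.zeros(n, dtype=int),
        choice=choice,
        outcome=outcome,
        dem_choice=np.full(n, -1),
        dem_outcome=np.zeros(n),
        correct=choice == 0,
    )


def test_random_policy_loglik(simulated_session):
    """Zero temperatures and no imitation give exactly n * log(0.5)."""
    _, _, sess = simulated_session
    p = SocialRLParams(0.0, 0.5, 0.0, 0.5, 0.0, 0.3)
    ll = s.session_loglik(p, sess)
    assert ll == pytest.approx(len(sess) * math.log(0.5), abs=1e-12)


def test_simulation_likelihood_consistency(simulated_session):
    """The likelihood of simulated data equals the sum of the log choice
    probabilities recorded during simulation, bit-exactly."""
    _, params, sess = simulated_session
    ll = s.session_loglik(params, sess)
    assert ll == sum(sess.logp)


def test_saturated_imitation_likelihood(default_schedule):
    """With kappa = 1 and a perfectly copying participant, Social-Choice
    trials after the first contribute log(1) = 0."""
    dem = s.simulate_demonstrator(default_schedule, rng=np.random.default_rng(3))
    p = SocialRLParams(0.0, 0.5, 0.0, 0.5, 1.0, 0.0)
    sess = s.simulate_participant(default_schedule, dem, p, np.random.default_rng(4))
    sc = sess.condition == int(Condition.SOCIAL_CHOICE)
    first = sess.trial == 0
    contrib = sess.logp[sc]
    assert np.all(contrib[sess.trial[sc] > 0] == 0.0)
    assert np.all(sess.logp[sc & first] == pytest.approx(math.log(0.5)))


def test_prior_densities_match_scipy():
    """The analytic log priors agree with scipy's gamma/beta densities."""
    priors = PriorSpec()
    gamma = stats.gamma(a=1.2, scale=5.0)
    beta = stats.beta(1.1, 1.1)
    for b in (0.05, 0.5, 2.2, 6.0, 30.0):
        assert priors.log_temp_prior(b) == pytest.approx(gamma.logpdf(b), abs=1e-10)
    for x in (0.01, 0.13, 0.5, 0.9, 0.99):
        assert priors.log_rate_prior(x) == pytest.approx(beta.logpdf(x), abs=1e-10)
    assert priors.log_temp_prior(-1.0) == -np.inf
    assert priors.log_rate_prior(1.5) == -np.inf


def test_log_posterior_decomposition(simulated_session):
    _, params, sess = simulated_session
    lpp = s.log_posterior(params, sess)
    ll = s.session_loglik(params, sess)
    pr = sum(
        PriorSpec().log_temp_prior(v) if k.startswith("beta") else PriorSpec().log_rate_prior(v)
        for k, v in zip(
            ("beta_p", "alpha_p", "beta_s", "alpha_s", "kappa", "alpha_o"),
            params.to_array(),
        )
    )
    assert lpp == pytest.approx(ll + pr, abs=1e-10)


def test_log_posterior_outside_support(simulated_session):
    _, _, sess = simulated_session
    assert s.log_posterior({"beta": -1.0, "alpha": 0.5}, sess, Model.QLEARN) == -np.inf


def test_empty_session_posterior_is_prior():
    empty = SessionData(*[np.empty(0, dtype=int)] * 5, np.empty(0), np.empty(0, dtype=int),
                        np.empty(0), np.empty(0, dtype=bool))
    params = {"beta": 2.0, "alpha": 0.5}
    assert s.session_loglik(params, empty, Model.QLEARN) == 0.0
    assert s.log_posterior(params, empty, Model.QLEARN) == pytest.approx(
        log_priors(params, Model.QLEARN, PriorSpec())
    )


def test_fit_matches_grid_search_oracle():
    """On a 2-parameter problem the optimizer must reach at least the best
    LPP found by a dense 41 x 41 grid."""
    sess = _private_session(seed=5)
    grid_best = -np.inf
    for alpha in np.linspace(0.01, 0.99, 41):
        for beta in np.linspace(0.05, 15.0, 41):
            lpp = s.log_posterior({"beta": beta, "alpha": alpha}, sess, Model.QLEARN)
            grid_best = max(grid_best, lpp)
    fit = s.fit_subject(sess, Model.QLEARN)
    assert fit.lpp >= grid_best - 1e-6


def test_fit_determinism(simulated_session):
    _, _, sess = simulated_session
    f1 = s.fit_subject(sess, options=FitOptions(seed=77))
    f2 = s.fit_subject(sess, options=FitOptions(seed=77))
    assert f1.params == f2.params and f1.lpp == f2.lpp


def test_fit_result_invariants(simulated_session):
    _, _, sess = simulated_session
    fit = s.fit_subject(sess)
    assert np.isfinite(fit.lpp)
    assert fit.lpp == pytest.approx(
        fit.loglik + log_priors(fit.params, Model.SOCIAL_RL, PriorSpec()), abs=1e-9
    )
    assert fit.converged


def test_long_session_parameter_recovery():
    """With 200-trial blocks the MAP estimate lands close to the generating
    parameters (rates within 0.1, temperatures within 25%)."""
    cfg = s.TaskConfig(n_trials=200)
    rng = np.random.default_rng(13)
    sch = s.build_schedule(cfg, rng)
    dem = s.simulate_demonstrator(sch, rng=rng)
    truth = SocialRLParams(2.2, 0.58, 1.83, 0.6, 0.13, 0.46)
    sess = s.simulate_participant(sch, dem, truth, rng)
    fit = s.fit_subject(sess, options=FitOptions(seed=1))
    for name in ("alpha_p", "alpha_s", "kappa", "alpha_o"):
        assert fit.params[name] == pytest.approx(getattr(truth, name), abs=0.1)
    for name in ("beta_p", "beta_s"):
        assert fit.params[name] == pytest.approx(getattr(truth, name), rel=0.25)


# ---------------------------------------------------------------------------
# Bayesian model selection


def test_bms_symmetry_identical_evidence():
    L = np.tile([[-1.0, -1.0, -1.0]], (20, 1))
    res = bms(L)
    np.testing.assert_allclose(res.posterior_prob, 1 / 3, atol=1e-8)
    np.testing.assert_allclose(res.exceedance_prob, 1 / 3, atol=0.02)
    assert res.posterior_prob.sum() == pytest.approx(1.0)
    assert res.exceedance_prob.sum() == pytest.approx(1.0)


def test_bms_two_subject_tie():
    res = bms(np.array([[0.0, -1.0], [-1.0, 0.0]]))
    np.testing.assert_allclose(res.posterior_prob, [0.5, 0.5], atol=1e-6)


def test_bms_overwhelming_evidence():
    L = np.zeros((50, 2))
    L[:, 0] = 10.0
    res = bms(L, model_names=("winner", "loser"))
    assert res.posterior_prob[0] > 0.95
    assert res.exceedance_prob[0] > 0.999
    assert res.winner() == "winner"


def test_bms_permutation_equivariance():
    rng = np.random.default_rng(0)
    L = rng.normal(size=(30, 3))
    res = bms(L)
    perm = [2, 0, 1]
    res_p = bms(L[:, perm])
    np.testing.assert_allclose(res_p.posterior_prob, res.posterior_prob[perm], atol=1e-8)
    np.testing.assert_allclose(res_p.exceedance_prob, res.exceedance_prob[perm], atol=0.01)


def test_bms_rejects_bad_input():
    with pytest.raises(ValueError):
        bms(np.array([[np.nan, 0.0], [0.0, 1.0]]))
    with pytest.raises(ValueError):
        bms(np.zeros((1, 2)))


# ---------------------------------------------------------------------------
# Posterior predictive check


def test_predictive_check_recovers_performance(fitted_cohort):
    """Correct rates simulated from fitted parameters track the observed
    per-subject rates in every condition."""
    cohort, fits = fitted_cohort
    res = predictive_check(fits, cohort.sessions, reps=30, rng=np.random.default_rng(5))
    for cond, corr in res.items():
        assert corr.r > 0.25, cond
        assert corr.p_value < 0.05, cond


def test_predictive_check_rejects_bad_reps(fitted_cohort):
    cohort, fits = fitted_cohort
    with pytest.raises(ValueError):
        predictive_check(fits, cohort.sessions, reps=0)


def test_averaging_reduces_simulation_noise(fitted_cohort):
    """More simulation repetitions give predictions closer to the model's
    expected rates, so the observed-predicted correlation does not degrade."""
    cohort, fits = fitted_cohort
    r1, r25 = [], []
    for seed in range(3):
        rng = np.random.default_rng(100 + seed)
        res1 = predictive_check(fits, cohort.sessions, reps=1, rng=rng)
        res25 = predictive_check(fits, cohort.sessions, reps=25, rng=rng)
        r1.append(np.mean([c.r for c in res1.values()]))
        r25.append(np.mean([c.r for c in res25.values()]))
    assert np.mean(r25) >= np.mean(r1) - 0.02
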