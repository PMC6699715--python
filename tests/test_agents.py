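import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import socialrl as s
from socialrl import (
    Condition,
    DemonstratorParams,
    ParameterError,
    SocialRLParams,
    action_pe,
    apply_imitation,
    choice_prob,
    observational_update,
    q_update,
    rpe,
)


@pytest.mark.parametrize(
    "q, beta, expected_p0",
    [
        ((0.3, -0.7), 0.0, 0.5),
        ((1.0, -1.0), 500.0, 1.0),
        ((0.5, 0.0), 2.0, 0.7310585786300049),
    ],
)
def test_softmax_choice_probability(q, beta, expected_p0):
    p = choice_prob(q, beta)
    assert p[0] == pytest.approx(expected_p0, abs=1e-12)
    assert p.sum() == pytest.approx(1.0)


def test_softmax_rejects_negative_temperature():
    with pytest.raises(ParameterError):
        choice_prob((0.0, 0.0), -1.0)


@pytest.mark.parametrize("q, r, expected", [(0.0, 1.0, 1.0), (1.0, 1.0, 0.0), (0.4, -1.0, -1.4)])
def test_reward_prediction_error(q, r, expected):
    assert rpe(q, r) == pytest.approx(expected)


def test_delta_rule_update():
    np.testing.assert_allclose(q_update((0.0, 0.0), 0, 1.0, 0.5), [0.5, 0.0])
    np.testing.assert_allclose(q_update((0.2, -0.3), 1, 1.0, 0.0), [0.2, -0.3])
    np.testing.assert_allclose(q_update((0.2, -0.3), 1, 1.0, 1.0), [0.2, 1.0])
    with pytest.raises(ParameterError):
        q_update((0.0, 0.0), 0, 1.0, 1.5)


@pytest.mark.parametrize("p, expected", [(1.0, 0.0), (0.0, 1.0), (0.4, 0.6)])
def test_action_prediction_error(p, expected):
    assert action_pe(p) == pytest.approx(expected)
    with pytest.raises(ParameterError):
        action_pe(1.2)


def test_imitation_bias():
    np.testing.assert_allclose(apply_imitation((0.4, 0.6), 0, 0.0), [0.4, 0.6])
    np.testing.assert_allclose(apply_imitation((0.4, 0.6), 0, 1.0), [1.0, 0.0])
    np.testing.assert_allclose(apply_imitation((0.4, 0.6), 0, 0.5), [0.7, 0.3])


@settings(deadline=None, max_examples=200)
@given(
    p0=st.floats(0.0, 1.0),
    kappa=st.floats(0.0, 1.0),
    dem=st.integers(0, 1),
)
def test_imitation_bias_stays_a_distribution(p0, kappa, dem):
    """kappa + (1 - kappa) * p is closed in [0, 1]: no clipping ever needed."""
    out = apply_imitation((p0, 1.0 - p0), dem, kappa)
    assert 0.0 <= out[0] <= 1.0 and 0.0 <= out[1] <= 1.0
    assert out.sum() == pytest.approx(1.0)
    assert out[dem] >= p0 if dem == 0 else out[dem] >= 1.0 - p0


def test_imitation_monotone_in_kappa():
    kappas = np.linspace(0, 1, 21)
    probs = [apply_imitation((0.3, 0.7), 0, k)[0] for k in kappas]
    assert np.all(np.diff(probs) > 0)


def test_observational_update_examples():
    np.testing.assert_allclose(observational_update((0.1, 0.2), 1, -1.0, 0.0), [0.1, 0.2])
    np.testing.assert_allclose(observational_update((0.1, 0.0), 1, -1.0, 0.46), [0.1, -0.46])


def test_observational_update_converges_to_reward():
    """Repeated vicarious updates with a constant +1 outcome drive the value
    monotonically to the delta-rule fixed point."""
    q = np.array([0.0, 0.0])
    prev = q[0]
    for _ in range(50):
        q = observational_update(q, 0, 1.0, 0.3)
        assert q[0] > prev
        prev = q[0]
    assert q[0] == pytest.approx(1.0, abs=1e-6)
    assert q[1] == 0.0


@settings(deadline=None, max_examples=100)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 1), st.sampled_from([-1.0, 1.0]), st.floats(0, 1)),
        min_size=1,
        max_size=60,
    )
)
def test_q_values_stay_bounded(data):
    """With +/-1 rewards, zero initialization and rates in [0, 1], values
    never leave [-1, 1]."""
    q = np.zeros(2)
    for choice, r, alpha in data:
        q = q_update(q, choice, r, alpha)
        assert np.all(np.abs(q) <= 1.0 + 1e-12)


def test_demonstrator_learns_stable_block():
    """A Q-learner with alpha=0.5, beta=10 climbs well above chance on a
    stable 30/70 block; a zero-temperature learner stays at chance."""
    from socialrl.task import Contingency

    rng = np.random.default_rng(3)
    cfg = s.TaskConfig()
    rates = np.zeros(20)
    n_blocks = 400
    for _ in range(n_blocks):
        sch = s.build_schedule(cfg, rng)
        dem = s.simulate_demonstrator(sch, rng=rng)
        arrays = sch.trial_arrays()
        stable = arrays["contingency"] == int(Contingency.STABLE_30_70)
        correct = (dem.choices == np.where(arrays["p0"] >= arrays["p1"], 0, 1))[stable]
        rates += correct.reshape(3, 20).mean(axis=0)
    curve = rates / n_blocks
    assert curve[:2].mean() < 0.65
    assert 0.7 < curve[-5:].mean() < 0.95

    flat = []
    for _ in range(100):
        sch = s.build_schedule(cfg, rng)
        dem = s.simulate_demonstrator(sch, DemonstratorParams(alpha=0.5, beta=0.0), rng)
        flat.append(dem.correct_rate())
    assert abs(np.mean(flat) - 0.5) < 0.03


def test_same_seed_identical_streams(default_schedule):
    d1 = s.simulate_demonstrator(default_schedule, rng=np.random.default_rng(9))
    d2 = s.simulate_demonstrator(default_schedule, rng=np.random.default_rng(9))
    np.testing.assert_array_equal(d1.choices, d2.choices)
    np.testing.assert_array_equal(d1.outcomes, d2.outcomes)

    p = SocialRLParams(2.0, 0.5, 2.0, 0.5, 0.1, 0.4)
    s1 = s.simulate_participant(default_schedule, d1, p, np.random.default_rng(10))
    s2 = s.simulate_participant(default_schedule, d1, p, np.random.default_rng(10))
    np.testing.assert_array_equal(s1.choice, s2.choice)
    np.testing.assert_array_equal(s1.outcome, s2.outcome)


def test_neutral_social_parameters_reduce_to_qlearner(default_schedule):
    """With kappa = alpha_o = 0 and shared private parameters, the social
    model's behavior and likelihood coincide bit-exactly with plain
    Q-learning on the same random stream."""
    dem = s.simulate_demonstrator(default_schedule, rng=np.random.default_rng(5))
    neutral = DemonstratorParams(alpha=0.6, beta=3.0).as_social()
    sess = s.simulate_participant(default_schedule, dem, neutral, np.random.default_rng(6))
    ll_social = s.session_loglik(neutral, sess, s.Model.SOCIAL_RL)
    ll_q = s.session_loglik({"beta": 3.0, "alpha": 0.6}, sess, s.Model.QLEARN)
    assert ll_social == ll_q


def test_full_imitation_copies_demonstrator(default_schedule):
    """kappa = 1 makes the participant reproduce the demonstrator's previous
    choice with probability 1 in Social-Choice blocks."""
    dem = s.simulate_demonstrator(default_schedule, rng=np.random.default_rng(7))
    p = SocialRLParams(2.0, 0.5, 2.0, 0.5, 1.0, 0.0)
    sess = s.simulate_participant(default_schedule, dem, p, np.random.default_rng(8))
    sc = sess.condition == int(Condition.SOCIAL_CHOICE)
    idx = np.flatnonzero(sc)
    for i in idx:
        if sess.trial[i] == 0:
            continue  # nothing displayed yet on the first trial
        assert sess.choice[i] == sess.dem_choice[i - 1]


def test_missing_demonstrator_stream_rejected(default_schedule):
    p = SocialRLParams(2.0, 0.5, 2.0, 0.5, 0.1, 0.4)
    with pytest.raises(ValueError):
        s.simulate_participant(default_schedule, None, p, np.random.default_rng(0))


def test_good_demonstrators_help_social_learning_only():
    """Across many sessions, the demonstrator's correct rate predicts the
    participant's correct rate in the social conditions but not in the
    Private condition."""
    rng = np.random.default_rng(21)
    cfg = s.TaskConfig()
    p = SocialRLParams(2.2, 0.58, 1.83, 0.6, 0.13, 0.46)
    dem_rate, part = [], {c: [] for c in Condition}
    for _ in range(300):
        sch = s.build_schedule(cfg, rng)
        dem = s.simulate_demonstrator(sch, rng=rng)
        sess = s.simulate_participant(sch, dem, p, rng)
        dem_rate.append(dem.correct_rate())
        for c in Condition:
            part[c].append(sess.correct_rate(c))
    r = {c: np.corrcoef(dem_rate, part[c])[0, 1] for c in Condition}
    assert r[Condition.SOCIAL_CHOICE] > 0.1
    assert r[Condition.SOCIAL_CHOICE_OUTCOME] > 0.1
    assert abs(r[Condition.PRIVATE]) < 0.12
    assert r[Condition.SOCIAL_CHOICE] > r[Condition.PRIVATE]
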