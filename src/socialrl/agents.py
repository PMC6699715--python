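"""Generative agents: the demonstrator Q-learner and the social RL model.

The participant model is a Q-learner extended with two social channels:

* **imitation** -- in Social-Choice blocks the probability of the option
  the demonstrator last chose is inflated by ``kappa`` times the action
  prediction error (how surprising that choice was);
* **vicarious learning** -- in Social-Choice+Outcome blocks the
  demonstrator's displayed outcome updates the value of the option the
  demonstrator chose, with rate ``alpha_o``.

The model further allows private learning itself to differ between the
Private context (``alpha_p``, ``beta_p``) and the two social contexts
(``alpha_s``, ``beta_s``), so a "negative audience effect" (worse private
learning merely because social information is on screen) is expressible
separately from deficits of the social channels themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .task import Condition, ExperimentSchedule, SessionData


class ParameterError(ValueError):
    """Raised when a model parameter is outside its admissible range."""


PARAM_NAMES = ("beta_p", "alpha_p", "beta_s", "alpha_s", "kappa", "alpha_o")
#: which parameters are softmax temperatures (the rest are rates in [0, 1])
TEMPERATURE_PARAMS = ("beta_p", "beta_s")


@dataclass(frozen=True)
class SocialRLParams:
    """The six parameters of the social reinforcement-learning model.

    beta_p, beta_s : softmax temperatures (> 0) in the Private / Social
        contexts; alpha_p, alpha_s : private learning rates in [0, 1];
    kappa : imitation rate in [0, 1]; alpha_o : observational (vicarious)
        learning rate in [0, 1].
    """

    beta_p: float
    alpha_p: float
    beta_s: float
    alpha_s: float
    kappa: float
    alpha_o: float

    def __post_init__(self) -> None:
        for name in TEMPERATURE_PARAMS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v}")
        for name in ("alpha_p", "alpha_s", "kappa", "alpha_o"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, values) -> "SocialRLParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))


@dataclass(frozen=True)
class DemonstratorParams:
    """Plain Q-learner parameters; defaults drive the virtual demonstrator."""

    alpha: float = 0.5
    beta: float = 10.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta) or self.beta < 0:
            raise ParameterError(f"beta must be finite and >= 0, got {self.beta}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError(f"alpha must lie in [0, 1], got {self.alpha}")

    def as_social(self) -> SocialRLParams:
        """Embed the 2-parameter model in the social parameter space.

        With ``kappa = alpha_o = 0`` and shared private parameters the
        social model's trial-wise policy reduces exactly to plain
        Q-learning, so one likelihood kernel serves both models.
        """
        return SocialRLParams(
            beta_p=self.beta,
            alpha_p=self.alpha,
            beta_s=self.beta,
            alpha_s=self.alpha,
            kappa=0.0,
            alpha_o=0.0,
        )


def choice_prob(q, beta: float) -> np.ndarray:
    """Softmax over the two action values: P(a) = 1/(1+exp(-beta*(q_a-q_b)))."""
    if beta < 0 or not np.isfinite(beta):
        raise ParameterError(f"beta must be finite and >= 0, got {beta}")
    q = np.asarray(q, dtype=float)
    if q.shape != (2,) or not np.all(np.isfinite(q)):
        raise ParameterError(f"q must be a finite pair, got {q}")
    p0 = 1.0 / (1.0 + np.exp(-beta * (q[0] - q[1])))
    return np.array([p0, 1.0 - p0])


def rpe(q_chosen: float, r: float) -> float:
    """Reward prediction error: received reward minus current value."""
    return r - q_chosen


def q_update(q, choice: int, r: float, alpha: float) -> np.ndarray:
    """Delta-rule update of the chosen option's value; the other is untouched."""
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError(f"alpha must lie in [0, 1], got {alpha}")
    q = np.asarray(q, dtype=float).copy()
    q[choice] = q[choice] + alpha * (r - q[choice])
    return q


def action_pe(p_dem_action: float) -> float:
    """Action prediction error: 1 minus the policy's probability of the
    demonstrator's observed choice (a surprise signal about actions)."""
    if not 0.0 <= p_dem_action <= 1.0:
        raise ParameterError(f"probability must lie in [0, 1], got {p_dem_action}")
    return 1.0 - p_dem_action


def apply_imitation(p, dem_choice: int, kappa: float) -> np.ndarray:
    """Bias the choice distribution toward the demonstrator's choice.

    P'(dem) = P(dem) + kappa * (1 - P(dem)); the other option takes the
    complement.  Closed under [0, 1] for kappa in [0, 1] -- no clipping.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ParameterError(f"kappa must lie in [0, 1], got {kappa}")
    p = np.asarray(p, dtype=float).copy()
    p[dem_choice] = p[dem_choice] + kappa * action_pe(p[dem_choice])
    p[1 - dem_choice] = 1.0 - p[dem_choice]
    return p


def observational_update(q, dem_choice: int, r_dem: float, alpha_o: float) -> np.ndarray:
    """Vicarious delta-rule update from the demonstrator's displayed outcome."""
    return q_update(q, dem_choice, r_dem, alpha_o)


class DemStream:
    """Per-trial choices and outcomes of a simulated demonstrator."""

    def __init__(self, schedule: ExperimentSchedule, choices, outcomes) -> None:
        self.schedule = schedule
        self.choices = np.asarray(choices, dtype=np.int64)
        self.outcomes = np.asarray(outcomes, dtype=np.float64)
        if len(self.choices) != schedule.n_total:
            raise ValueError("demonstrator stream misaligned with schedule")

    def correct_rate(self) -> float:
        arrays = self.schedule.trial_arrays()
        correct = np.where(arrays["p0"] >= arrays["p1"], 0, 1)
        return float((self.choices == correct).mean())

    def to_session(self) -> SessionData:
        """The demonstrator's own play as a fittable session.

        The demonstrator sees no social information, so all blocks are
        recorded as Private regardless of what the paired participant saw.
        """
        a = self.schedule.trial_arrays()
        n = len(self.choices)
        correct = self.choices == np.where(a["p0"] >= a["p1"], 0, 1)
        return SessionData(
            block_id=a["block_id"],
            trial=a["trial"],
            condition=np.zeros(n, dtype=np.int64),
            contingency=a["contingency"],
            choice=self.choices,
            outcome=self.outcomes,
            dem_choice=np.full(n, -1, dtype=np.int64),
            dem_outcome=np.zeros(n),
            correct=correct,
            p0=a["p0"],
            p1=a["p1"],
        )


def simulate_demonstrator(
    schedule: ExperimentSchedule,
    params: DemonstratorParams | None = None,
    rng: np.random.Generator | None = None,
) -> DemStream:
    """Play every block of ``schedule`` as a plain Q-learner.

    The demonstrator learns only from its own outcomes; values reset to
    (0, 0) at each block start.
    """
    params = params or DemonstratorParams()
    rng = rng if rng is not None else np.random.default_rng()
    a = schedule.trial_arrays()
    n = schedule.n_total
    u_choice = rng.random(n)
    u_outcome = rng.random(n)
    choices = np.zeros(n, dtype=np.int64)
    outcomes = np.zeros(n, dtype=np.float64)
    _kernel.run_qlearner(
        a["block_id"], a["p0"], a["p1"], params.beta, params.alpha,
        u_choice, u_outcome, choices, outcomes,
    )
    return DemStream(schedule, choices, outcomes)


def simulate_participant(
    schedule: ExperimentSchedule,
    dem_stream: DemStream | None,
    params: SocialRLParams,
    rng: np.random.Generator,
    subject_id=None,
) -> SessionData:
    """Simulate one participant session under the social RL model.

    Private blocks use (``alpha_p``, ``beta_p``) only.  Social-Choice blocks
    add the imitation bias from the most recently displayed demonstrator
    choice; Social-Choice+Outcome blocks add the vicarious value update from
    the displayed demonstrator outcome.  The first trial of each block
    carries no social bias (nothing displayed yet).

    The per-trial log choice probabilities are recorded in the returned
    session's ``logp``; summing them reproduces the model log-likelihood of
    the simulated data exactly.
    """
    a = schedule.trial_arrays()
    n = schedule.n_total
    cond = a["condition"]
    needs_dem = (cond != int(Condition.PRIVATE)).any()
    if needs_dem and dem_stream is None:
        raise ValueError("schedule contains social blocks but no demonstrator stream")
    if dem_stream is not None and dem_stream.schedule is not schedule:
        if dem_stream.schedule.trial_arrays()["condition"].shape != cond.shape:
            raise ValueError("demonstrator stream misaligned with schedule")
    # mask the demonstrator fields down to what is actually displayed
    dem_choice = np.full(n, -1, dtype=np.int64)
    dem_outcome = np.zeros(n, dtype=np.float64)
    if dem_stream is not None:
        social = cond != int(Condition.PRIVATE)
        dem_choice[social] = dem_stream.choices[social]
        shown = cond == int(Condition.SOCIAL_CHOICE_OUTCOME)
        dem_outcome[shown] = dem_stream.outcomes[shown]

    u_choice = rng.random(n)
    u_outcome = rng.random(n)
    choices = np.zeros(n, dtype=np.int64)
    outcomes = np.zeros(n, dtype=np.float64)
    logp = np.zeros(n, dtype=np.float64)
    _kernel.run_session(
        a["block_id"], cond, a["p0"], a["p1"], dem_choice, dem_outcome,
        choices, outcomes,
        params.beta_p, params.alpha_p, params.beta_s, params.alpha_s,
        params.kappa, params.alpha_o,
        _kernel.MODE_SIM, u_choice, u_outcome, choices, outcomes, logp,
    )
    correct = choices == np.where(a["p0"] >= a["p1"], 0, 1)
    return SessionData(
        block_id=a["block_id"],
        trial=a["trial"],
        condition=cond,
        contingency=a["contingency"],
        choice=choices,
        outcome=outcomes,
        dem_choice=dem_choice,
        dem_outcome=dem_outcome,
        correct=correct,
        p0=a["p0"],
        p1=a["p1"],
        logp=logp,
        subject_id=subject_id,
    )
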