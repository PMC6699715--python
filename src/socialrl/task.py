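"""Three-context probabilistic instrumental learning task.

The environment is a repeated two-armed bandit played in six blocks.  Each
block pairs one of three information conditions (Private, Social-Choice,
Social-Choice+Outcome) with one of two reward contingencies:

* ``STABLE_30_70`` -- reciprocal 30/70% reward probabilities, fixed for the
  whole block;
* ``REVERSAL_20_80`` -- reciprocal 20/80% probabilities that swap between
  the two options once, around the middle of the block.

Outcomes are +1 or -1 points.  Internally option 0 is always the
initially-better option; presentation-side randomization (symbols, screen
side) is out of scope and irrelevant to the learning dynamics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd


class Condition(enum.IntEnum):
    """Information condition of a learning block."""

    PRIVATE = 0
    SOCIAL_CHOICE = 1
    SOCIAL_CHOICE_OUTCOME = 2


class Contingency(enum.IntEnum):
    """Reward-probability regime of a block."""

    STABLE_30_70 = 0
    REVERSAL_20_80 = 1


#: CSV column order for trial logs.
TRIAL_COLUMNS = [
    "subject_id",
    "block_id",
    "condition",
    "contingency",
    "trial",
    "participant_choice",
    "participant_outcome",
    "demonstrator_choice",
    "demonstrator_outcome",
    "correct",
]


class ConfigurationError(ValueError):
    """Raised for invalid task configurations."""


def _check_prob_pair(p: Sequence[float], name: str) -> tuple[float, float]:
    p = (float(p[0]), float(p[1]))
    if not (0.0 < p[0] < 1.0 and 0.0 < p[1] < 1.0):
        raise ConfigurationError(f"{name} entries must lie in (0, 1), got {p}")
    if abs(p[0] + p[1] - 1.0) > 1e-12:
        raise ConfigurationError(f"{name} must be reciprocal (sum to 1), got {p}")
    return p


@dataclass(frozen=True)
class TaskConfig:
    """Ground-truth parameters of the experiment.

    Parameters
    ----------
    n_trials
        Trials per block (default 20).
    stable_probs
        Reward probabilities (better option first) in stable blocks.
    reversal_probs
        Reward probabilities (initially-better option first) in reversal
        blocks; they swap between options at the reversal trial.
    reversal_window
        Inclusive 0-based range from which the reversal trial is drawn
        uniformly, i.e. the contingency inverts around the middle of the
        block, give or take one trial.
    points_per_dollar
        Conversion of accumulated points to bonus money.  Metadata only.
    """

    n_trials: int = 20
    stable_probs: tuple[float, float] = (0.7, 0.3)
    reversal_probs: tuple[float, float] = (0.8, 0.2)
    reversal_window: tuple[int, int] = (9, 11)
    points_per_dollar: float = 40.0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        _check_prob_pair(self.stable_probs, "stable_probs")
        _check_prob_pair(self.reversal_probs, "reversal_probs")
        lo, hi = self.reversal_window
        if not (0 <= lo <= hi):
            raise ConfigurationError("invalid reversal_window")


@dataclass(frozen=True)
class BlockSchedule:
    """One learning block: condition, contingency and reward probabilities.

    ``p_reward`` is the probability of a +1 outcome for (option 0, option 1)
    *before* any reversal; option 0 is the initially-better option.  For
    reversal blocks the probabilities swap between options from
    ``reversal_trial`` (0-based, inclusive) onward.
    """

    block_id: int
    condition: Condition
    contingency: Contingency
    p_reward: tuple[float, float]
    reversal_trial: int | None
    n_trials: int = 20

    def __post_init__(self) -> None:
        _check_prob_pair(self.p_reward, "p_reward")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.contingency == Contingency.REVERSAL_20_80:
            if self.reversal_trial is None:
                raise ConfigurationError("reversal block requires reversal_trial")
            if not (0 < self.reversal_trial < self.n_trials):
                raise ConfigurationError(
                    f"reversal_trial {self.reversal_trial} infeasible for "
                    f"block of {self.n_trials} trials"
                )
        elif self.reversal_trial is not None:
            raise ConfigurationError("stable block must not set reversal_trial")

    def option_probs(self, t: int) -> tuple[float, float]:
        """Reward probabilities of (option 0, option 1) at trial ``t``."""
        if not 0 <= t < self.n_trials:
            raise IndexError(f"trial {t} out of range [0, {self.n_trials})")
        p0, p1 = self.p_reward
        if self.reversal_trial is not None and t >= self.reversal_trial:
            p0, p1 = p1, p0
        return p0, p1

    def correct_option(self, t: int) -> int:
        """Currently-majority-rewarded option at trial ``t``."""
        p0, p1 = self.option_probs(t)
        return 0 if p0 >= p1 else 1


@dataclass(frozen=True)
class ExperimentSchedule:
    """Ordered sequence of the six blocks one subject plays."""

    blocks: tuple[BlockSchedule, ...]

    def __post_init__(self) -> None:
        pairs = {(b.condition, b.contingency) for b in self.blocks}
        if len(self.blocks) != 6 or len(pairs) != 6:
            raise ConfigurationError(
                "schedule must contain each condition x contingency pair exactly once"
            )

    def __iter__(self) -> Iterator[BlockSchedule]:
        return iter(self.blocks)

    @property
    def n_total(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def trial_arrays(self) -> dict[str, np.ndarray]:
        """Flat per-trial arrays used by the simulation/likelihood kernel."""
        n = self.n_total
        block_id = np.empty(n, dtype=np.int64)
        trial = np.empty(n, dtype=np.int64)
        cond = np.empty(n, dtype=np.int64)
        conting = np.empty(n, dtype=np.int64)
        p0 = np.empty(n, dtype=np.float64)
        p1 = np.empty(n, dtype=np.float64)
        i = 0
        for b in self.blocks:
            for t in range(b.n_trials):
                block_id[i] = b.block_id
                trial[i] = t
                cond[i] = int(b.condition)
                conting[i] = int(b.contingency)
                p0[i], p1[i] = b.option_probs(t)
                i += 1
        return {
            "block_id": block_id,
            "trial": trial,
            "condition": cond,
            "contingency": conting,
            "p0": p0,
            "p1": p1,
        }


def build_schedule(
    config: TaskConfig, rng: np.random.Generator
) -> ExperimentSchedule:
    """Draw one subject's block schedule.

    Each of the three conditions appears twice, once stable and once with a
    reversal; the block order is a uniform random permutation and the
    reversal trial of every reversal block is drawn uniformly from the
    configured window.
    """
    lo, hi = config.reversal_window
    if hi >= config.n_trials:
        raise ConfigurationError(
            f"reversal window {config.reversal_window} infeasible for "
            f"{config.n_trials}-trial blocks"
        )
    specs = [
        (cond, conting)
        for cond in Condition
        for conting in (Contingency.STABLE_30_70, Contingency.REVERSAL_20_80)
    ]
    order = rng.permutation(len(specs))
    blocks = []
    for block_id, idx in enumerate(order):
        cond, conting = specs[idx]
        if conting == Contingency.REVERSAL_20_80:
            reversal = int(rng.integers(lo, hi + 1))
            probs = config.reversal_probs
        else:
            reversal = None
            probs = config.stable_probs
        blocks.append(
            BlockSchedule(
                block_id=block_id,
                condition=cond,
                contingency=conting,
                p_reward=probs,
                reversal_trial=reversal,
                n_trials=config.n_trials,
            )
        )
    return ExperimentSchedule(blocks=tuple(blocks))


def draw_outcome(
    schedule: BlockSchedule, t: int, choice: int, rng: np.random.Generator
) -> int:
    """Sample the +/-1 outcome of ``choice`` at trial ``t`` of a block."""
    p = schedule.option_probs(t)[choice]
    return 1 if rng.random() < p else -1


class SessionData:
    """Per-trial record of one subject's full session.

    Arrays are aligned across the whole session (all blocks concatenated).
    ``demonstrator_choice`` is -1 and ``demonstrator_outcome`` is 0 where the
    corresponding information was not displayed (Private blocks; outcomes
    also in Social-Choice blocks).  ``logp`` holds the log choice
    probabilities recorded during simulation and is ``None`` for imported
    data.
    """

    def __init__(
        self,
        block_id: np.ndarray,
        trial: np.ndarray,
        condition: np.ndarray,
        contingency: np.ndarray,
        choice: np.ndarray,
        outcome: np.ndarray,
        dem_choice: np.ndarray,
        dem_outcome: np.ndarray,
        correct: np.ndarray,
        p0: np.ndarray | None = None,
        p1: np.ndarray | None = None,
        logp: np.ndarray | None = None,
        subject_id: str | int | None = None,
    ) -> None:
        self.block_id = np.asarray(block_id, dtype=np.int64)
        self.trial = np.asarray(trial, dtype=np.int64)
        self.condition = np.asarray(condition, dtype=np.int64)
        self.contingency = np.asarray(contingency, dtype=np.int64)
        self.choice = np.asarray(choice, dtype=np.int64)
        self.outcome = np.asarray(outcome, dtype=np.float64)
        self.dem_choice = np.asarray(dem_choice, dtype=np.int64)
        self.dem_outcome = np.asarray(dem_outcome, dtype=np.float64)
        self.correct = np.asarray(correct, dtype=bool)
        self.p0 = None if p0 is None else np.asarray(p0, dtype=np.float64)
        self.p1 = None if p1 is None else np.asarray(p1, dtype=np.float64)
        self.logp = None if logp is None else np.asarray(logp, dtype=np.float64)
        self.subject_id = subject_id
        self._validate()

    def _validate(self) -> None:
        n = len(self.block_id)
        for name in ("trial", "condition", "contingency", "choice", "outcome",
                     "dem_choice", "dem_outcome", "correct"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array {name!r} misaligned with block_id")
        if not np.isin(self.choice, [0, 1]).all():
            raise ValueError("participant choices must be 0 or 1")
        if not np.isin(self.outcome, [-1.0, 1.0]).all():
            raise ValueError("outcomes must be -1 or +1")
        priv = self.condition == int(Condition.PRIVATE)
        if (self.dem_choice[priv] != -1).any():
            raise ValueError("demonstrator choice present in a Private block")
        if (self.dem_choice[~priv] < 0).any():
            raise ValueError("demonstrator choice missing in a social block")
        sco = self.condition == int(Condition.SOCIAL_CHOICE_OUTCOME)
        if not np.isin(self.dem_outcome[sco], [-1.0, 1.0]).all():
            raise ValueError("demonstrator outcome missing in Social-Choice+Outcome")
        if (self.dem_outcome[~sco] != 0.0).any():
            raise ValueError("demonstrator outcome displayed outside Social-Choice+Outcome")

    def __len__(self) -> int:
        return len(self.block_id)

    def correct_rate(self, condition: Condition | None = None) -> float:
        """Fraction of correct choices, optionally within one condition."""
        mask = (
            np.ones(len(self), dtype=bool)
            if condition is None
            else self.condition == int(condition)
        )
        return float(self.correct[mask].mean())

    def correct_rates_by_condition(self) -> dict[Condition, float]:
        return {c: self.correct_rate(c) for c in Condition}

    def to_frame(self, subject_id: str | int | None = None) -> pd.DataFrame:
        """Export the session as a tidy trial log (CSV dialect).

        Missing social fields are encoded as missing values so they
        serialize to empty CSV cells.
        """
        sid = subject_id if subject_id is not None else self.subject_id
        dem_choice = self.dem_choice.astype(float)
        dem_choice[dem_choice < 0] = np.nan
        dem_outcome = self.dem_outcome.copy()
        dem_outcome[self.condition != int(Condition.SOCIAL_CHOICE_OUTCOME)] = np.nan
        return pd.DataFrame(
            {
                "subject_id": sid,
                "block_id": self.block_id,
                "condition": [Condition(c).name for c in self.condition],
                "contingency": [Contingency(c).name for c in self.contingency],
                "trial": self.trial,
                "participant_choice": self.choice,
                "participant_outcome": self.outcome.astype(int),
                "demonstrator_choice": dem_choice,
                "demonstrator_outcome": dem_outcome,
                "correct": self.correct.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, subject_id=None) -> "SessionData":
        """Rebuild a session from the tidy trial log of one subject."""
        f = frame.sort_values(["block_id", "trial"]).reset_index(drop=True)
        cond = np.array([int(Condition[c]) for c in f["condition"]])
        conting = np.array([int(Contingency[c]) for c in f["contingency"]])
        dem_choice = f["demonstrator_choice"].to_numpy(dtype=float)
        dem_choice = np.where(np.isnan(dem_choice), -1, dem_choice).astype(np.int64)
        dem_outcome = f["demonstrator_outcome"].to_numpy(dtype=float)
        dem_outcome = np.where(np.isnan(dem_outcome), 0.0, dem_outcome)
        return cls(
            block_id=f["block_id"].to_numpy(),
            trial=f["trial"].to_numpy(),
            condition=cond,
            contingency=conting,
            choice=f["participant_choice"].to_numpy(),
            outcome=f["participant_outcome"].to_numpy(dtype=float),
            dem_choice=dem_choice,
            dem_outcome=dem_outcome,
            correct=f["correct"].to_numpy(dtype=bool),
            subject_id=subject_id,
        )


def sessions_to_frame(
    sessions: Sequence[SessionData], subject_ids: Sequence | None = None
) -> pd.DataFrame:
    """Concatenate sessions into one long trial log."""
    frames = []
    for i, s in enumerate(sessions):
        sid = subject_ids[i] if subject_ids is not None else (s.subject_id or i)
        frames.append(s.to_frame(subject_id=sid))
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def read_sessions_csv(path) -> list[SessionData]:
    """Read a trial-log CSV into one :class:`SessionData` per subject."""
    df = pd.read_csv(path)
    return [
        SessionData.from_frame(g, subject_id=sid)
        for sid, g in df.groupby("subject_id", sort=True)
    ]
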