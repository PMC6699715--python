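"""Validation machinery: parameter recovery, model recovery, simulation.

Parameter recovery asks whether a correlation between a covariate (e.g. a
questionnaire score) and one model parameter, imposed in simulation, is
detected on the *recovered* parameters after refitting -- and whether it
leaks into the other parameters (false alarms).  Model recovery checks
that group-level model selection picks plain Q-learning when the data
really come from plain Q-learners (the simulated demonstrators).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import PARAM_NAMES, DemonstratorParams, SocialRLParams, simulate_demonstrator, simulate_participant
from .analysis import pearson_correlation
from .cohort import DEFAULT_POPULATION, ParamPopulation, ScoreMargin
from .fitting import BMSResult, FitOptions, FitResult, Model, bms, fit_subject
from .task import Condition, TaskConfig, build_schedule


@dataclass(frozen=True)
class RecoveryDesign:
    """Design of the parameter-recovery simulation.

    Per manipulated parameter, ``n_datasets`` synthetic samples of
    ``n_subjects`` are generated in which that parameter follows the
    covariate with strength ``coupling_strength`` (1.0: deterministic
    linear map of the covariate onto the parameter's fitted range; 0.0:
    independent), while every other parameter is drawn uniformly within
    its fitted range.  Fitted ranges default to the central 95% population
    interval.
    """

    n_datasets: int = 100
    n_subjects: int = 100
    coupling_strength: float = 1.0
    alpha_level: float = 0.05
    param_ranges: dict | None = None
    parameters: tuple[str, ...] = PARAM_NAMES
    covariate_margin: ScoreMargin = field(default_factory=lambda: ScoreMargin(5.2, 4.5))
    population: ParamPopulation = field(default_factory=ParamPopulation)
    task: TaskConfig = field(default_factory=TaskConfig)
    dem_params: DemonstratorParams = field(default_factory=DemonstratorParams)
    fit_options: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self) -> None:
        if self.n_datasets < 1 or self.n_subjects < 3:
            raise ValueError("counts must be positive (and n_subjects >= 3)")
        if not 0.0 < self.alpha_level < 1.0:
            raise ValueError("alpha_level must lie in (0, 1)")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        unknown = set(self.parameters) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters {unknown}")

    def ranges(self) -> dict[str, tuple[float, float]]:
        if self.param_ranges is not None:
            return dict(self.param_ranges)
        return {name: self.population.interval(name) for name in PARAM_NAMES}


@dataclass
class RecoveryMatrix:
    """Detection rates of covariate correlations after refitting.

    Rows: manipulated parameter.  Columns: recovered parameter tested
    against the covariate.  The diagonal measures sensitivity, the
    off-diagonal entries are false alarms.  ``mean_r`` holds the mean
    recovered correlation coefficients (signed).
    """

    detection_rate: pd.DataFrame
    mean_r: pd.DataFrame
    n_datasets: int
    n_subjects: int

    def diagonal_detection(self) -> pd.Series:
        return pd.Series(np.diag(self.detection_rate), index=self.detection_rate.index)

    def mean_diagonal_r(self) -> float:
        return float(np.mean(np.diag(self.mean_r)))

    def max_false_alarm(self, exclude: tuple[tuple[str, str], ...] = (("alpha_p", "beta_p"),)) -> float:
        """Largest off-diagonal detection rate, excluding the listed pairs
        (both orientations)."""
        excluded = {frozenset(p) for p in exclude}
        worst = 0.0
        for row in self.detection_rate.index:
            for col in self.detection_rate.columns:
                if row == col or frozenset((row, col)) in excluded:
                    continue
                worst = max(worst, float(self.detection_rate.loc[row, col]))
        return worst


def _simulate_and_fit(
    true_params: np.ndarray,
    design: RecoveryDesign,
    rng: np.random.Generator,
    fit_seed: int,
) -> np.ndarray:
    """Simulate sessions for a sample of subjects and refit the social model."""
    n = true_params.shape[0]
    recovered = np.empty_like(true_params)
    for i in range(n):
        p = SocialRLParams(**dict(zip(PARAM_NAMES, true_params[i])))
        schedule = build_schedule(design.task, rng)
        dem = simulate_demonstrator(schedule, design.dem_params, rng)
        session = simulate_participant(schedule, dem, p, rng)
        opts = FitOptions(
            n_restarts=design.fit_options.n_restarts,
            seed=(fit_seed + 7919 * i) % (2**31 - 1),
            maxiter=design.fit_options.maxiter,
            gtol=design.fit_options.gtol,
        )
        fit = fit_subject(session, Model.SOCIAL_RL, options=opts)
        recovered[i] = [fit.params[k] for k in PARAM_NAMES]
    return recovered


def parameter_recovery(
    design: RecoveryDesign, rng: np.random.Generator
) -> RecoveryMatrix:
    """Run the full recovery grid and aggregate detection rates.

    For each manipulated parameter and dataset, the covariate is drawn
    from the score margin, the manipulated parameter is mapped onto its
    fitted range, sessions are simulated and refit, and every recovered
    parameter is Pearson-tested against the covariate at ``alpha_level``.
    """
    ranges = design.ranges()
    k = len(design.parameters)
    names = list(design.parameters)
    all_names = list(PARAM_NAMES)
    detect = np.zeros((k, len(all_names)))
    mean_r = np.zeros((k, len(all_names)))
    for row, manip in enumerate(names):
        for _ds in range(design.n_datasets):
            cov = design.covariate_margin.rvs(design.n_subjects, rng)
            while np.ptp(cov) == 0:  # degenerate draw; retry
                cov = design.covariate_margin.rvs(design.n_subjects, rng)
            true = np.empty((design.n_subjects, len(all_names)))
            for j, name in enumerate(all_names):
                lo, hi = ranges[name]
                if name == manip:
                    linear = lo + (hi - lo) * (cov - cov.min()) / (cov.max() - cov.min())
                    s = design.coupling_strength
                    true[:, j] = s * linear + (1 - s) * rng.uniform(lo, hi, design.n_subjects)
                else:
                    true[:, j] = rng.uniform(lo, hi, design.n_subjects)
            fit_seed = int(rng.integers(0, 2**31 - 1))
            recovered = _simulate_and_fit(true, design, rng, fit_seed)
            for j in range(len(all_names)):
                res = pearson_correlation(cov, recovered[:, j])
                detect[row, j] += res.p_value < design.alpha_level
                mean_r[row, j] += res.r
    detect /= design.n_datasets
    mean_r /= design.n_datasets
    return RecoveryMatrix(
        detection_rate=pd.DataFrame(detect, index=names, columns=all_names),
        mean_r=pd.DataFrame(mean_r, index=names, columns=all_names),
        n_datasets=design.n_datasets,
        n_subjects=design.n_subjects,
    )


def fit_models_to_demonstrators(
    n_demonstrators: int,
    rng: np.random.Generator,
    dem_params: DemonstratorParams = DemonstratorParams(),
    task: TaskConfig = TaskConfig(),
    fit_options: FitOptions = FitOptions(),
) -> tuple[list[FitResult], list[FitResult], np.ndarray]:
    """Fit both candidate models to simulated demonstrators.

    Returns (q-learning fits, social fits, log-evidence matrix) with model
    order (Q-learning, social RL).
    """
    if n_demonstrators < 2:
        raise ValueError("need at least 2 demonstrators")
    q_fits, s_fits = [], []
    evidence = np.empty((n_demonstrators, 2))
    for i in range(n_demonstrators):
        schedule = build_schedule(task, rng)
        dem = simulate_demonstrator(schedule, dem_params, rng)
        session = dem.to_session()
        seed = int(rng.integers(0, 2**31 - 1))
        opts_q = FitOptions(n_restarts=fit_options.n_restarts, seed=seed)
        opts_s = FitOptions(n_restarts=fit_options.n_restarts, seed=seed + 1)
        fq = fit_subject(session, Model.QLEARN, options=opts_q)
        fs = fit_subject(session, Model.SOCIAL_RL, options=opts_s)
        q_fits.append(fq)
        s_fits.append(fs)
        evidence[i] = (fq.lpp, fs.lpp)
    return q_fits, s_fits, evidence


def model_recovery(
    n_demonstrators: int,
    rng: np.random.Generator,
    dem_params: DemonstratorParams = DemonstratorParams(),
    task: TaskConfig = TaskConfig(),
    fit_options: FitOptions = FitOptions(),
) -> BMSResult:
    """Group-level model selection on data truly generated by Q-learners."""
    _, _, evidence = fit_models_to_demonstrators(
        n_demonstrators, rng, dem_params, task, fit_options
    )
    return bms(evidence, model_names=(Model.QLEARN.value, Model.SOCIAL_RL.value))


def simulate_from_fits(
    fits: list[FitResult],
    reps: int,
    rng: np.random.Generator,
    task: TaskConfig = TaskConfig(),
    dem_params: DemonstratorParams = DemonstratorParams(),
    subject_ids=None,
) -> pd.DataFrame:
    """Simulate behavioral data from fitted parameters.

    Each repetition draws a fresh schedule and a fresh demonstrator per
    subject, so simulated data are independent of the originally
    experienced contingencies.  Returns per-subject correct rates per
    condition averaged over repetitions, in the same wide format as
    observed-data summaries.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    for i, fit in enumerate(fits):
        params = fit.social_params()
        acc = {c: 0.0 for c in Condition}
        for _ in range(reps):
            schedule = build_schedule(task, rng)
            dem = simulate_demonstrator(schedule, dem_params, rng)
            sim = simulate_participant(schedule, dem, params, rng)
            for c in Condition:
                acc[c] += sim.correct_rate(c)
        sid = subject_ids[i] if subject_ids is not None else (fit.subject_id if fit.subject_id is not None else i)
        rows.append(
            {"subject_id": sid, **{c.name: acc[c] / reps for c in Condition}}
        )
    return pd.DataFrame(rows)
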