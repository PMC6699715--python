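"""Synthetic cohort generator.

Emulates a two-sample study of the bandit task in the general population:
per-subject depression and anxiety questionnaire scores (integer 0-21
subscales, right-skewed and mutually correlated), per-subject social-RL
parameters drawn from population distributions, a negative coupling
between the depression score and the social-context learning rate
``alpha_s``, and one fully simulated session per subject.

Score margins are truncated negative-binomial distributions moment-matched
to the target mean/SD; the depression-anxiety dependence is a Gaussian
copula.  Rate-type parameters follow logit-normal population laws
moment-matched to the target mean/SD and temperatures follow truncated
normals.  The depression -> alpha_s coupling acts on the logit scale and
its strength is calibrated numerically so the realized Pearson correlation
between the integer depression score and alpha_s hits the requested value.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .agents import (
    PARAM_NAMES,
    DemonstratorParams,
    SocialRLParams,
    simulate_demonstrator,
    simulate_participant,
)
from .task import SessionData, TaskConfig, build_schedule, sessions_to_frame

SCORE_MAX = 21


class SymptomClass(enum.Enum):
    ABSENT = "absent"
    PRESENT = "present"


#: conventional clinical cut-off on the depression subscale
SYMPTOM_THRESHOLD = 8


def score_threshold(depression_score: int) -> SymptomClass:
    """Classify a depression subscale score: PRESENT iff score >= 8."""
    s = int(depression_score)
    if s != depression_score or not 0 <= s <= SCORE_MAX:
        raise ValueError(f"score must be an integer in [0, {SCORE_MAX}], got {depression_score}")
    return SymptomClass.PRESENT if s >= SYMPTOM_THRESHOLD else SymptomClass.ABSENT


# ---------------------------------------------------------------------------
# Score margins


@lru_cache(maxsize=32)
def _truncnb_pmf(mean: float, sd: float) -> tuple[np.ndarray, float, float]:
    """Negative-binomial pmf truncated to 0..21, moment-matched to (mean, sd).

    Returns (pmf, realized mean, realized sd).  The shape parameters of the
    untruncated law are solved so the *truncated* moments match.
    """
    k = np.arange(SCORE_MAX + 1)

    def moments(x):
        log_r, logit_p = x
        r = math.exp(log_r)
        p = expit(logit_p)
        pmf = stats.nbinom.pmf(k, r, p)
        total = pmf.sum()
        if total <= 0:
            return np.array([1e6, 1e6])
        pmf = pmf / total
        m = float((k * pmf).sum())
        v = float((k * k * pmf).sum()) - m * m
        return np.array([m - mean, math.sqrt(max(v, 1e-12)) - sd])

    # start from untruncated moment match: p = m/v, r = m^2/(v-m)
    v0 = sd * sd
    if v0 <= mean:
        raise ValueError("margin requires overdispersion (sd^2 > mean)")
    x0 = np.array([math.log(mean**2 / (v0 - mean)), logit(mean / v0)])
    sol = optimize.least_squares(moments, x0, xtol=1e-14, ftol=1e-14)
    r = math.exp(sol.x[0])
    p = expit(sol.x[1])
    pmf = stats.nbinom.pmf(k, r, p)
    pmf = pmf / pmf.sum()
    m = float((k * pmf).sum())
    s = math.sqrt(float((k * k * pmf).sum()) - m * m)
    if abs(m - mean) > 0.05 or abs(s - sd) > 0.05:
        raise ValueError(
            f"margin calibration failed: target ({mean}, {sd}), got ({m:.3f}, {s:.3f})"
        )
    return pmf, m, s


@dataclass(frozen=True)
class ScoreMargin:
    """Discrete right-skewed questionnaire-score distribution on 0..21."""

    mean: float
    sd: float

    @property
    def pmf(self) -> np.ndarray:
        return _truncnb_pmf(self.mean, self.sd)[0]

    @property
    def realized_mean(self) -> float:
        return _truncnb_pmf(self.mean, self.sd)[1]

    @property
    def realized_sd(self) -> float:
        return _truncnb_pmf(self.mean, self.sd)[2]

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function mapping uniforms to integer scores."""
        cdf = np.cumsum(self.pmf)
        cdf[-1] = 1.0
        return np.searchsorted(cdf, np.asarray(u), side="left").clip(0, SCORE_MAX)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return self.ppf(rng.random(size))


# ---------------------------------------------------------------------------
# Parameter populations


@lru_cache(maxsize=64)
def _logitnormal_location_scale(mean: float, sd: float) -> tuple[float, float]:
    """Solve the logit-normal (mu, sigma) with the given mean and SD.

    Moments are computed by Gauss-Hermite quadrature; infeasible targets
    (SD too large for the mean on (0, 1)) raise.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(101)
    weights = weights / weights.sum()

    def moments(x):
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        vals = expit(mu + sigma * nodes)
        m = float((weights * vals).sum())
        v = float((weights * vals * vals).sum()) - m * m
        return np.array([m - mean, math.sqrt(max(v, 1e-16)) - sd])

    sol = optimize.least_squares(
        moments, np.array([logit(mean), 0.0]), xtol=1e-14, ftol=1e-14
    )
    resid = moments(sol.x)
    if abs(resid[0]) > 1e-3 or abs(resid[1]) > 1e-3:
        raise ValueError(
            f"no logit-normal with mean {mean} and sd {sd} (residual {resid})"
        )
    return float(sol.x[0]), float(math.exp(sol.x[1]))


@dataclass(frozen=True)
class ParamPopulation:
    """Population means/SDs of the six model parameters.

    Temperatures are truncated-normal on (0.05, 100); rates are
    logit-normal.  Defaults reproduce the parameter spread reported for
    general-population samples on this task.
    """

    means: dict = field(
        default_factory=lambda: {
            "beta_p": 2.20, "alpha_p": 0.58, "beta_s": 1.83,
            "alpha_s": 0.60, "kappa": 0.13, "alpha_o": 0.46,
        }
    )
    sds: dict = field(
        default_factory=lambda: {
            "beta_p": 2.40, "alpha_p": 0.255, "beta_s": 1.735,
            "alpha_s": 0.306, "kappa": 0.102, "alpha_o": 0.306,
        }
    )
    temp_lo: float = 0.05
    temp_hi: float = 100.0

    def _truncnorm(self, name: str) -> stats.rv_continuous:
        m, s = self.means[name], self.sds[name]
        a, b = (self.temp_lo - m) / s, (self.temp_hi - m) / s
        return stats.truncnorm(a, b, loc=m, scale=s)

    def logitnormal_params(self, name: str) -> tuple[float, float]:
        return _logitnormal_location_scale(self.means[name], self.sds[name])

    def rvs(self, name: str, size: int, rng: np.random.Generator) -> np.ndarray:
        if name.startswith("beta"):
            return self._truncnorm(name).rvs(size=size, random_state=rng)
        mu, sigma = self.logitnormal_params(name)
        return expit(mu + sigma * rng.standard_normal(size))

    def interval(self, name: str, coverage: float = 0.95) -> tuple[float, float]:
        """Central population interval, the default "fitted range" used by
        the recovery suite."""
        q = (1.0 - coverage) / 2.0
        if name.startswith("beta"):
            d = self._truncnorm(name)
            return float(d.ppf(q)), float(d.ppf(1.0 - q))
        mu, sigma = self.logitnormal_params(name)
        z = stats.norm.ppf([q, 1.0 - q])
        return float(expit(mu + sigma * z[0])), float(expit(mu + sigma * z[1]))


DEFAULT_POPULATION = ParamPopulation()


# ---------------------------------------------------------------------------
# Cohort spec and generation


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of one synthetic study.

    Two independent samples of 50 subjects by default (a discovery and a
    replication sample drawn from the same population).  ``coupling_r`` is
    the target Pearson correlation between the depression score and
    ``alpha_s``; only ``alpha_s`` is coupled to depression by default, but
    ``coupled_param`` allows power studies on any parameter.
    """

    n_subjects: int = 50
    n_samples: int = 2
    depression_mean: float = 5.2
    depression_sd: float = 4.5
    anxiety_mean: float = 6.35
    anxiety_sd: float = 4.4
    score_correlation: float = 0.6
    coupling_r: float = -0.25
    coupled_param: str = "alpha_s"
    population: ParamPopulation = field(default_factory=ParamPopulation)
    trust_covariate: bool = False
    trust_kappa_r: float = 0.3
    task: TaskConfig = field(default_factory=TaskConfig)
    dem_params: DemonstratorParams = field(default_factory=DemonstratorParams)

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_samples < 1:
            raise ValueError("counts must be positive")
        if not -1.0 < self.coupling_r < 1.0:
            raise ValueError("coupling_r must lie in (-1, 1)")
        if not -1.0 < self.score_correlation < 1.0:
            raise ValueError("score_correlation must lie in (-1, 1)")
        if self.coupled_param not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.coupled_param!r}")
        if self.coupled_param.startswith("beta"):
            raise ValueError("coupling is defined for rate-type parameters only")

    @property
    def depression_margin(self) -> ScoreMargin:
        return ScoreMargin(self.depression_mean, self.depression_sd)

    @property
    def anxiety_margin(self) -> ScoreMargin:
        return ScoreMargin(self.anxiety_mean, self.anxiety_sd)


@dataclass
class Cohort:
    """Realized synthetic sample: scores, parameters and sessions."""

    spec: CohortSpec
    scores: pd.DataFrame
    params: pd.DataFrame
    sessions: list[SessionData]

    def trials_frame(self) -> pd.DataFrame:
        df = sessions_to_frame(self.sessions, subject_ids=self.scores["subject_id"])
        return df

    def correct_rates(self) -> pd.DataFrame:
        """Per-subject correct-choice rate per condition (wide format)."""
        rows = []
        for sid, s in zip(self.scores["subject_id"], self.sessions):
            row = {"subject_id": sid}
            for cond, rate in s.correct_rates_by_condition().items():
                row[cond.name] = rate
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(d / "scores.csv", index=False)
        self.params.to_csv(d / "params.csv", index=False)
        self.trials_frame().to_csv(d / "trials.csv", index=False)


@lru_cache(maxsize=32)
def _calibrate_coupling(
    dep_mean: float, dep_sd: float, mu: float, sigma: float, target_abs_r: float
) -> float:
    """Loading b such that logit(alpha) = mu - b*z_dep + sqrt(sigma^2-b^2)*eps
    yields |Pearson r(score, alpha)| = target, measured on a fixed large
    deterministic sample."""
    if target_abs_r == 0.0:
        return 0.0
    margin = ScoreMargin(dep_mean, dep_sd)
    rng = np.random.default_rng(987_654_321)  # calibration sample, not cohort draws
    n = 40_000
    dep = margin.rvs(n, rng)
    z = (dep - margin.realized_mean) / margin.realized_sd
    eps = rng.standard_normal(n)

    def realized(b):
        a = expit(mu + b * z + math.sqrt(sigma**2 - b**2) * eps)
        return float(np.corrcoef(dep, a)[0, 1])

    max_r = realized(sigma * 0.999)
    if target_abs_r > max_r:
        raise ValueError(
            f"coupling_r {target_abs_r} unreachable: maximum attainable "
            f"|r| is {max_r:.3f} for this margin and parameter spread"
        )
    b = optimize.brentq(
        lambda b: realized(b) - target_abs_r, 0.0, sigma * 0.999, xtol=1e-6
    )
    return float(b)


def generate_cohort(
    spec: CohortSpec,
    rng: np.random.Generator,
    simulate_sessions: bool = True,
) -> Cohort:
    """Draw a full synthetic cohort.

    Scores come from a Gaussian copula over the two margins; parameters
    from the population laws, with the coupled parameter's logit location
    shifted linearly in the standardized depression score (total logit
    variance held fixed, so the marginal law is preserved).  Each subject
    then plays one session against a fresh simulated demonstrator.
    """
    n = spec.n_subjects * spec.n_samples
    dep_margin = spec.depression_margin
    anx_margin = spec.anxiety_margin

    # Gaussian copula over the integer margins
    rho = spec.score_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    zz = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    depression = dep_margin.ppf(stats.norm.cdf(zz[:, 0]))
    anxiety = anx_margin.ppf(stats.norm.cdf(zz[:, 1]))

    pop = spec.population
    params = {}
    for name in PARAM_NAMES:
        if name == spec.coupled_param:
            continue
        params[name] = pop.rvs(name, n, rng)

    mu, sigma = pop.logitnormal_params(spec.coupled_param)
    b = _calibrate_coupling(
        spec.depression_mean, spec.depression_sd, mu, sigma, abs(spec.coupling_r)
    )
    sign = -1.0 if spec.coupling_r < 0 else 1.0
    z_dep = (depression - dep_margin.realized_mean) / dep_margin.realized_sd
    eps = rng.standard_normal(n)
    params[spec.coupled_param] = expit(
        mu + sign * b * z_dep + math.sqrt(sigma**2 - b**2) * eps
    )

    subject_ids = np.arange(n)
    sample_ids = np.repeat(np.arange(spec.n_samples), spec.n_subjects)
    scores = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "sample_id": sample_ids,
            "depression": depression.astype(int),
            "anxiety": anxiety.astype(int),
        }
    )
    if spec.trust_covariate:
        # post-test trustworthiness rating on 1..9, correlated with kappa
        z_k = (logit(params["kappa"]) - pop.logitnormal_params("kappa")[0]) / (
            pop.logitnormal_params("kappa")[1]
        )
        r = spec.trust_kappa_r
        z_t = r * z_k + math.sqrt(1 - r * r) * rng.standard_normal(n)
        scores["trust"] = np.clip(np.round(5 + 2 * z_t), 1, 9).astype(int)

    params_df = pd.DataFrame({"subject_id": subject_ids, **params})

    sessions: list[SessionData] = []
    if simulate_sessions:
        for i in range(n):
            p = SocialRLParams(**{k: float(params[k][i]) for k in PARAM_NAMES})
            schedule = build_schedule(spec.task, rng)
            dem = simulate_demonstrator(schedule, spec.dem_params, rng)
            sessions.append(
                simulate_participant(schedule, dem, p, rng, subject_id=int(i))
            )
    return Cohort(spec=spec, scores=scores, params=params_df, sessions=sessions)
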