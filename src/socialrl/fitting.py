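"""Per-subject MAP fitting, model evidence and Bayesian model selection.

Parameters are estimated by maximizing the log posterior probability

    LPP = log P(data | theta) + sum_k log P(theta_k),

with a gamma(shape 1.2, scale 5) prior on softmax temperatures and a
beta(1.1, 1.1) prior on all rate-type parameters.  The LPP at the optimum
is used as the per-subject approximation to log model evidence entering
random-effects Bayesian model selection; an optional Laplace correction
(Hessian determinant term) can be added but is off by default.

Optimization runs in transformed space (log temperatures, logit rates)
with L-BFGS-B from multiple restarts drawn from the priors.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, psi

from . import _kernel
from .agents import (
    PARAM_NAMES,
    DemonstratorParams,
    SocialRLParams,
    simulate_demonstrator,
    simulate_participant,
)
from .task import Condition, SessionData, TaskConfig, build_schedule


class Model(enum.Enum):
    SOCIAL_RL = "social"
    QLEARN = "qlearn"


MODEL_PARAM_NAMES = {
    Model.SOCIAL_RL: PARAM_NAMES,
    Model.QLEARN: ("beta", "alpha"),
}


@dataclass(frozen=True)
class PriorSpec:
    """Priors over model parameters.

    ``temp_cap`` bounds the nominally unbounded temperature support for
    numerical stability of the optimizer.
    """

    temp_shape: float = 1.2
    temp_scale: float = 5.0
    rate_a: float = 1.1
    rate_b: float = 1.1
    temp_cap: float = 100.0

    def log_temp_prior(self, beta: float) -> float:
        """log gamma(shape, scale) density at ``beta``."""
        if beta <= 0:
            return -np.inf
        a, s = self.temp_shape, self.temp_scale
        return (a - 1.0) * math.log(beta) - beta / s - a * math.log(s) - math.lgamma(a)

    def log_rate_prior(self, x: float) -> float:
        """log beta(a, b) density at ``x``."""
        if not 0.0 < x < 1.0:
            return -np.inf
        a, b = self.rate_a, self.rate_b
        log_beta_fn = math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)
        return (a - 1.0) * math.log(x) + (b - 1.0) * math.log(1.0 - x) - log_beta_fn

    def sample_temperature(self, rng: np.random.Generator) -> float:
        v = rng.gamma(self.temp_shape, self.temp_scale)
        return float(np.clip(v, 1e-3, self.temp_cap * 0.99))

    def sample_rate(self, rng: np.random.Generator) -> float:
        v = rng.beta(self.rate_a, self.rate_b)
        return float(np.clip(v, 1e-3, 1.0 - 1e-3))


DEFAULT_PRIORS = PriorSpec()


@dataclass
class FitResult:
    """MAP estimate for one subject under one model."""

    model: Model
    params: dict[str, float]
    lpp: float
    loglik: float
    n_restarts: int
    converged: bool
    n_floored: int = 0
    subject_id: object = None

    def social_params(self) -> SocialRLParams:
        """The estimate embedded in the 6-dimensional social parameter space."""
        if self.model == Model.SOCIAL_RL:
            return SocialRLParams(**self.params)
        return DemonstratorParams(
            alpha=self.params["alpha"], beta=self.params["beta"]
        ).as_social()


@dataclass(frozen=True)
class FitOptions:
    n_restarts: int = 10
    seed: int = 0
    maxiter: int = 500
    gtol: float = 1e-6
    hessian_correction: bool = False


@dataclass
class BMSResult:
    """Random-effects model comparison over a group of subjects."""

    model_names: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    posterior_prob: np.ndarray
    exceedance_prob: np.ndarray

    def winner(self) -> str:
        return self.model_names[int(np.argmax(self.posterior_prob))]


def _kernel_params(params: dict[str, float], model: Model) -> tuple[float, ...]:
    if model == Model.SOCIAL_RL:
        return tuple(params[n] for n in PARAM_NAMES)
    b, a = params["beta"], params["alpha"]
    return (b, a, b, a, 0.0, 0.0)


def _loglik_raw(data: SessionData, kp: tuple[float, ...]) -> tuple[float, int]:
    n = len(data)
    dummy = np.empty(0)
    out_logp = np.empty(n)
    ll, n_floored = _kernel.run_session(
        data.block_id, data.condition,
        data.p0 if data.p0 is not None else np.zeros(n),
        data.p1 if data.p1 is not None else np.zeros(n),
        data.dem_choice, data.dem_outcome, data.choice, data.outcome,
        *kp,
        _kernel.MODE_EVAL, dummy, dummy,
        np.empty(0, dtype=np.int64), np.empty(0), out_logp,
    )
    return ll, n_floored


def session_loglik(params, data: SessionData, model: Model = Model.SOCIAL_RL) -> float:
    """Summed log probability of the subject's actual choices.

    ``params`` is a :class:`SocialRLParams`, a :class:`DemonstratorParams`,
    or a name -> value mapping for the given model.  Probabilities are
    floored at 1e-9, so the result is finite even for saturated policies.
    """
    params = _as_param_dict(params, model)
    ll, _ = _loglik_raw(data, _kernel_params(params, model))
    return ll


def _as_param_dict(params, model: Model) -> dict[str, float]:
    if isinstance(params, SocialRLParams):
        return {n: getattr(params, n) for n in PARAM_NAMES}
    if isinstance(params, DemonstratorParams):
        return {"beta": params.beta, "alpha": params.alpha}
    return {n: float(params[n]) for n in MODEL_PARAM_NAMES[model]}


def log_priors(params: dict[str, float], model: Model, priors: PriorSpec) -> float:
    total = 0.0
    for name in MODEL_PARAM_NAMES[model]:
        v = params[name]
        if name.startswith("beta"):
            total += priors.log_temp_prior(v)
        else:
            total += priors.log_rate_prior(v)
    return total


def log_posterior(
    params,
    data: SessionData,
    model: Model = Model.SOCIAL_RL,
    priors: PriorSpec = DEFAULT_PRIORS,
) -> float:
    """LPP = session log-likelihood plus summed log prior densities."""
    params = _as_param_dict(params, model)
    lp = log_priors(params, model, priors)
    if not np.isfinite(lp):
        return -np.inf
    return session_loglik(params, data, model) + lp


# ---------------------------------------------------------------------------
# MAP optimization


def _transform(x: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    out = {}
    for v, name in zip(x, names):
        out[name] = math.exp(v) if name.startswith("beta") else float(expit(v))
    return out


def _bounds(names: tuple[str, ...], priors: PriorSpec):
    bounds = []
    for name in names:
        if name.startswith("beta"):
            bounds.append((math.log(1e-3), math.log(priors.temp_cap)))
        else:
            bounds.append((-8.0, 8.0))
    return bounds


def fit_subject(
    data: SessionData,
    model: Model = Model.SOCIAL_RL,
    priors: PriorSpec = DEFAULT_PRIORS,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Multi-start MAP fit of one subject's session.

    Restart initializations are drawn from the priors; the best restart by
    LPP wins.  Deterministic given ``options.seed``.
    """
    names = MODEL_PARAM_NAMES[model]
    bounds = _bounds(names, priors)
    rng = np.random.default_rng(options.seed)

    def negative_lpp(x: np.ndarray) -> float:
        params = _transform(x, names)
        ll, _ = _loglik_raw(data, _kernel_params(params, model))
        return -(ll + log_priors(params, model, priors))

    best = None
    any_success = False
    for _ in range(options.n_restarts):
        x0 = np.array(
            [
                math.log(priors.sample_temperature(rng))
                if n.startswith("beta")
                else float(np.log(p := priors.sample_rate(rng)) - np.log1p(-p))
                for n in names
            ]
        )
        res = optimize.minimize(
            negative_lpp,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options=dict(maxiter=options.maxiter, gtol=options.gtol, ftol=1e-12),
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(
            f"MAP fit failed for all {options.n_restarts} restarts "
            f"(model={model.value}, best={best})"
        )
    params = _transform(best.x, names)
    ll, n_floored = _loglik_raw(data, _kernel_params(params, model))
    lpp = ll + log_priors(params, model, priors)
    if options.hessian_correction:
        lpp += _laplace_correction(params, data, model, priors, names)
    return FitResult(
        model=model,
        params=params,
        lpp=float(lpp),
        loglik=float(ll),
        n_restarts=options.n_restarts,
        converged=any_success,
        n_floored=n_floored,
        subject_id=data.subject_id,
    )


def _laplace_correction(params, data, model, priors, names) -> float:
    """0.5*k*log(2*pi) - 0.5*log|H| with H the negative LPP Hessian at the
    optimum, finite-differenced in the original parameter space."""
    theta = np.array([params[n] for n in names])
    k = len(theta)

    def f(v):
        p = dict(zip(names, v))
        return log_posterior(p, data, model, priors)

    h = np.maximum(1e-4, 1e-4 * np.abs(theta))
    hess = np.zeros((k, k))
    f0 = f(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                hess[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                hess[i, j] = hess[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    sign, logdet = np.linalg.slogdet(-hess)
    if sign <= 0:
        return 0.0  # not locally concave; skip the correction
    return 0.5 * k * math.log(2 * math.pi) - 0.5 * logdet


def fit_cohort(
    sessions,
    model: Model = Model.SOCIAL_RL,
    priors: PriorSpec = DEFAULT_PRIORS,
    options: FitOptions = FitOptions(),
) -> list[FitResult]:
    """Fit every session; per-subject seeds derive from ``options.seed``."""
    results = []
    for i, s in enumerate(sessions):
        opt = FitOptions(
            n_restarts=options.n_restarts,
            seed=(options.seed + 7919 * i) % (2**31 - 1),
            maxiter=options.maxiter,
            gtol=options.gtol,
            hessian_correction=options.hessian_correction,
        )
        results.append(fit_subject(s, model, priors, opt))
    return results


# ---------------------------------------------------------------------------
# Random-effects Bayesian model selection


def bms(
    log_evidence: np.ndarray,
    model_names=None,
    n_samples: int = 100_000,
    seed: int = 20_2407,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> BMSResult:
    """Variational random-effects model selection over model frequencies.

    ``log_evidence`` is subjects x models (LPP per subject per model).  A
    Dirichlet posterior over population model frequencies is estimated by
    the standard variational scheme; ``posterior_prob`` is its mean and
    ``exceedance_prob`` the Monte-Carlo probability that each model is the
    most frequent (fixed-seed Dirichlet sampling).
    """
    L = np.asarray(log_evidence, dtype=float)
    if L.ndim != 2 or L.shape[0] < 2 or L.shape[1] < 2:
        raise ValueError("log_evidence must be a subjects x models matrix (>= 2 each)")
    if not np.all(np.isfinite(L)):
        raise ValueError("log_evidence contains non-finite entries")
    n_subj, n_models = L.shape
    if model_names is None:
        model_names = tuple(f"model_{i}" for i in range(n_models))
    model_names = tuple(model_names)

    alpha0 = np.ones(n_models)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        ln_r = psi(alpha) - psi(alpha.sum())
        u = L + ln_r[None, :]
        u -= u.max(axis=1, keepdims=True)
        g = np.exp(u)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    posterior = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    exceedance = np.bincount(winners, minlength=n_models) / n_samples
    return BMSResult(
        model_names=model_names,
        dirichlet_alpha=alpha,
        posterior_prob=posterior,
        exceedance_prob=exceedance,
    )


# ---------------------------------------------------------------------------
# Posterior predictive check


def predictive_check(
    fits: list[FitResult],
    sessions: list[SessionData],
    reps: int = 100,
    rng: np.random.Generator | None = None,
    task: TaskConfig = TaskConfig(),
    dem_params: DemonstratorParams = DemonstratorParams(),
) -> dict[Condition, "CorrelationResult"]:
    """Correlate observed and model-predicted correct rates per condition.

    For each subject, ``reps`` fresh sessions (new schedules and new
    demonstrators) are simulated from the fitted parameters; the simulated
    correct rates, averaged over repetitions, are correlated with the
    observed ones across subjects.
    """
    from .analysis import CorrelationResult, pearson_correlation  # local: no cycle

    if reps < 1:
        raise ValueError("reps must be >= 1")
    if len(fits) != len(sessions):
        raise ValueError("need exactly one fit per session")
    rng = rng if rng is not None else np.random.default_rng()
    conditions = list(Condition)
    observed = np.array(
        [[s.correct_rate(c) for c in conditions] for s in sessions]
    )
    simulated = np.zeros_like(observed)
    for i, fit in enumerate(fits):
        params = fit.social_params()
        acc = np.zeros(len(conditions))
        for _ in range(reps):
            schedule = build_schedule(task, rng)
            dem = simulate_demonstrator(schedule, dem_params, rng)
            sim = simulate_participant(schedule, dem, params, rng)
            acc += [sim.correct_rate(c) for c in conditions]
        simulated[i] = acc / reps
    return {
        c: pearson_correlation(observed[:, j], simulated[:, j])
        for j, c in enumerate(conditions)
    }
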