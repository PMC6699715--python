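"""Cohort-level statistics: correlations, meta-analysis, classification.

These stages run identically on observed and simulated trial logs.  The
meta-analytic combination of per-sample Pearson correlations uses the
Fisher-z transform with DerSimonian-Laird random-effects pooling (the
between-sample variance estimate is clipped at zero, the standard
convention).  The symptom classifier is the single-threshold cut-off rule:
on a random half of the sample the cut-off jointly maximizing sensitivity
and specificity (Youden's J) is chosen, then evaluated on the held-out
half; repeated splits give the report's mean and s.e.m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task import Condition
from .cohort import SYMPTOM_THRESHOLD, Cohort


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided t-test."""

    r: float
    t_stat: float
    df: int
    p_value: float
    n: int

    @property
    def fisher_z(self) -> float:
        return math.atanh(self.r)

    @property
    def fisher_var(self) -> float:
        return 1.0 / (self.n - 3)


def pearson_correlation(x, y) -> CorrelationResult:
    """Standard Pearson r with the exact two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    df = n - 2
    if abs(r) >= 1.0:
        t = math.copysign(math.inf, r)
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
    return CorrelationResult(r=r, t_stat=t, df=df, p_value=float(res.pvalue), n=n)


@dataclass(frozen=True)
class MetaResult:
    """Random-effects combination of per-sample effects."""

    effect: float
    ci95: tuple[float, float]
    z_stat: float
    p_value: float
    tau2: float
    k: int


def _dl_pool(effects: np.ndarray, variances: np.ndarray) -> tuple[float, float, float]:
    """DerSimonian-Laird random-effects pooling; returns (pooled, se, tau2)."""
    w = 1.0 / variances
    fixed = float((w * effects).sum() / w.sum())
    q = float((w * (effects - fixed) ** 2).sum())
    df = len(effects) - 1
    c = w.sum() - (w * w).sum() / w.sum()
    tau2 = max(0.0, (q - df) / c)  # clipped at zero
    w_re = 1.0 / (variances + tau2)
    pooled = float((w_re * effects).sum() / w_re.sum())
    se = math.sqrt(1.0 / w_re.sum())
    return pooled, se, tau2


def meta_correlation(per_sample: list[CorrelationResult]) -> MetaResult:
    """Pool per-sample Pearson correlations across samples.

    Each r is Fisher-z transformed (variance 1/(n-3)), pooled with
    random-effects weights, and the pooled effect is back-transformed.
    """
    if len(per_sample) < 2:
        raise ValueError("need at least 2 samples")
    for c in per_sample:
        if c.n <= 3:
            raise ValueError("every sample must have n > 3 for the Fisher-z variance")
    z = np.array([c.fisher_z for c in per_sample])
    v = np.array([c.fisher_var for c in per_sample])
    pooled, se, tau2 = _dl_pool(z, v)
    z_stat = pooled / se
    p = 2.0 * stats.norm.sf(abs(z_stat))
    ci = (math.tanh(pooled - 1.959963984540054 * se), math.tanh(pooled + 1.959963984540054 * se))
    return MetaResult(
        effect=math.tanh(pooled), ci95=ci, z_stat=float(z_stat),
        p_value=float(p), tau2=float(tau2), k=len(per_sample),
    )


def meta_means(means, sems) -> MetaResult:
    """Pool per-sample means weighted by 1/SEM^2 with the same machinery."""
    m = np.asarray(means, dtype=float)
    s = np.asarray(sems, dtype=float)
    if len(m) < 2:
        raise ValueError("need at least 2 samples")
    if np.any(s <= 0):
        raise ValueError("SEMs must be positive")
    pooled, se, tau2 = _dl_pool(m, s * s)
    z_stat = pooled / se
    p = 2.0 * stats.norm.sf(abs(z_stat))
    ci = (pooled - 1.959963984540054 * se, pooled + 1.959963984540054 * se)
    return MetaResult(
        effect=pooled, ci95=ci, z_stat=float(z_stat),
        p_value=float(p), tau2=float(tau2), k=len(m),
    )


# ---------------------------------------------------------------------------
# Threshold classifier


@dataclass
class ClassifierReport:
    """Held-out performance of the cut-off classifier over repeated splits."""

    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_resampled: int

    @property
    def n_repeats(self) -> int:
        return len(self.accuracy)

    def summary(self) -> dict[str, float]:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity"):
            v = getattr(self, name)
            out[f"{name}_mean"] = float(v.mean())
            out[f"{name}_sem"] = float(v.std(ddof=1) / math.sqrt(len(v)))
        return out


def _best_cutoff(feature: np.ndarray, labels: np.ndarray) -> tuple[float, int]:
    """Cut-off and direction maximizing sensitivity + specificity.

    Candidates are the midpoints of adjacent sorted unique feature values;
    direction +1 predicts positive for feature >= cutoff, -1 for <=.
    Ties go to the median best candidate.
    """
    uniq = np.unique(feature)
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    if len(cuts) == 0:
        cuts = uniq  # degenerate: constant training feature
    pos = labels
    neg = ~labels
    best = (-np.inf, 0.0, 1)
    scored = []
    for direction in (1, -1):
        for c in cuts:
            pred = feature >= c if direction == 1 else feature <= c
            sens = (pred & pos).sum() / max(pos.sum(), 1)
            spec = (~pred & neg).sum() / max(neg.sum(), 1)
            scored.append((sens + spec, c, direction))
    best_j = max(s[0] for s in scored)
    ties = sorted(s for s in scored if s[0] >= best_j - 1e-12)
    _, c, direction = ties[len(ties) // 2]
    return float(c), int(direction)


def threshold_classifier_cv(
    feature,
    labels,
    n_repeats: int = 100,
    train_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
) -> ClassifierReport:
    """Out-of-sample evaluation of the single cut-off classifier.

    Per repeat: random split; the cut-off (and direction) is optimized on
    the training half and evaluated on the held-out half.  Training halves
    that miss one class are resampled (counted in ``n_resampled``).
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if feature.shape != labels.shape:
        raise ValueError("feature and labels misaligned")
    n = len(feature)
    if n < 20:
        raise ValueError("need at least 20 subjects")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    rng = rng if rng is not None else np.random.default_rng()
    n_train = int(round(train_fraction * n))
    acc = np.empty(n_repeats)
    sens = np.empty(n_repeats)
    spec = np.empty(n_repeats)
    n_resampled = 0
    for i in range(n_repeats):
        for _attempt in range(1000):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if labels[tr].any() and not labels[tr].all() and labels[te].any() and not labels[te].all():
                break
            n_resampled += 1
        else:
            raise RuntimeError("could not draw a two-class split")
        c, direction = _best_cutoff(feature[tr], labels[tr])
        pred = feature[te] >= c if direction == 1 else feature[te] <= c
        pos = labels[te]
        acc[i] = (pred == pos).mean()
        sens[i] = (pred & pos).sum() / pos.sum()
        spec[i] = (~pred & ~pos).sum() / (~pos).sum()
    return ClassifierReport(
        accuracy=acc, sensitivity=sens, specificity=spec, n_resampled=n_resampled
    )


def compare_classifiers(
    report_a: ClassifierReport, report_b: ClassifierReport, metric: str
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test across repeats on one metric.

    Returns (t, df, p) with df = 2 * n_repeats - 2.
    """
    if report_a.n_repeats != report_b.n_repeats:
        raise ValueError("repeat counts differ")
    a = np.asarray(getattr(report_a, metric), dtype=float)
    b = np.asarray(getattr(report_b, metric), dtype=float)
    df = report_a.n_repeats + report_b.n_repeats - 2
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # degenerate case (e.g. perfect separation on every repeat)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


# ---------------------------------------------------------------------------
# Cohort pipelines


def correct_rates_wide(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject correct-choice rates per condition from a trial log."""
    g = trials.groupby(["subject_id", "condition"])["correct"].mean().unstack()
    return g.reset_index()


def depression_performance_meta(
    cohort: Cohort, covariate: str = "depression"
) -> dict[Condition, dict]:
    """Per-condition correlation between a score and correct rate, per
    sample, plus its meta-analytic combination across samples."""
    rates = cohort.correct_rates().merge(cohort.scores, on="subject_id")
    out: dict[Condition, dict] = {}
    for cond in Condition:
        per_sample = [
            pearson_correlation(g[covariate], g[cond.name])
            for _, g in rates.groupby("sample_id")
        ]
        out[cond] = {
            "per_sample": per_sample,
            "meta": meta_correlation(per_sample) if len(per_sample) >= 2 else None,
        }
    return out


def export_long_table(cohort: Cohort) -> pd.DataFrame:
    """Tidy per-trial table (subject, condition, trial, correct, scores)
    for external mixed-model or SEM software."""
    trials = cohort.trials_frame()
    return trials.merge(cohort.scores, on="subject_id")[
        [c for c in trials.columns] + [c for c in cohort.scores.columns if c != "subject_id"]
    ]
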