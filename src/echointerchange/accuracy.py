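"""Diagnostic accuracy at an LVEF cutoff: confusion-matrix metrics, ROC AUC,
metric-consistent 2x2 recovery, and margin-of-error sample-size arithmetic.

The clinical question is binary: does the patient have a reduced ejection
fraction (LVEF at or below 40% under the primary rule; strictly below 50%
under the post-hoc rule)? The reference method's classification defines
truth; the test method's classification defines the prediction. Proportion
CIs use the Wilson score interval (Clopper-Pearson behind a flag); the AUC
is the Mann-Whitney statistic with midrank tie handling, with a
Hanley-McNeil CI (DeLong behind a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import ConfigurationError, DegenerateDataError, InsufficientDataError

__all__ = [
    "ConfusionCounts",
    "MetricEstimate",
    "AccuracySummary",
    "confusion_at_cutoff",
    "accuracy_metrics",
    "empirical_auc",
    "metric_consistent_counts",
    "sample_size_prevalence",
    "round_half_up",
]


def round_half_up(x: float, dp: int = 0) -> float:
    """Round half away from zero at ``dp`` decimals (the presentation rule)."""
    scale = 10.0**dp
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ConfigurationError("confusion counts must be non-negative")
        if self.total < 1:
            raise InsufficientDataError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_text(self) -> str:
        """2x2 block, reference status in columns."""
        w = max(len(str(v)) for v in (self.tp, self.fp, self.fn, self.tn)) + 2
        return (
            f"{'':>12}{'ref+':>{w}}{'ref-':>{w}}\n"
            f"{'test+':>12}{self.tp:>{w}}{self.fp:>{w}}\n"
            f"{'test-':>12}{self.fn:>{w}}{self.tn:>{w}}"
        )


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion-type metric with its CI, or a reason it is undefined."""

    value: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class AccuracySummary:
    accuracy: MetricEstimate
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    n: int
    cutoff: float
    counts: ConfusionCounts
    ci_level: float
    auc: MetricEstimate | None = None


def confusion_at_cutoff(
    pairs: Sequence[tuple[float, float]],
    cutoff: float = 40.0,
    inclusive: bool = True,
) -> ConfusionCounts:
    """Classify complete (test LVEF, reference LVEF) pairs at a cutoff.

    ``inclusive=True`` uses "value <= cutoff" (the 40% primary rule);
    ``inclusive=False`` uses strict "<" (the 50% post-hoc rule). The
    reference defines truth, the test defines the prediction.
    """
    if len(pairs) == 0:
        raise InsufficientDataError("no complete pairs to classify")
    test = np.asarray([p[0] for p in pairs], dtype=float)
    ref = np.asarray([p[1] for p in pairs], dtype=float)
    if np.isnan(test).any() or np.isnan(ref).any():
        raise ConfigurationError("pairs must be complete-case (no missing values)")
    pred = test <= cutoff if inclusive else test < cutoff
    truth = ref <= cutoff if inclusive else ref < cutoff
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def _proportion(k: int, n: int, name: str, ci_level: float, method: str) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(None, undefined_reason=f"{name}: zero denominator")
    lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method=method)
    p = k / n
    # clamp float fuzz at the boundaries so the CI always contains the estimate
    return MetricEstimate(p, float(min(np.clip(lo, 0, 1), p)),
                          float(max(np.clip(hi, 0, 1), p)))


def accuracy_metrics(
    counts: ConfusionCounts,
    ci_level: float = 0.95,
    ci_method: str = "wilson",
    cutoff: float = 40.0,
) -> AccuracySummary:
    """Accuracy, sensitivity, specificity, PPV and NPV with proportion CIs.

    accuracy = (tp + tn) / total; sens = tp/(tp+fn); spec = tn/(tn+fp);
    ppv = tp/(tp+fp); npv = tn/(tn+fn). A zero-denominator metric is reported
    as undefined with a reason, never as 0. ``ci_method`` is "wilson" or
    "beta" (Clopper-Pearson, statsmodels naming).
    """
    if ci_method not in ("wilson", "beta"):
        raise ConfigurationError(f"unknown proportion CI method {ci_method!r}")
    c = counts
    return AccuracySummary(
        accuracy=_proportion(c.tp + c.tn, c.total, "accuracy", ci_level, ci_method),
        sensitivity=_proportion(c.tp, c.tp + c.fn, "sensitivity", ci_level, ci_method),
        specificity=_proportion(c.tn, c.tn + c.fp, "specificity", ci_level, ci_method),
        ppv=_proportion(c.tp, c.tp + c.fp, "ppv", ci_level, ci_method),
        npv=_proportion(c.tn, c.tn + c.fn, "npv", ci_level, ci_method),
        n=c.total,
        cutoff=cutoff,
        counts=c,
        ci_level=ci_level,
    )


def empirical_auc(
    scores: Sequence[tuple[float, bool]],
    ci_level: float = 0.95,
    ci_method: str = "hanley-mcneil",
) -> tuple[float, tuple[float, float]]:
    """Empirical ROC AUC by the Mann-Whitney statistic with midrank ties.

    ``scores`` pairs a risk score with the true binary label (higher score =
    more likely positive; for LVEF use -LVEF or cutoff - LVEF so that lower
    ejection fraction means higher risk). The CI is Hanley-McNeil by default,
    DeLong with ``ci_method="delong"``; both are clipped to [0, 1].
    """
    y = np.asarray([s[1] for s in scores], dtype=bool)
    x = np.asarray([s[0] for s in scores], dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("AUC needs both classes present")

    ranks = stats.rankdata(x)  # midranks
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    if ci_method == "hanley-mcneil":
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (
            auc * (1 - auc)
            + (n_pos - 1) * (q1 - auc**2)
            + (n_neg - 1) * (q2 - auc**2)
        ) / (n_pos * n_neg)
        se = math.sqrt(max(var, 0.0))
    elif ci_method == "delong":
        se = math.sqrt(_delong_variance(x[y], x[~y]))
    else:
        raise ConfigurationError(f"unknown AUC CI method {ci_method!r}")

    z = stats.norm.ppf(0.5 + ci_level / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return float(auc), (float(lo), float(hi))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the AUC from placement (structural) components."""
    m, n = len(pos), len(neg)
    # V10[i] = P(neg < pos_i) + P(neg == pos_i)/2, and symmetrically V01
    v10 = np.array([(np.sum(neg < p) + 0.5 * np.sum(neg == p)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def metric_consistent_counts(
    targets: Mapping[str, float],
    total: int,
    dp: int = 2,
) -> list[ConfusionCounts]:
    """All integer 2x2 tables of a given total whose metrics round to targets.

    ``targets`` maps metric names (``sensitivity``, ``specificity``, ``ppv``,
    ``npv``, ``accuracy``) to their printed values; rounding is half-up at
    ``dp`` decimals. Exhaustive, vectorised search; an empty list (no
    solution) is a result, not an error.
    """
    if total < 1:
        raise ConfigurationError("total must be >= 1")
    if dp < 1:
        raise ConfigurationError("dp must be >= 1")
    known = {"sensitivity", "specificity", "ppv", "npv", "accuracy"}
    unknown = set(targets) - known
    if unknown:
        raise ConfigurationError(f"unknown metric name(s): {sorted(unknown)}")

    scale = 10.0**dp

    def rounds_to(num: np.ndarray, den: np.ndarray, target: float) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.floor(num / den * scale + 0.5) / scale
        return (den > 0) & (np.abs(r - target) < 0.5 / scale / 10)

    out: list[ConfusionCounts] = []
    for pos in range(total + 1):  # reference positives: tp + fn
        neg = total - pos
        tp = np.arange(pos + 1)
        fp = np.arange(neg + 1)
        TP, FP = np.meshgrid(tp, fp, indexing="ij")
        FN = pos - TP
        TN = neg - FP
        ok = np.ones_like(TP, dtype=bool)
        if "sensitivity" in targets:
            ok &= rounds_to(TP, np.full_like(TP, pos), targets["sensitivity"])
        if "specificity" in targets:
            ok &= rounds_to(TN, np.full_like(TN, neg), targets["specificity"])
        if "ppv" in targets:
            ok &= rounds_to(TP, TP + FP, targets["ppv"])
        if "npv" in targets:
            ok &= rounds_to(TN, TN + FN, targets["npv"])
        if "accuracy" in targets:
            ok &= rounds_to(TP + TN, np.full_like(TP, total), targets["accuracy"])
        for i, j in zip(*np.nonzero(ok)):
            out.append(ConfusionCounts(int(TP[i, j]), int(FP[i, j]),
                                       int(FN[i, j]), int(TN[i, j])))
    return out


def sample_size_prevalence(p: float, margin: float, ci_level: float = 0.95) -> int:
    """Sample size so a prevalence estimate's margin of error stays within bounds.

    n = z^2 p (1 - p) / margin^2 with z the two-sided normal quantile at
    ``ci_level``, rounded half-up to the nearest integer. For p = 0.10,
    margin = 0.02 and 95% confidence this gives 864.
    """
    if not 0 < p < 1:
        raise ConfigurationError("prevalence p must be in (0, 1)")
    if not 0 < margin < 1:
        raise ConfigurationError("margin must be in (0, 1)")
    z = stats.norm.ppf(0.5 + ci_level / 2)
    n = z**2 * p * (1 - p) / margin**2
    return int(round_half_up(n))
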