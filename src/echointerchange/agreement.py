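"""Pairwise agreement statistics: Bland-Altman bias and limits, Pearson r.

Differences are always test - reference (AI - human); the sign convention is
fixed and stated in the output headers. Limits of agreement use the
conventional 1.96 multiplier on the SD of the differences; the mean
difference gets a t-based CI. A proportional-bias regression of difference on
pair mean is computed as an advisory diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DegenerateDataError, InsufficientDataError

__all__ = ["AgreementSummary", "bland_altman", "pearson_correlation"]


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman summary for one (test, reference) method pair."""

    n_pairs: int
    mean_diff: float                      # test - reference, parameter units
    mean_diff_ci: tuple[float, float]
    sd_diff: float                        # n-1 denominator
    loa_low: float                        # mean - 1.96 SD
    loa_high: float                       # mean + 1.96 SD
    pearson_r: float                      # nan when a side has zero variance
    r_pvalue: float
    prop_bias_slope: float                # advisory: slope of diff ~ pair mean
    table: pd.DataFrame                   # plot-ready: pair_mean, diff


def bland_altman(
    pairs: Sequence[tuple[float, float]],
    ci_level: float = 0.95,
    min_pairs: int = 3,
) -> AgreementSummary:
    """Bland-Altman agreement analysis of complete (test, reference) pairs."""
    if len(pairs) < min_pairs:
        raise InsufficientDataError(
            f"Bland-Altman needs at least {min_pairs} pairs, got {len(pairs)}"
        )
    test = np.asarray([p[0] for p in pairs], dtype=float)
    ref = np.asarray([p[1] for p in pairs], dtype=float)
    diff = test - ref
    n = len(diff)
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    se = sd / math.sqrt(n)
    tq = stats.t.ppf(0.5 + ci_level / 2, df=n - 1)
    pair_mean = (test + ref) / 2.0

    if n >= 3 and np.ptp(test) > 0 and np.ptp(ref) > 0:
        r, p = pearson_correlation(pairs)
    else:
        r, p = float("nan"), float("nan")

    if np.ptp(pair_mean) > 0:
        slope = float(np.polyfit(pair_mean, diff, 1)[0])
    else:
        slope = float("nan")

    return AgreementSummary(
        n_pairs=n,
        mean_diff=mean,
        mean_diff_ci=(mean - tq * se, mean + tq * se),
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        pearson_r=r,
        r_pvalue=p,
        prop_bias_slope=slope,
        table=pd.DataFrame({"pair_mean": pair_mean, "diff_test_minus_ref": diff}),
    )


def pearson_correlation(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value (n-2 df)."""
    if len(pairs) < 3:
        raise InsufficientDataError("Pearson correlation needs at least 3 pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined: a side has zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
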