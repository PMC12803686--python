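"""Individual equivalence coefficient (IEC) estimation and interchangeability.

The IEC measures the disagreement between a test method (here the AI-automated
measurement) and two human reference measurements, relative to the
disagreement among the references themselves:

    Q_RR = mean over patients of (r1 - r2)^2
    Q_TR = mean over patients of [(t - r1)^2 + (t - r2)^2] / 2
    IEC  = (Q_TR - Q_RR) / (Q_RR / 2)

A negative IEC means the test method disagrees with the human references less
than the references disagree with each other. Interchangeability is declared
when the upper bound of the IEC's 95% confidence interval is below 0.25
(strict inequality). Confidence intervals are built by a patient-level
nonparametric bootstrap (percentile by default, BCa behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import (
    CohortTable,
    ConfigurationError,
    DegenerateDataError,
    Device,
    InsufficientDataError,
    MethodId,
    QUALITY_LEVELS,
    Triad,
    select_triads,
)

__all__ = [
    "Triad",
    "IECResult",
    "NotEstimable",
    "INTERCHANGEABILITY_THRESHOLD",
    "compute_iec",
    "bootstrap_iec_ci",
    "iec_by_quality",
]

#: Upper 95% CI bound below which interchangeability is declared.
INTERCHANGEABILITY_THRESHOLD = 0.25


@dataclass(frozen=True)
class IECResult:
    """IEC point estimate, bootstrap CI and interchangeability verdict."""

    iec: float
    q_rr: float
    q_tr: float
    n_triads: int
    ci_low: float
    ci_high: float
    ci_level: float
    n_boot: int
    seed: int
    interchangeable: bool
    threshold: float = INTERCHANGEABILITY_THRESHOLD
    n_degenerate: int = 0       # bootstrap resamples skipped because Q_RR = 0
    degenerate_warning: bool = False


@dataclass(frozen=True)
class NotEstimable:
    """Placeholder for a stratum with too few triads to estimate the IEC."""

    n_triads: int
    reason: str


def _triad_arrays(triads: Sequence[Triad]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.asarray([tr.t for tr in triads], dtype=float)
    r1 = np.asarray([tr.r1 for tr in triads], dtype=float)
    r2 = np.asarray([tr.r2 for tr in triads], dtype=float)
    return t, r1, r2


def compute_iec(triads: Sequence[Triad]) -> tuple[float, float, float]:
    """Return (iec, q_rr, q_tr) for a collection of complete triads.

    Q_TR averages the two squared test-reference differences within each
    patient first, then across patients, making the patient the unit of
    analysis (and of bootstrap resampling). Symmetric in r1/r2.
    """
    if len(triads) < 2:
        raise InsufficientDataError(
            f"IEC needs at least 2 triads, got {len(triads)}"
        )
    t, r1, r2 = _triad_arrays(triads)
    q_rr = float(np.mean((r1 - r2) ** 2))
    q_tr = float(np.mean(((t - r1) ** 2 + (t - r2) ** 2) / 2.0))
    if q_rr == 0.0:
        raise DegenerateDataError(
            "IEC undefined: the two references are identical for every patient (Q_RR = 0)"
        )
    return (q_tr - q_rr) / (q_rr / 2.0), q_rr, q_tr


def bootstrap_iec_ci(
    triads: Sequence[Triad],
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
    threshold: float = INTERCHANGEABILITY_THRESHOLD,
    method: str = "percentile",
) -> IECResult:
    """Patient-level bootstrap confidence interval for the IEC.

    Triads (patients) are resampled with replacement ``n_boot`` times and the
    IEC recomputed per resample; resamples with Q_RR = 0 are skipped and
    counted (a warning flag is set when they exceed 10%). ``method`` is
    ``"percentile"`` (default) or ``"bca"`` (bias-corrected and accelerated).
    Deterministic given ``seed``.
    """
    if n_boot < 200:
        raise ConfigurationError("n_boot must be at least 200")
    if not 0 < ci_level < 1:
        raise ConfigurationError("ci_level must be in (0, 1)")
    if method not in ("percentile", "bca"):
        raise ConfigurationError(f"unknown CI method {method!r}")

    iec, q_rr, q_tr = compute_iec(triads)
    t, r1, r2 = _triad_arrays(triads)
    n = len(triads)
    d_rr = (r1 - r2) ** 2
    d_tr = ((t - r1) ** 2 + (t - r2) ** 2) / 2.0

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    q_rr_b = d_rr[idx].mean(axis=1)
    q_tr_b = d_tr[idx].mean(axis=1)
    valid = q_rr_b > 0
    n_degenerate = int(n_boot - valid.sum())
    if valid.sum() == 0:
        raise DegenerateDataError("every bootstrap resample had Q_RR = 0")
    iec_b = (q_tr_b[valid] - q_rr_b[valid]) / (q_rr_b[valid] / 2.0)

    alpha = 1.0 - ci_level
    if method == "percentile":
        ci_low, ci_high = np.quantile(iec_b, [alpha / 2, 1 - alpha / 2])
    else:
        ci_low, ci_high = _bca_interval(iec_b, iec, d_rr, d_tr, alpha)

    # degenerate point estimates (all resamples identical) can put the point
    # estimate at the quantile boundary; clamp for float fuzz only
    ci_low = min(ci_low, iec)
    ci_high = max(ci_high, iec)

    return IECResult(
        iec=iec,
        q_rr=q_rr,
        q_tr=q_tr,
        n_triads=n,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        ci_level=ci_level,
        n_boot=n_boot,
        seed=seed,
        interchangeable=bool(ci_high < threshold),
        threshold=threshold,
        n_degenerate=n_degenerate,
        degenerate_warning=n_degenerate > 0.10 * n_boot,
    )


def _bca_interval(
    iec_b: np.ndarray,
    iec_hat: float,
    d_rr: np.ndarray,
    d_tr: np.ndarray,
    alpha: float,
) -> tuple[float, float]:
    """Bias-corrected and accelerated percentile interval (jackknife a)."""
    from scipy.stats import norm

    n = len(d_rr)
    prop = np.mean(iec_b < iec_hat)
    prop = min(max(prop, 1.0 / (len(iec_b) + 1)), 1 - 1.0 / (len(iec_b) + 1))
    z0 = norm.ppf(prop)

    # leave-one-out IECs
    s_rr, s_tr = d_rr.sum(), d_tr.sum()
    q_rr_j = (s_rr - d_rr) / (n - 1)
    q_tr_j = (s_tr - d_tr) / (n - 1)
    ok = q_rr_j > 0
    theta_j = (q_tr_j[ok] - q_rr_j[ok]) / (q_rr_j[ok] / 2.0)
    theta_bar = theta_j.mean()
    num = ((theta_bar - theta_j) ** 3).sum()
    den = 6.0 * (((theta_bar - theta_j) ** 2).sum()) ** 1.5
    a = 0.0 if den == 0 else num / den

    def adj(q: float) -> float:
        z = norm.ppf(q)
        return float(norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z))))

    lo = np.quantile(iec_b, adj(alpha / 2))
    hi = np.quantile(iec_b, adj(1 - alpha / 2))
    return float(lo), float(hi)


def iec_by_quality(
    cohort: CohortTable,
    parameter: str,
    test: MethodId,
    refs: Sequence[MethodId],
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int = 0,
    threshold: float = INTERCHANGEABILITY_THRESHOLD,
    quality_device: Device | None = None,
) -> dict[str, IECResult | NotEstimable]:
    """IEC per image-quality category.

    Triads are partitioned by the quality grade of the ``quality_device``
    scan (default: the test method's device). Categories with fewer than two
    triads are reported as :class:`NotEstimable`, never silently dropped;
    empty categories are omitted.
    """
    triads = select_triads(cohort, parameter, test, refs, quality_device=quality_device)
    out: dict[str, IECResult | NotEstimable] = {}
    for level in QUALITY_LEVELS:
        group = [tr for tr in triads if tr.quality == level]
        if not group:
            continue
        if len(group) < 2:
            out[level] = NotEstimable(n_triads=len(group), reason="fewer than 2 triads")
            continue
        try:
            out[level] = bootstrap_iec_ci(
                group, n_boot=n_boot, ci_level=ci_level, seed=seed, threshold=threshold
            )
        except DegenerateDataError as exc:
            out[level] = NotEstimable(n_triads=len(group), reason=str(exc))
    return out
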