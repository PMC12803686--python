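"""Full-study orchestration: reporting rates, primary endpoint, IEC tables,
agreement summaries and image-quality stratification, written out as one
CSV/JSON pair per section plus a deterministic run log.

The study's analysis arms are configuration, not code: each IEC arm is a
(test method, two reference methods) tuple and each accuracy/agreement arm a
(test, reference) pair, so new comparisons need no code change. Any stage
failure is recorded and the remaining stages continue; the CLI maps recorded
failures to a non-zero exit status.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .accuracy import (
    AccuracySummary,
    accuracy_metrics,
    confusion_at_cutoff,
    empirical_auc,
    round_half_up,
)
from .agreement import AgreementSummary, bland_altman
from .cohort import (
    Analyst,
    CohortTable,
    ConfigurationError,
    Device,
    MethodId,
    select_triads,
    write_cohort,
)
from .interchangeability import (
    IECResult,
    NotEstimable,
    bootstrap_iec_ci,
    iec_by_quality,
)
from .simulate import CohortSpec, simulate_cohort

__all__ = [
    "ReportingRates",
    "IECArm",
    "PairArm",
    "AnalysisConfig",
    "StudyReport",
    "reporting_rates",
    "pair_average_pct",
    "run_study",
    "default_config",
]

log = logging.getLogger("echointerchange")

# Shorthand for the six study methods.
HH_AI = MethodId(Device.HANDHELD, Analyst.AI)
HH_CL1 = MethodId(Device.HANDHELD, Analyst.HUMAN_CORELAB_1)
HH_CL2 = MethodId(Device.HANDHELD, Analyst.HUMAN_CORELAB_2)
CART_AI = MethodId(Device.CART, Analyst.AI)
CART_CLIN = MethodId(Device.CART, Analyst.HUMAN_CLINICAL)
CART_CL1 = MethodId(Device.CART, Analyst.HUMAN_CORELAB_1)


# ---------------------------------------------------------------------------
# Reporting rates

@dataclass(frozen=True)
class ReportingRates:
    """Per-method reporting (non-missing) rates and named pair averages."""

    per_method: dict[str, tuple[int, int, float]]  # label -> (n_reported, n_total, rate)
    pair_averages: dict[str, float]                # name -> mean of component rates
    n_patients: int

    def display_pct(self, name: str) -> int:
        """Pair average as integer percent, rounded half-up (presentation)."""
        return int(round_half_up(100 * self.pair_averages[name]))


def pair_average_pct(*rates_pct: float) -> int:
    """Arithmetic mean of reporting percentages, rounded half-up to integer."""
    return int(round_half_up(sum(rates_pct) / len(rates_pct)))


def reporting_rates(
    cohort: CohortTable,
    parameter: str,
    pairs: Mapping[str, Sequence[MethodId]] | None = None,
) -> ReportingRates:
    """Fraction of patients with a reported value per method.

    The denominator is all patients in the cohort. ``pairs`` names groups of
    methods whose rates are averaged arithmetically (e.g. the two handheld
    core-laboratory readers); every method named must exist in the data.
    """
    if len(cohort) == 0:
        raise ConfigurationError("cohort is empty")
    if pairs is None:
        pairs = {
            "handheld_corelab_avg": (HH_CL1, HH_CL2),
            "cart_human_avg": (CART_CLIN, CART_CL1),
        }
    n_total = cohort.n_patients
    df = cohort.df[cohort.df["parameter"] == parameter]
    present = {m.label for m in cohort.methods(parameter)}

    per_method: dict[str, tuple[int, int, float]] = {}
    for m in cohort.methods(parameter):
        sub = df[(df["device"] == m.device.value) & (df["analyst"] == m.analyst.value)]
        n_rep = int(sub["value"].notna().sum())
        per_method[m.label] = (n_rep, n_total, n_rep / n_total)

    averages: dict[str, float] = {}
    for name, methods in pairs.items():
        missing = [m.label for m in methods if m.label not in present]
        if missing:
            raise ConfigurationError(
                f"reporting-rate pair {name!r} references unknown method(s): {missing}"
            )
        averages[name] = float(np.mean([per_method[m.label][2] for m in methods]))
    return ReportingRates(per_method=per_method, pair_averages=averages, n_patients=n_total)


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class IECArm:
    name: str
    parameter: str
    test: MethodId
    refs: tuple[MethodId, MethodId]


@dataclass(frozen=True)
class PairArm:
    name: str
    parameter: str
    test: MethodId
    reference: MethodId


def _default_iec_arms() -> tuple[IECArm, ...]:
    return (
        # secondary endpoint: AI on handheld vs. the two human cart reads
        IECArm("handheld_ai_vs_cart_humans", "lvef", HH_AI, (CART_CLIN, CART_CL1)),
        # exploratory: AI on cart vs. the two human cart reads
        IECArm("cart_ai_vs_cart_humans", "lvef", CART_AI, (CART_CLIN, CART_CL1)),
        # post hoc: AI on handheld vs. the two handheld core-lab reads
        IECArm("handheld_ai_vs_handheld_corelab", "lvef", HH_AI, (HH_CL1, HH_CL2)),
    )


def _default_agreement_arms() -> tuple[PairArm, ...]:
    return (
        PairArm("handheld_ai_vs_cart_corelab", "lvef", HH_AI, CART_CL1),
        PairArm("cart_ai_vs_cart_corelab", "lvef", CART_AI, CART_CL1),
    )


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything run_study needs: data source, arms, cutoff and bootstrap."""

    input: Path | CohortSpec               # CSV path or generator spec
    parameters: tuple[str, ...] = ("lvef",)
    accuracy_arm: PairArm = PairArm("primary_accuracy", "lvef", HH_AI, CART_CLIN)
    iec_arms: tuple[IECArm, ...] = field(default_factory=_default_iec_arms)
    agreement_arms: tuple[PairArm, ...] = field(default_factory=_default_agreement_arms)
    quality_arms: tuple[IECArm, ...] = ()  # defaults to the first two IEC arms
    cutoff: float = 40.0
    cutoff_inclusive: bool = True
    n_boot: int = 2000
    ci_level: float = 0.95
    seed: int = 0
    outdir: Path | None = None


def default_config(
    input: Path | CohortSpec,
    seed: int = 0,
    outdir: Path | None = None,
    n_boot: int = 2000,
    cutoff: float = 40.0,
    cutoff_inclusive: bool = True,
) -> AnalysisConfig:
    return AnalysisConfig(
        input=input, seed=seed, outdir=outdir, n_boot=n_boot,
        cutoff=cutoff, cutoff_inclusive=cutoff_inclusive,
    )


@dataclass
class StudyReport:
    sections: dict[str, object]
    failures: list[tuple[str, str]]
    seed: int
    outdir: Path | None = None

    @property
    def ok(self) -> bool:
        return not self.failures


# ---------------------------------------------------------------------------
# Serialization helpers

def _iec_row(arm: str, parameter: str, stratum: str,
             res: IECResult | NotEstimable) -> dict:
    if isinstance(res, NotEstimable):
        return dict(arm=arm, parameter=parameter, stratum=stratum,
                    n_triads=res.n_triads, iec=np.nan, ci_low=np.nan,
                    ci_high=np.nan, n_boot=0, seed=np.nan,
                    interchangeable=False, estimable=False, note=res.reason)
    return dict(arm=arm, parameter=parameter, stratum=stratum,
                n_triads=res.n_triads, iec=res.iec, ci_low=res.ci_low,
                ci_high=res.ci_high, n_boot=res.n_boot, seed=res.seed,
                interchangeable=res.interchangeable, estimable=True, note="")


def _accuracy_json(summary: AccuracySummary) -> dict:
    def m(est):
        if est is None:
            return None
        if not est.defined:
            return {"value": None, "reason": est.undefined_reason}
        return {"value": est.value, "ci_low": est.ci_low, "ci_high": est.ci_high}

    c = summary.counts
    return {
        "n": summary.n,
        "cutoff": summary.cutoff,
        "counts": {"tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn},
        "accuracy": m(summary.accuracy),
        "sensitivity": m(summary.sensitivity),
        "specificity": m(summary.specificity),
        "ppv": m(summary.ppv),
        "npv": m(summary.npv),
        "auc": m(summary.auc),
    }


def _agreement_row(arm: PairArm, s: AgreementSummary) -> dict:
    return dict(
        arm=arm.name, parameter=arm.parameter,
        test=arm.test.label, reference=arm.reference.label,
        n_pairs=s.n_pairs, mean_diff_test_minus_ref=s.mean_diff,
        mean_diff_ci_low=s.mean_diff_ci[0], mean_diff_ci_high=s.mean_diff_ci[1],
        sd_diff=s.sd_diff, loa_low=s.loa_low, loa_high=s.loa_high,
        pearson_r=s.pearson_r, r_pvalue=s.r_pvalue,
        prop_bias_slope=s.prop_bias_slope,
    )


def _write(outdir: Path, name: str, df: pd.DataFrame | None = None,
           payload: object = None) -> None:
    if df is not None:
        df.to_csv(outdir / f"{name}.csv", index=False)
    if payload is not None:
        with open(outdir / f"{name}.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _complete_pairs(cohort: CohortTable, parameter: str,
                    test: MethodId, ref: MethodId) -> list[tuple[float, float]]:
    df = cohort.df[cohort.df["parameter"] == parameter]

    def series(m: MethodId):
        sub = df[(df["device"] == m.device.value) & (df["analyst"] == m.analyst.value)]
        return sub.set_index("patient_id")["value"]

    joined = pd.concat({"t": series(test), "r": series(ref)}, axis=1).dropna()
    return list(joined.itertuples(index=False, name=None))


# ---------------------------------------------------------------------------
# Orchestration

def run_study(config: AnalysisConfig) -> StudyReport:
    """Execute the full analysis pipeline on a CSV cohort or a generated one.

    Stage order: reporting rates; primary-endpoint diagnostic accuracy;
    IEC per arm (with per-parameter rows, Table-2 shape); agreement
    summaries; image-quality-stratified IEC. Each stage's outputs are written
    (when ``outdir`` is set) as a CSV/JSON pair; a stage that fails is
    recorded and the pipeline continues.
    """
    t_start = time.perf_counter()
    sections: dict[str, object] = {}
    failures: list[tuple[str, str]] = []
    outdir = Path(config.outdir) if config.outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    if isinstance(config.input, CohortSpec):
        generated = simulate_cohort(config.input)
        cohort = generated.cohort
        if outdir is not None:
            write_cohort(cohort, outdir / "cohort.csv")
            pd.DataFrame({
                "patient_id": generated.patient_ids,
                "true_value": generated.truth,
                "reduced": generated.labels,
            }).to_csv(outdir / "truth.csv", index=False)
    else:
        from .cohort import read_cohort

        cohort = read_cohort(config.input)
    log.info("cohort loaded: %d patients, %d records, seed=%d",
             cohort.n_patients, len(cohort), config.seed)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
                log.info("stage %-12s ok      (%.2fs)", name, time.perf_counter() - t0)
            except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
                failures.append((name, str(exc)))
                log.warning("stage %-12s FAILED: %s", name, exc)
        return wrap

    # -- reporting rates ------------------------------------------------------
    @stage("rates")
    def _rates():
        rr = reporting_rates(cohort, config.parameters[0])
        sections["rates"] = rr
        df = pd.DataFrame(
            [(m, *v) for m, v in sorted(rr.per_method.items())],
            columns=["method", "n_reported", "n_total", "rate"],
        )
        payload = {
            "per_method": {m: {"n_reported": v[0], "n_total": v[1], "rate": v[2]}
                           for m, v in rr.per_method.items()},
            "pair_averages": rr.pair_averages,
            "pair_averages_display_pct": {k: rr.display_pct(k)
                                          for k in rr.pair_averages},
        }
        if outdir is not None:
            _write(outdir, "rates", df, payload)

    # -- primary endpoint -----------------------------------------------------
    @stage("accuracy")
    def _accuracy():
        arm = config.accuracy_arm
        pairs = _complete_pairs(cohort, arm.parameter, arm.test, arm.reference)
        counts = confusion_at_cutoff(pairs, config.cutoff, config.cutoff_inclusive)
        summary = accuracy_metrics(counts, config.ci_level, cutoff=config.cutoff)
        # risk score: lower LVEF = higher risk of the reduced-EF label
        scores = [(-t, (r <= config.cutoff) if config.cutoff_inclusive
                   else (r < config.cutoff)) for t, r in pairs]
        try:
            auc, auc_ci = empirical_auc(scores, config.ci_level)
            from .accuracy import MetricEstimate

            summary = dataclasses.replace(
                summary, auc=MetricEstimate(auc, auc_ci[0], auc_ci[1])
            )
        except Exception as exc:
            from .accuracy import MetricEstimate

            summary = dataclasses.replace(
                summary, auc=MetricEstimate(None, undefined_reason=str(exc))
            )
        sections["accuracy"] = summary
        payload = _accuracy_json(summary)
        rows = [{"metric": k, **(v or {})} for k, v in payload.items()
                if k in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "auc")]
        if outdir is not None:
            _write(outdir, "accuracy", pd.DataFrame(rows), payload)
            (outdir / "confusion.txt").write_text(counts.as_text() + "\n", encoding="utf-8")

    # -- IEC arms (Table-2 shape: one row per arm x parameter) ---------------
    @stage("iec")
    def _iec():
        rows = []
        results: dict[str, IECResult] = {}
        for arm in config.iec_arms:
            for parameter in config.parameters:
                try:
                    triads = select_triads(cohort, parameter, arm.test, arm.refs)
                    if len(triads) < 2:
                        rows.append(_iec_row(arm.name, parameter, "all",
                                             NotEstimable(len(triads),
                                                          "fewer than 2 triads")))
                        continue
                    res = bootstrap_iec_ci(
                        triads, n_boot=config.n_boot, ci_level=config.ci_level,
                        seed=config.seed,
                    )
                except Exception as exc:  # noqa: BLE001 - arms are isolated
                    failures.append((f"iec:{arm.name}:{parameter}", str(exc)))
                    log.warning("IEC arm %s (%s) skipped: %s", arm.name, parameter, exc)
                    continue
                results[f"{arm.name}:{parameter}"] = res
                rows.append(_iec_row(arm.name, parameter, "all", res))
        sections["iec"] = results
        df = pd.DataFrame(rows)
        if outdir is not None:
            _write(outdir, "iec", df,
                   {r["arm"] + ":" + r["parameter"]:
                    {k: v for k, v in r.items() if k not in ("arm", "parameter")}
                    for r in _jsonable_rows(rows)})

    # -- agreement ------------------------------------------------------------
    @stage("agreement")
    def _agreement():
        rows = []
        summaries: dict[str, AgreementSummary] = {}
        for arm in config.agreement_arms:
            try:
                pairs = _complete_pairs(cohort, arm.parameter, arm.test, arm.reference)
                s = bland_altman(pairs, ci_level=config.ci_level)
            except Exception as exc:  # noqa: BLE001 - arms are isolated
                failures.append((f"agreement:{arm.name}", str(exc)))
                log.warning("agreement arm %s skipped: %s", arm.name, exc)
                continue
            summaries[arm.name] = s
            rows.append(_agreement_row(arm, s))
            if outdir is not None:
                s.table.to_csv(outdir / f"agreement_pairs_{arm.name}.csv", index=False)
        sections["agreement"] = summaries
        if outdir is not None:
            _write(outdir, "agreement", pd.DataFrame(rows),
                   _jsonable_rows(rows))

    # -- image-quality stratification ----------------------------------------
    @stage("quality")
    def _quality():
        arms = config.quality_arms or config.iec_arms[:2]
        rows = []
        stratified: dict[str, dict] = {}
        for arm in arms:
            try:
                by_q = iec_by_quality(
                    cohort, arm.parameter, arm.test, arm.refs,
                    n_boot=config.n_boot, ci_level=config.ci_level, seed=config.seed,
                )
            except Exception as exc:  # noqa: BLE001 - arms are isolated
                failures.append((f"quality:{arm.name}", str(exc)))
                log.warning("quality arm %s skipped: %s", arm.name, exc)
                continue
            stratified[arm.name] = by_q
            for level, res in by_q.items():
                rows.append(_iec_row(arm.name, arm.parameter, level, res))
        sections["quality"] = stratified
        if outdir is not None:
            _write(outdir, "quality_iec", pd.DataFrame(rows), _jsonable_rows(rows))

    # -- run log --------------------------------------------------------------
    if outdir is not None:
        _write(outdir, "run_log", payload={
            "package": "echointerchange",
            "version": __version__,
            "seed": config.seed,
            "n_boot": config.n_boot,
            "ci_level": config.ci_level,
            "cutoff": config.cutoff,
            "cutoff_inclusive": config.cutoff_inclusive,
            "n_patients": cohort.n_patients,
            "n_records": len(cohort),
            "failures": [{"stage": s, "error": e} for s, e in failures],
        })
    log.info("study complete: %d stage failure(s), %.2fs total",
             len(failures), time.perf_counter() - t_start)
    return StudyReport(sections=sections, failures=failures,
                       seed=config.seed, outdir=outdir)


def _jsonable_rows(rows: list[dict]) -> list[dict]:
    out = []
    for r in rows:
        clean = {}
        for k, v in r.items():
            if isinstance(v, (float, np.floating)):
                clean[k] = None if pd.isna(v) else float(v)
            elif isinstance(v, (np.integer,)):
                clean[k] = int(v)
            elif isinstance(v, (np.bool_,)):
                clean[k] = bool(v)
            else:
                clean[k] = v
        out.append(clean)
    return out
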