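"""Domain types and delimited-text I/O for multi-reader, multi-device measurement tables.

A cohort is a long (tidy) table with one row per observed-or-missing value of
one echocardiographic parameter, for one patient, by one *method* — a method
being the combination of the acquisition device (handheld or cart-based
scanner) and the analyst that produced the measurement (the automated AI
software, the usual-care clinical sonographer, or one of the blinded
core-laboratory readers).

The study design has exactly one core-laboratory read of each cart scan and
two of each handheld scan, so the (cart, human_corelab_2) combination is
rejected at construction time.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Device",
    "Analyst",
    "MethodId",
    "MeasurementRecord",
    "CohortTable",
    "Triad",
    "PARAMETERS",
    "QUALITY_LEVELS",
    "COLUMNS",
    "SchemaError",
    "IntegrityError",
    "ConfigurationError",
    "InsufficientDataError",
    "DegenerateDataError",
    "read_cohort",
    "write_cohort",
    "select_triads",
]


# ---------------------------------------------------------------------------
# Errors

class SchemaError(ValueError):
    """A required column is absent or a field cannot be parsed."""


class IntegrityError(ValueError):
    """A table invariant is violated (duplicate keys, out-of-range values...)."""


class ConfigurationError(ValueError):
    """An analysis was configured with inconsistent methods or parameters."""


class InsufficientDataError(ValueError):
    """Too few observations to compute the requested statistic."""


class DegenerateDataError(ValueError):
    """The statistic is undefined on this input (e.g. identical references)."""


# ---------------------------------------------------------------------------
# Method identity

class Device(str, enum.Enum):
    HANDHELD = "handheld"
    CART = "cart"


class Analyst(str, enum.Enum):
    AI = "ai"
    HUMAN_CLINICAL = "human_clinical"
    HUMAN_CORELAB_1 = "human_corelab_1"
    HUMAN_CORELAB_2 = "human_corelab_2"


@dataclass(frozen=True, order=True)
class MethodId:
    """One measurement method: acquisition device x analyst."""

    device: Device
    analyst: Analyst

    def __post_init__(self) -> None:
        object.__setattr__(self, "device", Device(self.device))
        object.__setattr__(self, "analyst", Analyst(self.analyst))
        if self.device is Device.CART and self.analyst is Analyst.HUMAN_CORELAB_2:
            raise ConfigurationError(
                "cart scans have a single core-laboratory read; "
                "(cart, human_corelab_2) is not a valid method"
            )

    @property
    def label(self) -> str:
        return f"{self.device.value}:{self.analyst.value}"

    @classmethod
    def from_label(cls, label: str) -> "MethodId":
        device, _, analyst = label.partition(":")
        return cls(Device(device), Analyst(analyst))


# ---------------------------------------------------------------------------
# Parameters and quality

@dataclass(frozen=True)
class ParameterInfo:
    token: str
    name: str
    unit: str
    lo: float  # inclusive lower plausibility bound
    hi: float  # inclusive upper plausibility bound


def _p(token: str, name: str, unit: str, lo: float = 0.0, hi: float = math.inf) -> ParameterInfo:
    return ParameterInfo(token, name, unit, lo, hi)


#: Recognised echocardiographic parameters. Values outside the plausibility
#: window are rejected; LVEF is bounded in [5, 90] %, all others must be
#: strictly positive.
PARAMETERS: dict[str, ParameterInfo] = {
    p.token: p
    for p in [
        _p("lvef", "LV ejection fraction", "%", 5.0, 90.0),
        _p("lvedv", "LV end-diastolic volume", "ml"),
        _p("lvesv", "LV end-systolic volume", "ml"),
        _p("lvidd", "LV internal diameter, diastole", "cm"),
        _p("lvids", "LV internal diameter, systole", "cm"),
        _p("ivsdd", "interventricular septal diameter, diastole", "cm"),
        _p("lvpwd", "LV posterior wall, diastole", "cm"),
        _p("raa", "right atrial area", "cm^2"),
        _p("rvidd", "RV internal diameter, diastole", "cm"),
        _p("tapse", "tricuspid annular plane systolic excursion", "cm"),
        _p("la_volume", "left atrial volume", "ml"),
        _p("lv_mass", "LV mass", "g"),
        _p("mv_e", "mitral E velocity", "m/s"),
        _p("mv_a", "mitral A velocity", "m/s"),
        _p("mv_e_a", "mitral E/A ratio", ""),
        _p("mv_dect", "mitral deceleration time", "ms"),
        _p("e_e_prime_avg", "average E/e'", ""),
        _p("tv_peak_velocity", "tricuspid peak velocity", "m/s"),
    ]
}

#: Image-quality grades, ordered best to worst.
QUALITY_LEVELS: tuple[str, ...] = (
    "excellent",
    "good",
    "fair",
    "poor",
    "technically_difficult",
)

#: Canonical CSV column order.
COLUMNS: tuple[str, ...] = ("patient_id", "device", "analyst", "parameter", "value", "quality")


@dataclass(frozen=True)
class MeasurementRecord:
    """One observed (or missing) value of one parameter by one method.

    ``value`` is ``None`` when the method produced no usable measurement
    (the scan was not reportable); ``quality`` is the five-level image-quality
    grade of the scan, or ``None`` when ungraded.
    """

    patient_id: str
    method: MethodId
    parameter: str
    value: float | None
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise SchemaError(f"unknown parameter token {self.parameter!r}")
        if self.quality is not None and self.quality not in QUALITY_LEVELS:
            raise SchemaError(f"unknown quality label {self.quality!r}")
        if self.value is not None:
            info = PARAMETERS[self.parameter]
            if not math.isfinite(self.value):
                raise IntegrityError(
                    f"non-finite value for {self.parameter} of patient {self.patient_id}"
                )
            if info.lo > 0:
                ok = info.lo <= self.value <= info.hi
            else:  # strictly positive parameters
                ok = 0 < self.value <= info.hi
            if not ok:
                raise IntegrityError(
                    f"{self.parameter}={self.value} outside plausibility window "
                    f"[{info.lo}, {info.hi}] {info.unit}".rstrip()
                )


@dataclass(frozen=True)
class Triad:
    """One patient's test measurement plus two reference measurements.

    The unit of analysis for the individual equivalence coefficient:
    ``t`` is the test method's value (e.g. AI-automated handheld LVEF) and
    ``r1``/``r2`` the two human reference values. ``quality`` carries the
    image-quality grade used for stratified analyses.
    """

    patient_id: str
    t: float
    r1: float
    r2: float
    quality: str | None = None

    def __post_init__(self) -> None:
        for name in ("t", "r1", "r2"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise IntegrityError(f"triad field {name} must be finite, got {v!r}")

    def swapped(self) -> "Triad":
        return replace(self, r1=self.r2, r2=self.r1)


# ---------------------------------------------------------------------------
# Cohort table

class CohortTable:
    """A validated collection of measurement records.

    Internally a pandas DataFrame in canonical column order; ``records``
    materialises :class:`MeasurementRecord` objects on demand.
    """

    def __init__(self, records: Iterable[MeasurementRecord]):
        rows = []
        for rec in records:
            rows.append(
                (
                    str(rec.patient_id),
                    rec.method.device.value,
                    rec.method.analyst.value,
                    rec.parameter,
                    np.nan if rec.value is None else float(rec.value),
                    rec.quality,
                )
            )
        self._df = pd.DataFrame(rows, columns=list(COLUMNS))
        if self._df.empty:
            self._df = self._df.astype({"value": float})
        self._validate()

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortTable":
        obj = cls.__new__(cls)
        out = df.loc[:, list(COLUMNS)].copy()
        out["patient_id"] = out["patient_id"].astype(str)
        out["value"] = pd.to_numeric(out["value"], errors="raise").astype(float)
        out["quality"] = out["quality"].where(pd.notna(out["quality"]), None)
        obj._df = out.reset_index(drop=True)
        obj._validate()
        return obj

    def _validate(self) -> None:
        df = self._df
        bad_dev = set(df["device"]) - {d.value for d in Device}
        if bad_dev:
            raise SchemaError(f"unknown device labels: {sorted(bad_dev)}")
        bad_an = set(df["analyst"]) - {a.value for a in Analyst}
        if bad_an:
            raise SchemaError(f"unknown analyst labels: {sorted(bad_an)}")
        forbidden = (df["device"] == Device.CART.value) & (
            df["analyst"] == Analyst.HUMAN_CORELAB_2.value
        )
        if forbidden.any():
            raise ConfigurationError(
                "cart scans have a single core-laboratory read; found cart/human_corelab_2 rows"
            )
        bad_par = set(df["parameter"]) - set(PARAMETERS)
        if bad_par:
            raise SchemaError(f"unknown parameter tokens: {sorted(bad_par)}")
        bad_q = set(df["quality"].dropna()) - set(QUALITY_LEVELS)
        if bad_q:
            raise SchemaError(f"unknown quality labels: {sorted(bad_q)}")

        dup = df.duplicated(subset=["patient_id", "device", "analyst", "parameter"])
        if dup.any():
            first = df.loc[dup.idxmax(), ["patient_id", "device", "analyst", "parameter"]]
            raise IntegrityError(
                "duplicate (patient, method, parameter) key: "
                f"({first['patient_id']}, {first['device']}:{first['analyst']}, "
                f"{first['parameter']})"
            )

        # plausibility windows
        for token, grp in df.dropna(subset=["value"]).groupby("parameter"):
            info = PARAMETERS[token]
            vals = grp["value"].to_numpy()
            if token == "lvef":
                bad = (vals < info.lo) | (vals > info.hi)
            else:
                bad = (vals <= 0) | (vals > info.hi)
            if bad.any():
                raise IntegrityError(
                    f"{token} value {vals[bad][0]} outside plausibility window"
                )

        # quality is a property of the (patient, device) scan: must be
        # consistent across the records that carry it
        q = df.dropna(subset=["quality"])
        if not q.empty:
            nuniq = q.groupby(["patient_id", "device"])["quality"].nunique()
            if (nuniq > 1).any():
                pid, dev = nuniq[nuniq > 1].index[0]
                raise IntegrityError(
                    f"inconsistent quality labels for patient {pid} on {dev} scan"
                )

    # -- accessors ------------------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self._df["patient_id"]))

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return sorted(self.records, key=_record_key) == sorted(other.records, key=_record_key)

    @property
    def records(self) -> list[MeasurementRecord]:
        out = []
        for row in self._df.itertuples(index=False):
            out.append(
                MeasurementRecord(
                    patient_id=row.patient_id,
                    method=MethodId(Device(row.device), Analyst(row.analyst)),
                    parameter=row.parameter,
                    value=None if pd.isna(row.value) else float(row.value),
                    quality=None if row.quality is None or pd.isna(row.quality) else row.quality,
                )
            )
        return out

    def methods(self, parameter: str | None = None) -> list[MethodId]:
        df = self._df if parameter is None else self._df[self._df["parameter"] == parameter]
        pairs = df[["device", "analyst"]].drop_duplicates().itertuples(index=False)
        return sorted(MethodId(Device(d), Analyst(a)) for d, a in pairs)


def _record_key(r: MeasurementRecord):
    return (r.patient_id, r.method.device.value, r.method.analyst.value, r.parameter,
            -math.inf if r.value is None else r.value, r.quality or "")


# ---------------------------------------------------------------------------
# I/O

_DEFAULT_SCHEMA = {c: c for c in COLUMNS}


def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None) -> CohortTable:
    """Read a cohort from a UTF-8, comma-delimited file.

    ``schema`` maps the canonical column names (``patient_id``, ``device``,
    ``analyst``, ``parameter``, ``value``, ``quality``) to the names used in
    the file header. Empty value/quality fields become missing; malformed
    numeric fields raise :class:`SchemaError` rather than being dropped.
    """
    schema = {**_DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing_cols = [schema[c] for c in COLUMNS if schema[c] not in df.columns]
    if missing_cols:
        raise SchemaError(f"required column(s) missing from {path}: {missing_cols}")
    df = df.rename(columns={v: k for k, v in schema.items()})[list(COLUMNS)]

    raw = df["value"].str.strip()
    value = pd.to_numeric(raw.replace({"": None}), errors="coerce")
    malformed = value.isna() & raw.ne("")
    if malformed.any():
        i = int(malformed.idxmax())
        raise SchemaError(
            f"malformed numeric value {raw[i]!r} in row {i + 2} of {path}"
        )
    df["value"] = value
    df["quality"] = df["quality"].str.strip().replace({"": None})
    return CohortTable.from_dataframe(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    """Write a cohort as CSV with deterministic row and column order.

    Rows are sorted by (patient_id, device, analyst, parameter); missing
    values are written as empty fields.
    """
    path = Path(path)
    df = cohort.df.sort_values(
        ["patient_id", "device", "analyst", "parameter"], kind="mergesort"
    )
    df.to_csv(path, index=False, encoding="utf-8", na_rep="")
    return path


# ---------------------------------------------------------------------------
# Triad selection

def select_triads(
    cohort: CohortTable,
    parameter: str,
    test: MethodId,
    refs: Sequence[MethodId],
    quality_device: Device | None = None,
) -> list[Triad]:
    """Select complete (test, reference-1, reference-2) triples per patient.

    A patient contributes a triad only when all three methods report a
    non-missing value for ``parameter`` (complete-triad rule); everyone else
    is excluded. The triad carries the image-quality grade of the
    ``quality_device`` scan (default: the test method's device) for
    stratified analyses.
    """
    if parameter not in PARAMETERS:
        raise SchemaError(f"unknown parameter token {parameter!r}")
    r1, r2 = refs
    if r1 == r2:
        raise ConfigurationError("the two reference methods must be distinct")
    for r in (r1, r2):
        if r.analyst is Analyst.AI:
            raise ConfigurationError("reference methods must be human analysts")
        if r == test:
            raise ConfigurationError("test method equals a reference method")
    if quality_device is None:
        quality_device = test.device

    df = cohort.df[cohort.df["parameter"] == parameter]
    by_method = {}
    for m in (test, r1, r2):
        sub = df[(df["device"] == m.device.value) & (df["analyst"] == m.analyst.value)]
        by_method[m] = sub.set_index("patient_id")["value"]

    qsub = df[df["device"] == quality_device.value].dropna(subset=["quality"])
    quality = qsub.groupby("patient_id")["quality"].first()

    triads = []
    for pid in cohort.patients:
        vals = [by_method[m].get(pid, np.nan) for m in (test, r1, r2)]
        if any(pd.isna(v) for v in vals):
            continue
        triads.append(
            Triad(pid, float(vals[0]), float(vals[1]), float(vals[2]),
                  quality=quality.get(pid))
        )
    return triads
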