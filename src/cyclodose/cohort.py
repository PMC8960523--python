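"""Domain types, validation and tabular I/O for multi-cycle dosimetry cohorts.

A cohort is a list of :class:`PatientCourse` objects, each holding one
:class:`CycleDose` record per treatment cycle.  The packaged six-patient,
four-cycle reference cohort is exposed through :func:`ludo_fixture`.

File formats
------------
Cohort CSV
    columns ``patient_id, sex, gfr_ml_min, cycle, aa_gbq, weight_kg,
    tumour_ad_gy, kidney_ad_gy, tumour_teff_h, kidney_teff_h``;
    UTF-8, dot decimal separator, one row per patient-cycle.
Series CSV
    columns ``patient_id, cycle, structure, time_h, rate_gy_per_h``.

Both formats also have a JSON mirror with identical field names
(a list of row objects).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TUMOUR",
    "KIDNEY",
    "KIDNEY_LEFT",
    "KIDNEY_RIGHT",
    "STRUCTURES",
    "CohortSchemaError",
    "CycleDose",
    "PatientCourse",
    "DoseRateSample",
    "DoseRateSeries",
    "load_cohort",
    "write_cohort",
    "load_series",
    "write_series",
    "ludo_fixture",
    "validate_course",
]

TUMOUR = "tumour"
KIDNEY = "kidney"  # left/right mean, as stored in cohort tables
KIDNEY_LEFT = "kidney_left"
KIDNEY_RIGHT = "kidney_right"
STRUCTURES = (TUMOUR, KIDNEY_LEFT, KIDNEY_RIGHT)

COHORT_COLUMNS = [
    "patient_id",
    "sex",
    "gfr_ml_min",
    "cycle",
    "aa_gbq",
    "weight_kg",
    "tumour_ad_gy",
    "kidney_ad_gy",
    "tumour_teff_h",
    "kidney_teff_h",
]

SERIES_COLUMNS = ["patient_id", "cycle", "structure", "time_h", "rate_gy_per_h"]


class CohortSchemaError(ValueError):
    """Raised when an input file violates the cohort or series schema."""


@dataclass(frozen=True)
class CycleDose:
    """One patient-cycle dosimetry record.

    Kidney fields hold the left/right mean; cycle indices are 1-based.
    """

    patient_id: str
    cycle_index: int
    aa_gbq: float
    weight_kg: float
    tumour_ad_gy: float
    kidney_ad_gy: float
    tumour_teff_h: float
    kidney_teff_h: float

    @property
    def aa_per_weight_mbq_kg(self) -> float:
        """Administered activity per unit body weight, MBq/kg."""
        return 1000.0 * self.aa_gbq / self.weight_kg

    def ad_gy(self, structure: str) -> float:
        if structure == TUMOUR:
            return self.tumour_ad_gy
        if structure == KIDNEY:
            return self.kidney_ad_gy
        raise ValueError(f"unknown structure {structure!r}")

    def teff_h(self, structure: str) -> float:
        if structure == TUMOUR:
            return self.tumour_teff_h
        if structure == KIDNEY:
            return self.kidney_teff_h
        raise ValueError(f"unknown structure {structure!r}")

    def ad_per_aa(self, structure: str) -> float:
        """Absorbed dose per unit administered activity, Gy/GBq."""
        return self.ad_gy(structure) / self.aa_gbq


@dataclass(frozen=True)
class PatientCourse:
    """A patient's full treatment course: demographics plus ordered cycles."""

    patient_id: str
    sex: str
    gfr: float  # mL/min
    cycles: tuple[CycleDose, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cycles", tuple(self.cycles))

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def cycle(self, index: int) -> CycleDose:
        """Return the cycle with 1-based ``index``; KeyError if absent."""
        for c in self.cycles:
            if c.cycle_index == index:
                return c
        raise KeyError(f"{self.patient_id}: no cycle {index}")


def validate_course(course: PatientCourse) -> list[str]:
    """Check all course invariants, returning human-readable findings.

    An empty list means the course is valid.  This never raises: it is the
    inspection counterpart of the hard validation done by :func:`load_cohort`.
    """
    findings: list[str] = []
    pid = course.patient_id
    if course.sex not in ("F", "M"):
        findings.append(f"{pid}: sex must be F or M, got {course.sex!r}")
    if not (course.gfr > 0):
        findings.append(f"{pid}: GFR must be > 0, got {course.gfr}")
    if course.n_cycles < 1:
        findings.append(f"{pid}: at least one cycle required")
    indices = [c.cycle_index for c in course.cycles]
    if len(set(indices)) != len(indices):
        findings.append(f"{pid}: duplicate cycle indices {indices}")
    elif indices != list(range(1, len(indices) + 1)):
        findings.append(f"{pid}: non-contiguous cycles {indices}")
    for c in course.cycles:
        tag = f"{pid} cycle {c.cycle_index}"
        if c.patient_id != pid:
            findings.append(f"{tag}: patient_id mismatch ({c.patient_id!r})")
        if not (c.aa_gbq > 0):
            findings.append(f"{tag}: administered activity must be > 0, got {c.aa_gbq}")
        if not (c.weight_kg > 0):
            findings.append(f"{tag}: weight must be > 0, got {c.weight_kg}")
        for name in ("tumour_ad_gy", "kidney_ad_gy", "tumour_teff_h", "kidney_teff_h"):
            v = getattr(c, name)
            if not (math.isfinite(v) and v >= 0):
                findings.append(f"{tag}: {name} must be finite and >= 0, got {v}")
    return findings


@dataclass(frozen=True)
class DoseRateSample:
    """A single absorbed-dose-rate measurement."""

    time_h: float
    rate_gy_per_h: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time_h) and self.time_h >= 0):
            raise ValueError(f"time must be finite and >= 0, got {self.time_h}")
        if not (math.isfinite(self.rate_gy_per_h) and self.rate_gy_per_h >= 0):
            raise ValueError(
                f"rate must be finite and >= 0, got {self.rate_gy_per_h}"
            )


@dataclass(frozen=True)
class DoseRateSeries:
    """Timestamped dose-rate samples for one structure in one cycle.

    Times must be unique and strictly increasing.  The nominal schedule is
    4/24/48/72 h post-injection but arbitrary positive times are accepted.
    """

    patient_id: str
    cycle_index: int
    structure: str
    samples: tuple[DoseRateSample, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        if self.structure not in STRUCTURES:
            raise ValueError(
                f"structure must be one of {STRUCTURES}, got {self.structure!r}"
            )
        times = self.times_h
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be unique and strictly increasing")

    @property
    def times_h(self) -> tuple[float, ...]:
        return tuple(s.time_h for s in self.samples)

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(s.rate_gy_per_h for s in self.samples)


# ---------------------------------------------------------------------------
# I/O


def _courses_from_frame(df: pd.DataFrame, source: str) -> list[PatientCourse]:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{source}: missing columns {missing}")
    numeric = [c for c in COHORT_COLUMNS if c not in ("patient_id", "sex")]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise CohortSchemaError(
                f"{source}: non-numeric value in column {col!r}, row {bad[0]} "
                f"({df.loc[bad[0], col]!r})"
            )
        if coerced.isna().any():
            row = int(coerced.index[coerced.isna()][0])
            raise CohortSchemaError(f"{source}: missing value in column {col!r}, row {row}")
        df[col] = coerced

    dup = df.duplicated(subset=["patient_id", "cycle"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise CohortSchemaError(
            f"{source}: duplicate (patient, cycle) = ({row.patient_id}, {int(row.cycle)})"
        )

    courses: list[PatientCourse] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("cycle")
        cycles = tuple(
            CycleDose(
                patient_id=str(pid),
                cycle_index=int(r.cycle),
                aa_gbq=float(r.aa_gbq),
                weight_kg=float(r.weight_kg),
                tumour_ad_gy=float(r.tumour_ad_gy),
                kidney_ad_gy=float(r.kidney_ad_gy),
                tumour_teff_h=float(r.tumour_teff_h),
                kidney_teff_h=float(r.kidney_teff_h),
            )
            for r in grp.itertuples()
        )
        course = PatientCourse(
            patient_id=str(pid),
            sex=str(grp.sex.iloc[0]),
            gfr=float(grp.gfr_ml_min.iloc[0]),
            cycles=cycles,
        )
        findings = validate_course(course)
        if findings:
            raise CohortSchemaError(f"{source}: " + "; ".join(findings))
        courses.append(course)
    return courses


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def load_cohort(path: str | Path, format: str | None = None) -> list[PatientCourse]:
    """Load and validate a cohort file (CSV or JSON).

    Raises :class:`CohortSchemaError` naming the offending column/row on any
    schema violation.  An empty table (header only) yields an empty list.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        rows = json.loads(path.read_text())
        df = pd.DataFrame(rows, columns=COHORT_COLUMNS if not rows else None)
    else:
        df = pd.read_csv(path)
    if df.empty:
        return []
    return _courses_from_frame(df, str(path))


def cohort_frame(cohort: Iterable[PatientCourse]) -> pd.DataFrame:
    """Flatten a cohort into the canonical one-row-per-cycle table."""
    rows = [
        {
            "patient_id": course.patient_id,
            "sex": course.sex,
            "gfr_ml_min": course.gfr,
            "cycle": c.cycle_index,
            "aa_gbq": c.aa_gbq,
            "weight_kg": c.weight_kg,
            "tumour_ad_gy": c.tumour_ad_gy,
            "kidney_ad_gy": c.kidney_ad_gy,
            "tumour_teff_h": c.tumour_teff_h,
            "kidney_teff_h": c.kidney_teff_h,
        }
        for course in cohort
        for c in course.cycles
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(
    cohort: Iterable[PatientCourse], path: str | Path, format: str | None = None
) -> None:
    """Write a cohort as CSV or JSON (inverse of :func:`load_cohort`)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    df = cohort_frame(cohort)
    if fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        df.to_csv(path, index=False)


def load_series(path: str | Path, format: str | None = None) -> list[DoseRateSeries]:
    """Load dose-rate series grouped by (patient, cycle, structure)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        rows = json.loads(path.read_text())
        df = pd.DataFrame(rows)
        if df.empty:
            return []
    else:
        df = pd.read_csv(path)
        if df.empty:
            return []
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing columns {missing}")
    out: list[DoseRateSeries] = []
    for (pid, cyc, struct), grp in df.groupby(
        ["patient_id", "cycle", "structure"], sort=False
    ):
        grp = grp.sort_values("time_h")
        samples = tuple(
            DoseRateSample(float(t), float(r))
            for t, r in zip(grp.time_h, grp.rate_gy_per_h)
        )
        out.append(DoseRateSeries(str(pid), int(cyc), str(struct), samples))
    return out


def write_series(
    series: Iterable[DoseRateSeries], path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    rows = [
        {
            "patient_id": s.patient_id,
            "cycle": s.cycle_index,
            "structure": s.structure,
            "time_h": smp.time_h,
            "rate_gy_per_h": smp.rate_gy_per_h,
        }
        for s in series
        for smp in s.samples
    ]
    df = pd.DataFrame(rows, columns=SERIES_COLUMNS)
    if fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        df.to_csv(path, index=False)


def ludo_fixture() -> list[PatientCourse]:
    """The packaged six-patient, four-cycle reference cohort.

    Values are stored at printed precision; kidney dose and half-life are the
    left/right means.  Where the source table's concatenated cumulative
    columns are typographically ambiguous, the packaged values are the ones
    consistent with the per-cycle sums.
    """
    ref = resources.files("cyclodose").joinpath("data/ludo_cohort.csv")
    with resources.as_file(ref) as p:
        return load_cohort(p, format="csv")
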