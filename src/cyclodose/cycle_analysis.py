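"""Inter-cycle comparisons: relative differences, cumulative doses,
per-cycle contribution fractions and cohort summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import KIDNEY, TUMOUR, CycleDose, PatientCourse
from .stats import median_range

__all__ = [
    "METRICS",
    "CycleDelta",
    "CohortSummary",
    "cycle_metric",
    "relative_difference",
    "cycle_delta",
    "cohort_deltas",
    "cumulative_doses",
    "contribution_fractions",
    "cohort_summary",
    "summary_table",
]

#: metrics understood by cycle_metric / cohort_summary
METRICS = ("ad_gy", "ad_per_aa", "teff_h")


def cycle_metric(cycle: CycleDose, metric: str, structure: str) -> float:
    """Extract one scalar metric from a cycle record."""
    if structure not in (TUMOUR, KIDNEY):
        raise ValueError(f"structure must be tumour or kidney, got {structure!r}")
    if metric == "ad_gy":
        return cycle.ad_gy(structure)
    if metric == "ad_per_aa":
        return cycle.ad_per_aa(structure)
    if metric == "teff_h":
        return cycle.teff_h(structure)
    raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")


@dataclass(frozen=True)
class CycleDelta:
    """Signed relative difference of a metric between two cycles of a patient.

    ``delta_pct`` follows the signed convention
    ``100 * (v_comparison - v_reference) / v_reference``; ``decrease_pct`` is
    its negation, matching the percent-decrease convention.
    """

    patient_id: str
    metric: str
    structure: str
    reference_cycle: int
    comparison_cycle: int
    delta_pct: float

    @property
    def decrease_pct(self) -> float:
        return -self.delta_pct


@dataclass(frozen=True)
class CohortSummary:
    metric: str
    structure: str
    cycle: int | None  # None = pooled over all cycles
    median: float
    range_min: float
    range_max: float
    n: int


def relative_difference(v1: float, v_ni: float) -> float:
    """Signed percent difference ``100 * (v_ni - v1) / v1``; requires v1 > 0."""
    if not v1 > 0:
        raise ValueError(f"reference value must be > 0, got {v1}")
    return 100.0 * (v_ni - v1) / v1


def cycle_delta(
    course: PatientCourse,
    metric: str,
    structure: str,
    comparison_cycle: int,
    reference_cycle: int = 1,
) -> CycleDelta:
    if comparison_cycle == reference_cycle:
        raise ValueError("reference and comparison cycles must differ")
    v1 = cycle_metric(course.cycle(reference_cycle), metric, structure)
    v_ni = cycle_metric(course.cycle(comparison_cycle), metric, structure)
    return CycleDelta(
        patient_id=course.patient_id,
        metric=metric,
        structure=structure,
        reference_cycle=reference_cycle,
        comparison_cycle=comparison_cycle,
        delta_pct=relative_difference(v1, v_ni),
    )


def cohort_deltas(
    cohort: Iterable[PatientCourse],
    metric: str,
    structure: str,
    comparison_cycle: int,
    reference_cycle: int = 1,
) -> list[CycleDelta]:
    """Per-patient deltas for every course that has both cycles."""
    out = []
    for course in cohort:
        try:
            course.cycle(reference_cycle)
            course.cycle(comparison_cycle)
        except KeyError:
            continue
        out.append(
            cycle_delta(course, metric, structure, comparison_cycle, reference_cycle)
        )
    return out


def cumulative_doses(course: PatientCourse, structure: str) -> list[float]:
    """Running cumulative absorbed dose, one value per cycle in cycle order."""
    ads = [cycle_metric(c, "ad_gy", structure) for c in course.cycles]
    return list(np.cumsum(ads))


def contribution_fractions(course: PatientCourse, structure: str) -> list[float]:
    """Each cycle's percent contribution to the final cumulative dose."""
    ads = np.array([cycle_metric(c, "ad_gy", structure) for c in course.cycles])
    total = float(ads.sum())
    if not total > 0:
        raise ValueError(f"{course.patient_id}: zero total {structure} dose")
    return list(100.0 * ads / total)


def cohort_summary(
    cohort: Sequence[PatientCourse],
    metric: str,
    structure: str,
    cycle: int | None,
) -> CohortSummary:
    """Median and range of a metric across the cohort.

    ``cycle=None`` pools all patient-cycles (the "median row" convention).
    """
    values = []
    for course in cohort:
        for c in course.cycles:
            if cycle is None or c.cycle_index == cycle:
                values.append(cycle_metric(c, metric, structure))
    if not values:
        raise ValueError(f"no data for {metric}/{structure} cycle {cycle}")
    med, lo, hi = median_range(values)
    return CohortSummary(metric, structure, cycle, med, lo, hi, len(values))


def summary_table(cohort: Sequence[PatientCourse]) -> pd.DataFrame:
    """Per-cycle and pooled medians/ranges for every metric and structure."""
    n_cycles = max(c.cycle_index for course in cohort for c in course.cycles)
    rows = []
    for structure in (TUMOUR, KIDNEY):
        for metric in METRICS:
            for cycle in [*range(1, n_cycles + 1), None]:
                s = cohort_summary(cohort, metric, structure, cycle)
                rows.append(
                    {
                        "metric": metric,
                        "structure": structure,
                        "cycle": "all" if cycle is None else cycle,
                        "n": s.n,
                        "median": s.median,
                        "min": s.range_min,
                        "max": s.range_max,
                    }
                )
    return pd.DataFrame(rows)
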