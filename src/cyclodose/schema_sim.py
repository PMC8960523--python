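"""Fixed dose-per-activity prescription schema and delivered/expected ratios.

The schema predicts the absorbed dose of a non-initial cycle as the cycle-1
dose-per-activity quotient times the later cycle's administered activity:
``AD_expected = (AD_1 / AA_1) * AA_cycle``.  Delivered/expected ratios
quantify how far actual biokinetics drift from the stable-biokinetics
assumption; cycle 1 has ratio 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import KIDNEY, TUMOUR, PatientCourse
from .stats import mann_whitney, median_range

__all__ = ["SchemaResult", "expected_ad", "delivered_expected_ratio", "schema_table"]


@dataclass(frozen=True)
class SchemaResult:
    """Expected vs delivered absorbed dose for one patient-cycle."""

    patient_id: str
    cycle_index: int
    structure: str
    ad_expected_gy: float
    ad_delivered_gy: float

    @property
    def ratio(self) -> float:
        return self.ad_delivered_gy / self.ad_expected_gy


def expected_ad(
    course: PatientCourse,
    structure: str,
    cycle: int,
    reference_cycle: int = 1,
) -> float:
    """Predicted absorbed dose for ``cycle`` assuming reference-cycle kinetics.

    For the reference cycle itself this returns the delivered dose (identity).
    """
    if structure not in (TUMOUR, KIDNEY):
        raise ValueError(f"structure must be tumour or kidney, got {structure!r}")
    try:
        ref = course.cycle(reference_cycle)
    except KeyError as e:
        raise ValueError(f"no reference cycle {reference_cycle}") from e
    if cycle == reference_cycle:
        return ref.ad_gy(structure)
    target = course.cycle(cycle)
    if not (ref.ad_gy(structure) > 0 and ref.aa_gbq > 0):
        raise ValueError(
            f"{course.patient_id}: reference-cycle dose and activity must be > 0"
        )
    return ref.ad_gy(structure) / ref.aa_gbq * target.aa_gbq


def delivered_expected_ratio(
    course: PatientCourse,
    structure: str,
    cycle: int,
    reference_cycle: int = 1,
) -> SchemaResult:
    """Delivered and expected dose (and their ratio) for one patient-cycle."""
    exp = expected_ad(course, structure, cycle, reference_cycle)
    if exp == 0:
        raise ValueError(f"{course.patient_id} cycle {cycle}: expected dose is zero")
    delivered = course.cycle(cycle).ad_gy(structure)
    return SchemaResult(
        patient_id=course.patient_id,
        cycle_index=cycle,
        structure=structure,
        ad_expected_gy=exp,
        ad_delivered_gy=delivered,
    )


def schema_table(
    cohort: Sequence[PatientCourse], reference_cycle: int = 1
) -> pd.DataFrame:
    """Per-cycle medians and ranges of expected, delivered and ratio.

    One row per structure and cycle, with an unpaired two-sample rank-test
    p-value comparing delivered against expected doses (NaN for the
    reference cycle, where the two coincide by construction).
    """
    n_cycles = max(c.cycle_index for course in cohort for c in course.cycles)
    rows = []
    for structure in (TUMOUR, KIDNEY):
        for cycle in range(1, n_cycles + 1):
            results = [
                delivered_expected_ratio(course, structure, cycle, reference_cycle)
                for course in cohort
                if any(c.cycle_index == cycle for c in course.cycles)
            ]
            expected = [r.ad_expected_gy for r in results]
            delivered = [r.ad_delivered_gy for r in results]
            ratios = [r.ratio for r in results]
            e_med, e_lo, e_hi = median_range(expected)
            d_med, d_lo, d_hi = median_range(delivered)
            r_med, r_lo, r_hi = median_range(ratios)
            if cycle == reference_cycle:
                p = np.nan
            else:
                p = mann_whitney(delivered, expected).p_value
            rows.append(
                {
                    "structure": structure,
                    "cycle": cycle,
                    "expected_median": e_med,
                    "expected_min": e_lo,
                    "expected_max": e_hi,
                    "delivered_median": d_med,
                    "delivered_min": d_lo,
                    "delivered_max": d_hi,
                    "ratio_median": r_med,
                    "ratio_min": r_lo,
                    "ratio_max": r_hi,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
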