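"""Synthetic multi-cycle cohort generator with known ground truth.

Dose-rate curves follow an uptake-then-clearance biexponential,
``rate(t) = A * (exp(-lambda*t) - exp(-mu*t))`` with clearance slower than
uptake (lambda < mu), so the zero-rate anchor at injection time is exactly
right and the closed-form dose ``A * (1/lambda - 1/mu)`` serves as an
integration oracle.  Tumour amplitude declines geometrically across cycles;
kidney kinetics are held constant.  Measurement noise is multiplicative
lognormal with mean 1.  All randomness flows from a single seed through
spawned per-patient streams, so patient i's data do not depend on cohort
size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import (
    KIDNEY_LEFT,
    KIDNEY_RIGHT,
    TUMOUR,
    CycleDose,
    DoseRateSample,
    DoseRateSeries,
    PatientCourse,
)

__all__ = [
    "SyntheticTruth",
    "SimulationConfig",
    "SyntheticCohort",
    "generate_cohort",
    "true_absorbed_dose",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth kinetic parameters for one simulated structure-cycle."""

    patient_id: str
    cycle_index: int
    structure: str
    amplitude_gy_per_h: float  # A, after any per-cycle decline
    uptake_halftime_h: float  # ln2 / mu
    clearance_teff_h: float  # ln2 / lambda
    uptake_decline_factor: float

    @property
    def rate_lambda(self) -> float:
        return LN2 / self.clearance_teff_h

    @property
    def rate_mu(self) -> float:
        return LN2 / self.uptake_halftime_h

    @property
    def true_ad_gy(self) -> float:
        return true_absorbed_dose(self)

    def rate(self, t: np.ndarray | float) -> np.ndarray | float:
        """Noiseless dose rate at time t (hours)."""
        lam, mu = self.rate_lambda, self.rate_mu
        return self.amplitude_gy_per_h * (np.exp(-lam * t) - np.exp(-mu * t))


def true_absorbed_dose(truth: SyntheticTruth) -> float:
    """Closed-form integral of the biexponential over [0, inf), in Gy."""
    lam, mu = truth.rate_lambda, truth.rate_mu
    if lam >= mu:
        raise ValueError(
            f"clearance must be slower than uptake (lambda < mu), "
            f"got lambda={lam:.4g}, mu={mu:.4g}"
        )
    return truth.amplitude_gy_per_h * (1.0 / lam - 1.0 / mu)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for :func:`generate_cohort`; ``seed`` is mandatory."""

    seed: int
    n_patients: int = 6
    n_cycles: int = 4
    weight_range_kg: tuple[float, float] = (15.0, 45.0)
    #: MBq/kg per cycle; last entry repeats for any further cycles
    aa_schedule_mbq_kg: tuple[float, ...] = (75.0, 100.0)
    noise_cv: float = 0.10
    sample_times_h: tuple[float, ...] = (4.0, 24.0, 48.0, 72.0)
    uptake_halftime_h: float = 2.0
    uptake_decline_factor: float = 0.7
    tumour_teff_range_h: tuple[float, float] = (25.0, 55.0)
    kidney_teff_range_h: tuple[float, float] = (40.0, 150.0)
    #: peak-scale dose-rate coefficient per unit administered activity,
    #: Gy/h per GBq; the cycle amplitude is this times the cycle's activity
    tumour_amp_per_aa_range: tuple[float, float] = (0.05, 0.20)
    kidney_amp_per_aa_range: tuple[float, float] = (0.003, 0.012)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_patients < 1 or self.n_cycles < 1:
            raise ValueError("n_patients and n_cycles must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 < self.uptake_decline_factor <= 1:
            raise ValueError("uptake_decline_factor must be in (0, 1]")
        if any(t <= 0 for t in self.sample_times_h):
            raise ValueError("sample times must be > 0")
        lo = min(self.tumour_teff_range_h[0], self.kidney_teff_range_h[0])
        if lo <= self.uptake_halftime_h:
            raise ValueError("clearance half-lives must exceed the uptake half-time")

    def aa_mbq_kg(self, cycle: int) -> float:
        idx = min(cycle - 1, len(self.aa_schedule_mbq_kg) - 1)
        return self.aa_schedule_mbq_kg[idx]


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated courses (truth-level dose fields), noisy series and truths."""

    courses: tuple[PatientCourse, ...]
    series: tuple[DoseRateSeries, ...]
    truths: tuple[SyntheticTruth, ...]

    def series_for(
        self, patient_id: str, cycle: int, structure: str
    ) -> DoseRateSeries:
        for s in self.series:
            if (
                s.patient_id == patient_id
                and s.cycle_index == cycle
                and s.structure == structure
            ):
                return s
        raise KeyError(f"no series for {patient_id}/{cycle}/{structure}")

    def truth_for(
        self, patient_id: str, cycle: int, structure: str
    ) -> SyntheticTruth:
        for t in self.truths:
            if (
                t.patient_id == patient_id
                and t.cycle_index == cycle
                and t.structure == structure
            ):
                return t
        raise KeyError(f"no truth for {patient_id}/{cycle}/{structure}")


def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative lognormal factors with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate a cohort: per-structure dose-rate series plus ground truth.

    The returned courses carry the analytic (truth-level) absorbed doses and
    clearance half-lives in their cycle records; the noisy series are what
    the estimation pipeline should be run on.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_patients)
    times = np.asarray(config.sample_times_h, dtype=float)

    courses: list[PatientCourse] = []
    all_series: list[DoseRateSeries] = []
    truths: list[SyntheticTruth] = []

    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        pid = f"S{i + 1}"
        weight = rng.uniform(*config.weight_range_kg)
        sex = "F" if rng.random() < 0.5 else "M"
        gfr = rng.uniform(60.0, 150.0)
        tum_amp_per_aa = rng.uniform(*config.tumour_amp_per_aa_range)
        tum_teff = rng.uniform(*config.tumour_teff_range_h)
        kid_teff = rng.uniform(*config.kidney_teff_range_h)
        kid_amp_per_aa = {
            KIDNEY_LEFT: rng.uniform(*config.kidney_amp_per_aa_range),
            KIDNEY_RIGHT: rng.uniform(*config.kidney_amp_per_aa_range),
        }

        cycles: list[CycleDose] = []
        for cycle in range(1, config.n_cycles + 1):
            aa_gbq = config.aa_mbq_kg(cycle) * weight / 1000.0
            decline = config.uptake_decline_factor ** (cycle - 1)
            cycle_truths = [
                SyntheticTruth(
                    patient_id=pid,
                    cycle_index=cycle,
                    structure=TUMOUR,
                    amplitude_gy_per_h=tum_amp_per_aa * aa_gbq * decline,
                    uptake_halftime_h=config.uptake_halftime_h,
                    clearance_teff_h=tum_teff,
                    uptake_decline_factor=config.uptake_decline_factor,
                )
            ] + [
                SyntheticTruth(
                    patient_id=pid,
                    cycle_index=cycle,
                    structure=side,
                    amplitude_gy_per_h=kid_amp_per_aa[side] * aa_gbq,
                    uptake_halftime_h=config.uptake_halftime_h,
                    clearance_teff_h=kid_teff,
                    uptake_decline_factor=1.0,
                )
                for side in (KIDNEY_LEFT, KIDNEY_RIGHT)
            ]
            for truth in cycle_truths:
                clean = np.asarray(truth.rate(times), dtype=float)
                noisy = clean * _noise_factors(rng, config.noise_cv, times.size)
                all_series.append(
                    DoseRateSeries(
                        patient_id=pid,
                        cycle_index=cycle,
                        structure=truth.structure,
                        samples=tuple(
                            DoseRateSample(float(t), float(r))
                            for t, r in zip(times, noisy)
                        ),
                    )
                )
                truths.append(truth)

            tum_truth = cycle_truths[0]
            kid_ad = 0.5 * sum(t.true_ad_gy for t in cycle_truths[1:])
            cycles.append(
                CycleDose(
                    patient_id=pid,
                    cycle_index=cycle,
                    aa_gbq=aa_gbq,
                    weight_kg=weight,
                    tumour_ad_gy=tum_truth.true_ad_gy,
                    kidney_ad_gy=kid_ad,
                    tumour_teff_h=tum_teff,
                    kidney_teff_h=kid_teff,
                )
            )
        courses.append(PatientCourse(pid, sex, gfr, tuple(cycles)))

    return SyntheticCohort(tuple(courses), tuple(all_series), tuple(truths))
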