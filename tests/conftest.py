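import math

import pytest

from cyclodose import DoseRateSample, DoseRateSeries, ludo_fixture


@pytest.fixture(scope="session")
def cohort():
    """The packaged six-patient, four-cycle reference cohort."""
    return ludo_fixture()


@pytest.fixture(scope="session")
def by_patient(cohort):
    return {c.patient_id: c for c in cohort}


def make_series(times, rates, structure="tumour", patient_id="X", cycle=1):
    return DoseRateSeries(
        patient_id=patient_id,
        cycle_index=cycle,
        structure=structure,
        samples=tuple(DoseRateSample(t, r) for t, r in zip(times, rates)),
    )


def monoexp_series(t_eff_h, rate_at_24, times=(24.0, 48.0, 72.0), **kw):
    """Noiseless mono-exponential series anchored at the 24 h rate."""
    rates = [rate_at_24 * 2.0 ** (-(t - 24.0) / t_eff_h) for t in times]
    return make_series(times, rates, **kw)


def printed_tol(printed, decimals):
    """Tolerance vs a printed table value: max(1% relative, half an ulp)."""
    return max(0.01 * abs(printed), 0.5 * 10.0 ** (-decimals))


def assert_printed(computed, printed, decimals):
    tol = printed_tol(printed, decimals)
    assert math.isclose(computed, printed, abs_tol=tol), (
        f"computed {computed!r} vs printed {printed!r} (tol {tol:.4g})"
    )
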