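import numpy as np
import pytest

from seawas import (
    EffectSpec,
    MonthlyContingency,
    PatientRecord,
    PopulationSpec,
    generate_cohort,
)


@pytest.fixture
def toy_contingency() -> MonthlyContingency:
    """n_m = 100 everywhere, 20 cases in January, 10 in every other month.

    Hand arithmetic: RR_1 = (20/100)/(110/1100) = 2.0,
    RR_2 = (10/100)/(120/1100) = 11/12.
    """
    return MonthlyContingency((20,) + (10,) * 11, (100,) * 12)


@pytest.fixture
def uniform_contingency() -> MonthlyContingency:
    """Perfectly homogeneous: identical risk in every month."""
    return MonthlyContingency((10,) * 12, (100,) * 12)


def make_patient(pid, month, codes=(), year=1960, **demo) -> PatientRecord:
    return PatientRecord(
        patient_id=str(pid),
        birth_year=year,
        birth_month=month,
        demographics={k: str(v) for k, v in demo.items()},
        condition_codes=set(codes),
    )


@pytest.fixture(scope="session")
def small_effect_cohort():
    """20k patients with one moderate cosine effect plus nulls; session-scoped
    because several tests only need any realistic generated dataset."""
    pop = PopulationSpec(n_patients=20_000, seed=11)
    return generate_cohort(
        pop,
        [EffectSpec("CVD", 0.08, 0.3, peak_month_phi=2)],
        null_conditions=4,
        seed=11,
    )


def random_contingency(rng: np.random.Generator) -> MonthlyContingency:
    """A random small 2x12 table with at least one case and one non-case."""
    while True:
        n = rng.integers(20, 200, size=12)
        p = rng.uniform(0.05, 0.4)
        c = rng.binomial(n, p)
        if 0 < c.sum() < n.sum():
            return MonthlyContingency(tuple(int(x) for x in c), tuple(int(x) for x in n))
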