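import numpy as np
import pytest

from synthehr.records import Cohort, PatientRecord, Visit
from synthehr.simulate import DiseaseSpec, SimConfig, simulate_cohort


def small_catalog(n: int = 8) -> tuple:
    """A compact disease catalog for fast tests: prevalences 0.3 .. 0.004."""
    prevs = np.geomspace(0.3, 0.004, n)
    return tuple(
        DiseaseSpec(
            code=f"C{i:02d}",
            base_prevalence=float(prevs[i]),
            female_multiplier=[1.0, 1.3, 0.8][i % 3],
            onset_age_mean=40.0 + 5.0 * i,
            onset_age_sd=10.0,
            risk_weight=0.8 if i < 3 else 0.0,
        )
        for i in range(n)
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_patients=500, diseases=small_catalog(), seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config) -> Cohort:
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def midsize_cohort() -> Cohort:
    return simulate_cohort(SimConfig(n_patients=2000, diseases=small_catalog(), seed=7))


def record(rid, sex, visits, year=None) -> PatientRecord:
    """Shorthand: visits as [(age_or_ages, codes), ...]."""
    vs = []
    for age, codes in visits:
        if age is None:
            ages = ()
        elif isinstance(age, (tuple, list)):
            ages = tuple(float(a) for a in age)
        else:
            ages = (float(age),)
        vs.append(Visit(codes=frozenset(codes), ages=ages))
    return PatientRecord(id=rid, sex=sex, visits=tuple(vs), diagnosis_year=year)


def toy_cohort(records, vocab=("DM", "CKD", "HTN", "OBE", "DEP")) -> Cohort:
    return Cohort(records=tuple(records), vocabulary=tuple(vocab))
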