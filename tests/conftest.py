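import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import c14turnover as ct

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bomb_record():
    """Stylised bomb-pulse curve with defaults (1920–2025, lag 1 y)."""
    return ct.make_bomb_curve()


@pytest.fixture(scope="session")
def flat_record():
    """Constant atmosphere at 100 ‰ (piecewise-constant special case)."""
    return ct.AtmosphericRecord(
        years=np.array([1900.0, 1960.0, 2020.0]),
        values=np.array([100.0, 100.0, 100.0]),
        lag=1.0,
    )


@pytest.fixture(scope="session")
def step_record():
    """High level (800 ‰) up to 1949, dropping steeply to 100 ‰.

    A subject born 1950 starts at c̄(0) = 800 while the source it
    relaxes toward is 100, so the constant-rate solution has the
    closed form 100 + 700·e^{−βT} — the identifiable single-sample
    configuration used by the grid-oracle tests.
    """
    return ct.AtmosphericRecord(
        years=np.array([1900.0, 1949.0, 1949.01, 2030.0]),
        values=np.array([800.0, 800.0, 100.0, 100.0]),
        lag=1.0,
    )


@pytest.fixture(scope="session")
def subject_1950():
    return ct.SubjectSample(
        subject_id="S1",
        birth_year=1950.0,
        collection_year=2010.0,
        population="neuronal",
        delta14c_permil=0.0,
    )


@pytest.fixture(scope="session")
def cohort_2pop(bomb_record):
    """Default study-scale synthetic cohort (2POP truth)."""
    spec = ct.default_sim_spec(seed=11)
    samples, truth = ct.simulate_measurements(spec, bomb_record)
    return samples, truth
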