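import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from grsmr import load_packaged_instruments
from grsmr.pipeline import dichotomized_recovery
from grsmr.synth import SimConfig, simulate_cohort

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def instruments():
    return load_packaged_instruments()


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort reused by tests that only need realistic data."""
    return simulate_cohort(SimConfig(n_cases=150, n_controls=170, seed=11))


@pytest.fixture(scope="session")
def overall_recovery():
    """200 replicate re-estimates of a true dichotomized OR of 1.44
    at the full study arm sizes (821 cases / 851 controls)."""
    return dichotomized_recovery(true_or=1.44, n_replicates=200, seed=1)


@pytest.fixture(scope="session")
def subtype_recovery():
    """200 replicate re-estimates of a true dichotomized OR of 2.20 for a
    200-case subtype stratum against 851 shared controls."""
    return dichotomized_recovery(
        true_or=2.20, n_cases=200, n_controls=851, n_replicates=200,
        seed=1, subtype="GIST",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


def random_2x2(rng, max_total=40):
    """Random nondegenerate 2x2 counts with total <= max_total."""
    while True:
        cells = rng.integers(0, max_total // 2, size=4)
        if cells.sum() == 0 or cells.sum() > max_total:
            continue
        a, b, c, d = (int(x) for x in cells)
        if min(a + c, b + d, a + b, c + d) > 0:
            return a, b, c, d
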