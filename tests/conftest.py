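import numpy as np
import pytest

from metasurv.cohort_io import (ClinicalTable, Cohort, CohortCollection,
                                ExpressionMatrix)
from metasurv.synthetic_cohorts import default_config, simulate_collection


def make_cohort(name, values, times, events, genes=None, prefix=None):
    """Small in-memory cohort from a features x samples array."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    genes = genes or [f"g{i}" for i in range(p)]
    prefix = prefix or name
    samples = [f"{prefix}_s{i}" for i in range(n)]
    return Cohort(
        name,
        ExpressionMatrix(genes, samples, values),
        ClinicalTable(samples, np.asarray(times, float), np.asarray(events)),
    )


def random_cohort(rng, name="c", n=20, p=5, censor_frac=0.3, genes=None):
    values = rng.standard_normal((p, n))
    times = rng.exponential(1.0, n) + 1e-3
    events = (rng.random(n) > censor_frac).astype(int)
    if events.sum() == 0:
        events[0] = 1
    return make_cohort(name, values, times, events, genes=genes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_collection():
    """The default synthetic scenario, simulated once per session."""
    return simulate_collection(default_config())


@pytest.fixture(scope="session")
def small_collection():
    """A fast 2-cohort collection for optimizer-level tests."""
    rng = np.random.default_rng(7)
    cohorts = [random_cohort(rng, name=f"c{k}", n=25, p=6) for k in range(2)]
    return CohortCollection(cohorts)
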