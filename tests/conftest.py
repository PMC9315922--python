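import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mutspec.classify import default_tables
from mutspec.pipeline import build_cohort
from mutspec.simulate import SimConfig, fixture_small, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tables():
    return default_tables()


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 12-patient hand-checkable cohort."""
    return fixture_small()


@pytest.fixture(scope="session")
def fixture_table(fixture_cohort):
    """Pipeline-computed cohort table for the hand fixture."""
    return build_cohort(
        fixture_cohort.patient_records,
        fixture_cohort.germline_records,
        fixture_cohort.clinical,
    )


@pytest.fixture(scope="session")
def sim300():
    """A small simulated cohort shared across tests (seed fixed)."""
    return simulate_cohort(SimConfig(n_patients=300, seed=42))


def random_prealigned_pair(rng: np.random.Generator, length: int = 120):
    """A random equal-length gapped pair for property tests."""
    bases = np.array(list("ACGT"))
    germ = rng.choice(bases, size=length)
    patient = germ.copy()
    n_mut = int(rng.integers(0, 12))
    pos = rng.choice(length, size=n_mut, replace=False)
    for p in pos:
        alts = [b for b in "ACGT" if b != germ[p]]
        patient[p] = alts[int(rng.integers(3))]
    # sprinkle Ns and a shared gap column
    for p in rng.choice(length, size=3, replace=False):
        patient[p] = "N"
    g = list(map(str, germ))
    q = list(map(str, patient))
    gap_at = int(rng.integers(length))
    g.insert(gap_at, ".")
    q.insert(gap_at, ".")
    return "".join(q), "".join(g)
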