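import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sigensemble import (
    ActivityMatrix,
    CohortSpec,
    MutationalCatalog,
    SignatureSet,
    simulate_cohort,
)
from sigensemble.channels import CANONICAL_LABELS

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def block_signatures() -> SignatureSet:
    """Three orthogonal toy signatures, each uniform over 32 channels."""
    W = np.zeros((96, 3))
    for k in range(3):
        W[32 * k : 32 * (k + 1), k] = 1.0 / 32.0
    df = pd.DataFrame(W, index=list(CANONICAL_LABELS), columns=["SIG_A", "SIG_B", "SIG_C"])
    return SignatureSet(df)


def catalog_from_mixture(
    signatures: SignatureSet, proportions, burden: int, sample_id: str = "S1"
) -> MutationalCatalog:
    """Noise-free integer catalog column for an exact mixture (test helper).

    Callers must pick burden/proportions so burden * W h is integral.
    """
    h = np.asarray(proportions, dtype=float)
    v = burden * (signatures.matrix @ h)
    assert np.allclose(v, np.round(v)), "choose an integral mixture"
    df = pd.DataFrame({sample_id: np.round(v).astype(int)}, index=list(CANONICAL_LABELS))
    return MutationalCatalog(df)


@pytest.fixture(scope="session")
def small_truth():
    """A 20-sample spiky cohort with fixed burden, shared across tests."""
    return simulate_cohort(
        CohortSpec(n_samples=20, prevalence=0.5, burden_range=(5000, 5000)),
        k=6,
        seed=3,
    )


def random_activity_matrix(rng: np.random.Generator, k: int = 4, n: int = 5) -> ActivityMatrix:
    props = rng.dirichlet(np.ones(k + 1), size=n).T  # includes Unassigned mass
    df = pd.DataFrame(
        props,
        index=[f"SBS{i + 1}" for i in range(k)] + ["Unassigned"],
        columns=[f"S{j + 1}" for j in range(n)],
    )
    burdens = rng.integers(1000, 9000, size=n)
    return ActivityMatrix.from_proportions(df, burdens)
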