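import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radphylo.genotypes import GenotypeMatrix
from radphylo.synthetic import make_ribes_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_bundle():
    """Reduced canonical fixture shared across tests (52 samples, 1500 loci)."""
    return make_ribes_fixture(seed=1, n_loci=1500)


@pytest.fixture
def small_genotypes():
    """4 samples x 5 loci with one missing entry."""
    dosages = np.array(
        [
            [0, 1, 2, 0, 1],
            [0, 1, 1, 2, 0],
            [2, 0, 1, -1, 1],
            [1, 2, 0, 0, 2],
        ]
    )
    return GenotypeMatrix(
        ["s1", "s2", "s3", "s4"], [f"L{i}" for i in range(1, 6)], dosages
    )


def random_genotypes(rng, n_samples, n_loci, missing_rate=0.0):
    dosages = rng.integers(0, 3, size=(n_samples, n_loci))
    if missing_rate:
        dosages = np.where(rng.random(dosages.shape) < missing_rate, -1, dosages)
    return GenotypeMatrix(
        [f"s{i}" for i in range(n_samples)],
        [f"L{j}" for j in range(n_loci)],
        dosages,
    )
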