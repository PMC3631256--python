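import numpy as np
import pytest

from virodisorder.simulate import FamilyTruth, default_config, simulate_corpus


def scaled_config(n_genomes: int) -> list[FamilyTruth]:
    """The default family configuration with per-family counts reduced."""
    return [
        FamilyTruth(**{**f.__dict__, "n_genomes": n_genomes}) for f in default_config()
    ]


@pytest.fixture(scope="session")
def small_corpus():
    """A reduced corpus (8 genomes/family) shared across integration tests."""
    return simulate_corpus(scaled_config(8), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
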