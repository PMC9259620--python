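import numpy as np
import pytest

from chromcompare.genome import GenomeAssembly
from chromcompare.pipeline import analyze, inputs_from_dataset
from chromcompare.simulate import simulate, small_config


@pytest.fixture(scope="session")
def small_ds():
    """Reduced two-genome dataset with planted truth (noise-free)."""
    return simulate(small_config(), seed=11)


@pytest.fixture(scope="session")
def small_results(small_ds):
    return analyze(inputs_from_dataset(small_ds))


@pytest.fixture
def assembly():
    return GenomeAssembly("toy", {"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture
def rng():
    return np.random.default_rng(42)
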