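import pytest
from hypothesis import settings

from tdt2g.fixtures import worked_example_dataset
from tdt2g.simulate import coalescent_pool

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def worked_example():
    """The published two-marker training/test pair (84 trios each)."""
    return worked_example_dataset()


@pytest.fixture(scope="session")
def pool():
    """One coalescent haplotype pool shared by the pool-based studies."""
    return coalescent_pool(seed=7)
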