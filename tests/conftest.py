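import pytest

from infodemic import ModelParams

# Fixed seed used throughout the suite: the date the fake-news video was
# first uploaded, also the package's default base seed.
BASE_SEED = 20190903


@pytest.fixture
def small_params() -> ModelParams:
    """A small, fast outbreak for unit tests (supercritical, N=500)."""
    return ModelParams(n=500, beta=0.2, gamma=0.1, contacts=1.0, i0=5, max_days=300)
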