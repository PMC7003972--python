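import pytest

from fiberscint.config import default_spectrum, reference_detector
from fiberscint.transport import McConfig, run_pencil_beam


@pytest.fixture(scope="session")
def detector():
    return reference_detector()


@pytest.fixture(scope="session")
def spectrum():
    return default_spectrum()


@pytest.fixture(scope="session")
def small_run(detector):
    """A modest pencil-beam run shared across tests (fixed seed)."""
    return run_pencil_beam(McConfig(n_histories=5000, seed=11), detector)
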