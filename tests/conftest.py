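import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glymph.cohort import CohortSpec
from glymph.phantom import PhantomSpec

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_spec() -> CohortSpec:
    """The shipped study-default cohort generator (27 CN + 56 AD)."""
    return CohortSpec.study_defaults()


@pytest.fixture(scope="session")
def small_phantom_spec() -> PhantomSpec:
    """A reduced grid for Monte-Carlo phantom tests (same zone structure)."""
    return PhantomSpec(shape=(24, 24, 8), snr=None)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240529)


def random_spd_tensor(rng: np.random.Generator) -> np.ndarray:
    """A random symmetric positive-definite tensor with tissue-like scale."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    eigs = rng.uniform(0.2e-3, 2.2e-3, size=3)
    return (q * eigs) @ q.T
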