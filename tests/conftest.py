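import numpy as np
import pytest

from smas.phantom import generate_cohort
from smas.pipeline import RunConfig, run_study


@pytest.fixture(scope="session")
def default_study():
    """The full phantom study at study-scale conditions (19 controls,
    16 glaucoma eyes, 256x256, seeded).  Shared across acceptance tests."""
    eyes = generate_cohort(seed=7)
    result = run_study(eyes, RunConfig())
    return eyes, result


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for pipeline unit tests."""
    return generate_cohort(n_controls=6, n_glaucoma=2, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
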