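import numpy as np
import pytest

import turbt_complexity as tc


@pytest.fixture(scope="session")
def catalog():
    return tc.load_default_catalog()


@pytest.fixture(scope="session")
def published_model():
    return tc.load_published_model()


@pytest.fixture(scope="session")
def published_checklist():
    return tc.load_published_checklist()


@pytest.fixture
def rng():
    return np.random.default_rng(20201020)


@pytest.fixture(scope="session")
def default_run():
    """One full synthetic study at the default configuration, shared
    across tests that only read its artifacts."""
    return tc.run_pipeline(tc.PipelineConfig(seed=0))
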