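import numpy as np
import pytest
from hypothesis import settings

import plasmut as pm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

PANEL_SEED = 11


@pytest.fixture(scope="session")
def references():
    return {r.amplicon_id: r for r in pm.default_references()}


@pytest.fixture(scope="session")
def default_panel():
    """A 48-sample simulated normal panel under the default error landscape."""
    return pm.simulate_normal_panel(pm.default_panel_spec(seed=PANEL_SEED))


@pytest.fixture(scope="session")
def fitted_detector(default_panel):
    """Per-type error models fitted from the default panel."""
    return pm.RareVariantDetector().fit(default_panel)


@pytest.fixture(scope="session")
def fitted_models(fitted_detector):
    return fitted_detector.models_


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
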