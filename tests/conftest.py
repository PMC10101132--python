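import numpy as np
import pytest

from pklss import build_cohort, load_model, sample_population
from pklss.report import default_model_path, make_toy_fixture


@pytest.fixture(scope="session")
def bax_model():
    return load_model(default_model_path("bax855"))


@pytest.fixture(scope="session")
def shl_model():
    return load_model(default_model_path("shl"))


@pytest.fixture(scope="session")
def toy():
    """Deterministic toy model + 5 patients with printed round parameters."""
    return make_toy_fixture(seed=0)


@pytest.fixture(scope="session")
def small_cohort(bax_model):
    """200 virtual patients on 50 IU/kg q72h BAX 855 prophylaxis."""
    demog = sample_population(200, seed=101)
    return build_cohort(bax_model, demog, iu_per_kg=50.0, seed=102)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
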