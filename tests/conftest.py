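import pytest
from hypothesis import HealthCheck, settings

import pathmeta as pm

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    """The built-in metabolic model (78 compounds, 13 pathways)."""
    return pm.builtin_toy_model()


@pytest.fixture(scope="session")
def small_model():
    """The bundled 12-compound / 3-pathway JSON fixture."""
    return pm.load_model(pm.toy_model_path())


@pytest.fixture()
def spiked_pair(model):
    """Two synthetic studies sharing one enriched pathway (P3)."""
    truth = pm.SyntheticTruth(enriched_pathway_ids={"P3"})
    return pm.generate_meta_set(model, truth, n_studies=2, base_seed=11), truth
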