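import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_ontology():
    """Four-class toy ontology (PC, PE, PS, TG) over six fatty acids."""
    from lipidont.simulate import make_toy_ontology

    return make_toy_ontology(n_classes=4)


@pytest.fixture(scope="session")
def full_ontology():
    """The full default build, biophysical category terms included."""
    from lipidont.defaults import build_default_ontology

    return build_default_ontology(include_biophysics=True)
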