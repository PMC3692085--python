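import pytest
from hypothesis import HealthCheck, settings

from pentashape import build_query_table
from pentashape.synthetic import make_model, make_corpus

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def model():
    """A deterministic noise-free ground-truth pentamer model."""
    return make_model(11)


@pytest.fixture(scope="session")
def corpus(model):
    """A small synthetic corpus with full 512-class coverage."""
    return make_corpus(model, n_fragments=250, length_range=(12, 27), trim=2)


@pytest.fixture(scope="session")
def table(corpus):
    """Complete query table mined from the small corpus."""
    return build_query_table(corpus, trim=2)
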