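import pytest
from hypothesis import HealthCheck, settings

from crfner.crf_core import CRFConfig
from crfner.synthetic_corpus import SynthConfig, generate_corpus
from crfner import ner_models

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_corpus():
    """60 generated documents used across module tests."""
    return generate_corpus(SynthConfig(n_docs=60, seed=7))


@pytest.fixture(scope="session")
def small_bundle(small_corpus):
    """Models (i)-(iii) trained once on the first 50 small-corpus documents."""
    train = small_corpus[:50]
    cfg = CRFConfig(max_iterations=80)
    return ner_models.TaggerBundle(
        chem_model=ner_models.train_span_model(train, "CHEMICAL", cfg),
        gene_model=ner_models.train_span_model(train, "GENE", cfg),
        type_model=ner_models.train_type_model(train, cfg),
    )
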