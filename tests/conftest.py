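import pytest

from ontonet.pipeline import run_pipeline
from ontonet.schema import build_default_network
from ontonet.synth import CorpusProfile, generate_corpus


@pytest.fixture(scope="session")
def default_network():
    return build_default_network()


@pytest.fixture(scope="session")
def pipeline_result():
    """One full end-to-end run shared by the read-only tests."""
    return run_pipeline(seed=7)


def small_profile(seed: int = 0) -> CorpusProfile:
    """A scaled-down corpus profile for fast tests."""
    return CorpusProfile(
        n_patients=10,
        n_male=5,
        n_female=5,
        diagnosis_quota={
            "Diabetes Mellitus Tipo 1": 9,
            "Diabetes Mellitus Tipo 2": 9,
            "other": 30,
        },
        prescription_quota={
            "Insulina Glargina": 8,
            "Metformina": 4,
            "Diosmina con Hesperidina": 3,
            "other": 45,
        },
        seed=seed,
    )


@pytest.fixture()
def small_corpus():
    return generate_corpus(small_profile(), seed=3)
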