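import pytest
from hypothesis import HealthCheck, settings

import lflink as L
from lflink.synthetic import SyntheticConfig, generate_corpus

settings.register_profile(
    "lflink",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("lflink")


@pytest.fixture(scope="session")
def mixed_corpus():
    """Moderate corpus with every variant stratum represented."""
    return generate_corpus(SyntheticConfig(n_concepts=800, seed=42))


@pytest.fixture(scope="session")
def mixed_index(mixed_corpus):
    return L.build_title_index(mixed_corpus.titles, lexicon=mixed_corpus.lexicon, n=2)
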