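import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_protein() -> str:
    from xlassist.examples_support import TOY_PROTEIN

    return TOY_PROTEIN


@pytest.fixture(scope="session")
def toy_candidates(toy_protein):
    """Digest + full candidate space of the toy protein (session-cached)."""
    from xlassist import xlsearch

    settings_ = xlsearch.SearchSettings()
    peptides = xlsearch.digest(toy_protein, settings_, protein_id="toy")
    return xlsearch.enumerate_candidates(
        peptides, settings=settings_, protein_lengths={"toy": len(toy_protein)}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
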