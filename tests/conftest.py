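import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_gene_transcriptome():
    """Two sequence-disjoint single-isoform genes plus their t2g map."""
    rng = np.random.default_rng(123)
    records = [
        ("gA_t0", random_seq(rng, 200)),
        ("gB_t0", random_seq(rng, 200)),
    ]
    t2g = {"gA_t0": "gA", "gB_t0": "gB"}
    return records, t2g
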