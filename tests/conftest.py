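import numpy as np
import pytest

from tenascope.records import ProteinRecord
from tenascope.synthetic_data import GeneratorConfig, GenomeConfig

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_protein(rng, n, pid="p", alphabet=AA20):
    return ProteinRecord(id=pid, seq="".join(
        alphabet[i] for i in rng.integers(0, len(alphabet), n)))


@pytest.fixture
def small_config():
    """Compact generator settings for fast unit tests."""
    return GeneratorConfig(
        seed=11,
        egf_counts={"TNC": 3, "TNR": 4, "TNW": 4, "TNX": 3},
        fn3_counts={"TNC": 4, "TNR": 9, "TNW": 5, "TNX": 5},
        genome=GenomeConfig())
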