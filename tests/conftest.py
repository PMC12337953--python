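import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from idpome.io import Proteome, ProteinRecord
from idpome.synthetic import generate_reference_sets

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_sets():
    """The shipped ordered/disordered calibration proteomes (200 + 200)."""
    return generate_reference_sets()


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">P1\nMKVMKVMKV\n>P2\nEEEKKKEEE\n>sp|Q9|NAME_HUMAN\nACDEFGHIKLMNP\n")
    return path


@pytest.fixture
def toy_proteome():
    return Proteome(
        "toy",
        [
            ProteinRecord("A", "MKVLIVFA" * 10),
            ProteinRecord("B", "PESKQGDE" * 10),
            ProteinRecord("C", "RGYSRGSQ" * 10),
        ],
    )
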