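import numpy as np
import pytest

from comscan.config import ThresholdConfig
from comscan.features import WW_INTERFACE
from comscan.io import ProteinRecord


@pytest.fixture(scope="session")
def config():
    return ThresholdConfig()


@pytest.fixture(scope="session")
def scale():
    return WW_INTERFACE


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def make_fasta(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text, name="input.fa"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def record(seq, rid="rec"):
    return ProteinRecord(id=rid, sequence=seq)


@pytest.fixture(scope="session")
def toy_scale():
    """A/G two-level scale for arithmetic-by-inspection tests."""
    from comscan.features import ResidueScale, AMINO_ACIDS

    values = {aa: 0.0 for aa in AMINO_ACIDS}
    values["A"] = 1.0
    return ResidueScale("toy", values)
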