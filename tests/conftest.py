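import numpy as np
import pytest

from idpkit.sequence import ProteinSequence


@pytest.fixture
def q_grid():
    """Dense low-noise q grid (Å^-1) used by the SAXS oracles."""
    return np.linspace(0.004, 0.4, 500)


@pytest.fixture
def hv_like():
    """Table-1-style printed charged fractions (f+, f-) of HvASR1."""
    return 0.136, 0.201


def make_seq(residues: str, seq_id: str = "test") -> ProteinSequence:
    return ProteinSequence(seq_id, residues)
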