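import numpy as np
import pytest

from nucbubble.geometry import MoleculeTrace, StrandTrace


def straight_molecule(
    sep_px: float = 5.0,
    length_px: float = 461.0,
    n_points: int = 462,
    template_len_bp: int = 461,
    molecule_id: str = "m0",
) -> MoleculeTrace:
    """Two parallel horizontal strands sep_px apart, co-oriented."""
    x = np.linspace(0.0, length_px, n_points)
    a = np.column_stack([x, np.full_like(x, sep_px / 2.0)])
    b = np.column_stack([x, np.full_like(x, -sep_px / 2.0)])
    return MoleculeTrace(molecule_id, StrandTrace("A", a), StrandTrace("B", b), template_len_bp)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def parallel_molecule():
    return straight_molecule()
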