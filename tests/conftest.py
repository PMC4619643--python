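import numpy as np
import pytest

from eccbarcodes.ldpc_design import generator_from_parity, select_best


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ldpc_19_4():
    """Best-of-1000 D-selected (19, 4) quaternary LDPC code, j = 3.

    Session-scoped: the same selected code backs the decoder sweeps, the
    channel benchmark and the monotonicity scan.
    """
    rng = np.random.default_rng(20151022)
    H = select_best(19, 15, pool_size=1000, rng=rng)
    return generator_from_parity(H)


@pytest.fixture(scope="session")
def ldpc_12_3():
    """A small (12, 3) code (m = 9, j = 3): 64 codewords, exhaustively checkable."""
    rng = np.random.default_rng(7)
    H = select_best(12, 9, pool_size=50, rng=rng)
    return generator_from_parity(H)
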