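import numpy as np
import pytest

from connfp.io_core import FCMatrix, TimeSeriesMatrix, devectorize


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_fc(rng):
    """A random 10-node symmetric zero-diagonal FC matrix."""
    n = 10
    vals = rng.standard_normal(n * (n - 1) // 2)
    return devectorize(vals, method_tag="pearson_sfc")


@pytest.fixture
def white_ts(rng):
    """200 x 5 white-noise run at TR 0.72 s."""
    return TimeSeriesMatrix(
        values=rng.standard_normal((200, 5)),
        tr_seconds=0.72,
        node_ids=[f"n{k}" for k in range(5)],
    )
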