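import numpy as np
import pytest

from emtpath.cellgraph import CellMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cell_map(rng, n, size=200.0, types=("T", "I", "S")):
    return CellMap(
        rng.uniform(0, size, n),
        rng.uniform(0, size, n),
        rng.choice(types, n).astype(object),
        patch_size_px=int(size),
    )
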