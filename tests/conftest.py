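import numpy as np
import pandas as pd
import pytest

from histoarch.core import CellMap


def make_cellmap(coords, types, sample_id="S1", area=None, group="SB",
                 donor_id="D1", region="r1"):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    cells = pd.DataFrame({
        "cell_id": [f"{sample_id}-{i:06d}" for i in range(n)],
        "x": coords[:, 0],
        "y": coords[:, 1],
        "cell_type": np.asarray(types, dtype=object),
        "sample_id": sample_id,
        "donor_id": donor_id,
        "region": region,
        "group": group,
    })
    if area is None:
        span_x = coords[:, 0].max() - coords[:, 0].min() or 1.0
        span_y = coords[:, 1].max() - coords[:, 1].min() or 1.0
        area = span_x * span_y
    return CellMap(cells=cells, area=area)


def random_cellmap(n=150, n_types=4, seed=0, width=100.0, sample_id="S1",
                   group="SB"):
    """Uniform random positions with i.i.d. (CSR) type labels."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, width, size=(n, 2))
    types = rng.choice([f"t{i}" for i in range(n_types)], size=n)
    return make_cellmap(coords, types, sample_id=sample_id,
                        area=width * width, group=group)


@pytest.fixture
def toy_map():
    """8 cells, two types, hand-placed."""
    coords = [(0, 0), (1, 0), (0, 1), (1, 1), (10, 10), (11, 10), (10, 11), (11, 11)]
    types = ["A", "A", "A", "B", "B", "B", "A", "B"]
    return make_cellmap(coords, types, area=121.0)
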