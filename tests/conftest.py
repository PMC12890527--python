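import numpy as np
import pandas as pd
import pytest

from spatialcoloc import CellMap


def make_cells(coords, types, sample_ids=None, lineage=None):
    """Build a CellMap from parallel arrays (test helper)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    table = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "sample_id": sample_ids if sample_ids is not None
            else ["s0"] * n,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "cell_type": types,
        }
    )
    if lineage is not None:
        table["lineage"] = lineage
    return CellMap(table)


@pytest.fixture
def collinear_cells():
    """Three collinear cells at x = 0, 10, 25."""
    return make_cells([[0, 0], [10, 0], [25, 0]], ["A", "A", "A"])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_cells(rng, n=50, types=("A", "B"), extent=100.0, n_samples=1):
    coords = rng.uniform(0, extent, size=(n, 2))
    labels = rng.choice(types, size=n)
    samples = [f"s{i % n_samples}" for i in range(n)]
    return make_cells(coords, labels, sample_ids=samples)
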