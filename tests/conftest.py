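import numpy as np
import pytest

from ctsr import ExpressionMatrix, CellLabeling


@pytest.fixture
def tiny_em():
    """3 genes x 4 cells with distinct values per cell."""
    values = np.array([
        [5.0, 0.0, 2.0, 1.0],
        [9.0, 3.0, 0.0, 4.0],
        [0.0, 7.0, 6.0, 2.0],
    ])
    return ExpressionMatrix(values, ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"],
                            normalized=True, log_transformed=True)


@pytest.fixture
def two_type_labels():
    return CellLabeling(["c1", "c2", "c3", "c4"], ["A", "A", "B", "B"])


def random_labeling(rng, cell_ids, n_types):
    labs = [f"T{rng.integers(1, n_types + 1)}" for _ in cell_ids]
    # guarantee every type appears
    for t in range(n_types):
        labs[t] = f"T{t + 1}"
    return CellLabeling(list(cell_ids), labs)
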