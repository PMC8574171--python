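import numpy as np
import pytest

from equiphen import CellAnnotation, CountMatrix


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """4 genes x 6 cells, two groups of 3, hand-checkable values."""
    values = np.array(
        [
            [10.0, 10.0, 12.0, 9.0, 11.0, 10.0],  # stable, balanced
            [5.0, 20.0, 35.0, 4.0, 18.0, 40.0],  # noisy, balanced
            [30.0, 28.0, 32.0, 0.0, 0.0, 0.0],  # group-A only
            [0.0, 0.0, 2.0, 0.0, 0.0, 3.0],  # rare
        ]
    )
    return CountMatrix(
        values,
        gene_ids=["StableA", "NoisyB", "OnlyA", "RareD"],
        cell_ids=[f"c{i}" for i in range(6)],
    )


@pytest.fixture
def tiny_ann(tiny_matrix) -> CellAnnotation:
    return CellAnnotation.from_labels(
        tiny_matrix.cell_ids, ["A", "A", "A", "B", "B", "B"]
    )


@pytest.fixture(scope="session")
def paperlike():
    """One default-condition simulation shared across tests (seed 1)."""
    from equiphen import default_paperlike_config, simulate

    return simulate(default_paperlike_config(seed=1))
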