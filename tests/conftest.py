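import numpy as np
import pytest

import spotalign as sa


@pytest.fixture
def toy_expr():
    """3 genes × 2 cells raw counts."""
    return sa.ExpressionMatrix(
        np.array([[1.0, 0.0], [2.0, 3.0], [0.0, 4.0]]),
        ["gA", "gB", "gC"],
        ["c1", "c2"],
        layer="raw",
    )


@pytest.fixture
def small_tissue():
    """A compact blocks-layout simulated tissue shared across tests."""
    return sa.simulate_tissue(
        n_types=4,
        n_genes=200,
        cells_per_type=30,
        layout="blocks",
        target_mean_cells_per_spot=5,
        seed=11,
    )


def random_expression(rng, n_genes, n_cols, prefix="x"):
    """Random nonnegative count-like matrix used for solver fuzzing."""
    vals = rng.poisson(rng.gamma(2.0, 2.0, size=(n_genes, n_cols))).astype(float)
    return sa.ExpressionMatrix(
        vals,
        [f"g{i}" for i in range(n_genes)],
        [f"{prefix}{j}" for j in range(n_cols)],
        layer="raw",
    )
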