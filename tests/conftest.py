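import numpy as np
import pytest

from scdisentangle import (
    ExpressionDataset,
    Stage,
    config_for,
    easy_benchmark,
    fit,
    preprocess,
)


@pytest.fixture(scope="session")
def easy_data():
    """Small benchmark dataset with ground truth, shared across tests."""
    return easy_benchmark(seed=1)


@pytest.fixture(scope="session")
def easy_staged(easy_data):
    ds, _ = easy_data
    return preprocess(ds)


@pytest.fixture(scope="session")
def trained_state(easy_staged):
    """One full training run on the easy benchmark, reused by every test
    that needs a fitted model (training dominates suite runtime)."""
    cfg = config_for(easy_staged, seed=1)
    return fit(easy_staged, cfg)


@pytest.fixture
def tiny_raw():
    """5 cells x 300 genes of small counts; every cell expresses >=200 genes."""
    rng = np.random.default_rng(42)
    X = rng.poisson(2.0, size=(5, 300)).astype(float)
    X[X == 0] = 1.0  # all genes expressed everywhere...
    X[:, 7] = 0.0  # ...except one silent gene column
    return ExpressionDataset(
        matrix=X,
        gene_ids=[f"g{i}" for i in range(300)],
        cell_ids=[f"c{i}" for i in range(5)],
        batch=np.array(["b1", "b1", "b2", "b2", "b2"]),
        condition=np.array(["x", "y", "x", "y", "x"]),
        cell_type=np.array(["t1", "t1", "t2", "t2", "t1"]),
        stage=Stage.raw,
    )
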