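import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dopanet.io_model import Edge, ExpressionExperiment, Interactome

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def tiny_graph():
    """A→X, X→A (directed) plus A–Y (undirected)."""
    return Interactome(
        nodes={"A", "X", "Y"},
        edges=[
            Edge("A", "X", "controls-expression-of", True),
            Edge("X", "A", "controls-expression-of", True),
            Edge("A", "Y", "interacts-with", False),
        ],
    )


@pytest.fixture
def two_group_experiment():
    """6 genes × 8 samples, two groups of four, reproducible."""
    rng = np.random.default_rng(123)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(8)]
    values = pd.DataFrame(
        8 + rng.standard_normal((6, 8)), index=genes, columns=samples
    )
    groups = pd.Series(["a"] * 4 + ["b"] * 4, index=samples)
    return ExpressionExperiment(values, groups)
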