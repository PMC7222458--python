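import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import instdiffs as idf

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def chain_spec():
    """A -> B -> C chain with standardized paths 0.7, 0.7."""
    return idf.SyntheticSpec(
        nodes=[("A", 1), ("B", 2), ("C", 3)],
        edges=[("A", "B", 0.7), ("B", "C", 0.7)],
        n_units=5000,
        seed=31,
    )


@pytest.fixture
def six_node_dag():
    """Sparse 6-node DAG with strong paths, plus its registry."""
    nodes = [(f"v{i}", i * 10) for i in range(1, 7)]
    edges = [
        ("v1", "v2", 0.7),
        ("v2", "v4", 0.6),
        ("v3", "v5", 0.8),
        ("v4", "v6", 0.65),
    ]
    spec = idf.SyntheticSpec(nodes=nodes, edges=edges, n_units=200, seed=42)
    registry = [
        idf.MeasureDefinition(name=n, group="institutional history", causal_rank=r)
        for n, r in nodes
    ]
    return spec, registry


def make_registry(names, ranks=None):
    ranks = ranks or list(range(1, len(names) + 1))
    return [
        idf.MeasureDefinition(name=n, group="institutional history", causal_rank=r)
        for n, r in zip(names, ranks)
    ]


@pytest.fixture
def noise_matrix():
    def _make(n_units, n_measures, seed):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(
            rng.standard_normal((n_units, n_measures)),
            index=[f"u{i:02d}" for i in range(n_units)],
            columns=[f"m{i:02d}" for i in range(n_measures)],
        )
        return idf.SchoolMeasureMatrix(values)

    return _make
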