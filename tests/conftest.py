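import networkx as nx
import numpy as np
import pandas as pd
import pytest

from proxirep.interactome import InteractomeGraph
from proxirep.signatures import CASE, CONTROL, ExpressionDataset


@pytest.fixture
def path_graph():
    """A-B-C-D-E chain."""
    g = nx.path_graph(5)
    g = nx.relabel_nodes(g, dict(zip(range(5), "ABCDE")))
    return InteractomeGraph(g)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_graph(edges) -> InteractomeGraph:
    g = nx.Graph()
    g.add_edges_from(edges)
    return InteractomeGraph(g)


def make_expression(values: dict, case_samples: list[str],
                    batch: dict | None = None) -> ExpressionDataset:
    """values: gene -> list of per-sample expression; samples named s0, s1..."""
    df = pd.DataFrame.from_dict(values, orient="index")
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    classes = pd.Series(
        [CASE if c in case_samples else CONTROL for c in df.columns],
        index=df.columns)
    b = pd.Series(batch).reindex(df.columns) if batch else None
    return ExpressionDataset(df, classes, b)
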