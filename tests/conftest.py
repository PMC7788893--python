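import numpy as np
import pandas as pd
import pytest

from ctsnet import (
    CellAnnotation,
    CellTypeNetwork,
    ExpressionMatrix,
    GeneNetwork,
    MeanExpressionTable,
)


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    # 3 genes x 4 cells, hand-checkable counts
    values = np.array(
        [
            [2.0, 0.0, 4.0, 1.0],
            [3.0, 5.0, 0.0, 2.0],
            [5.0, 5.0, 6.0, 7.0],
        ]
    )
    return ExpressionMatrix(["gA", "gB", "gC"], ["c1", "c2", "c3", "c4"], values)


@pytest.fixture
def small_ann() -> CellAnnotation:
    return CellAnnotation({"c1": "A", "c2": "A", "c3": "B", "c4": "B"})


def make_network(edges) -> GeneNetwork:
    rows = []
    for u, v, w in edges:
        if u > v:
            u, v = v, u
        rows.append((u, v, float(w)))
    df = (
        pd.DataFrame(rows, columns=["gene1", "gene2", "weight"])
        .sort_values(["gene1", "gene2"])
        .reset_index(drop=True)
    )
    return GeneNetwork(df)


def make_ctn(edges, cell_type="X", vertices=None) -> CellTypeNetwork:
    net = make_network(edges)
    if vertices is not None:
        net = GeneNetwork(net.edges, vertices=frozenset(vertices))
    return CellTypeNetwork(net, cell_type, threshold=float("-inf"))


@pytest.fixture
def mean_table() -> MeanExpressionTable:
    means = np.array(
        [
            [10.0, 5.0, 2.0],
            [7.0, 7.0, 7.0],
            [4.0, 0.0, 1.0],
        ]
    )
    return MeanExpressionTable(
        ["gA", "gB", "gC"], ["c1", "c2", "c3"], means, np.array([2, 2, 2])
    )
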