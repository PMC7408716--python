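import pandas as pd
import pytest

import sigcircuits as sc


def make_graph(edges, nodes=None, pathway_id="pw", genes=None,
               flags=None, sign_aliases=None):
    """Build a PathwayGraph from a terse edge list.

    ``edges``: iterable of (source, target, sign); ``nodes`` defaults to the
    union of edge endpoints; ``genes`` maps node -> ";"-joined gene string
    (default: one gene "g<node>" per node); ``flags`` maps node ->
    (receptor, effector) 0/1 pair.
    """
    if nodes is None:
        nodes = sorted({n for e in edges for n in e[:2]})
    genes = genes or {}
    flags = flags or {}
    node_df = pd.DataFrame({
        "node_id": nodes,
        "genes": [genes.get(n, f"g{n}") for n in nodes],
        "label": nodes,
        "receptor": [flags.get(n, (0, 0))[0] for n in nodes],
        "effector": [flags.get(n, (0, 0))[1] for n in nodes],
    })
    edge_df = pd.DataFrame(edges, columns=["source", "target", "sign"])
    return sc.load_pathway(node_df, edge_df, pathway_id=pathway_id,
                           sign_aliases=sign_aliases)


@pytest.fixture
def chain_graph():
    """R -> M -> E, all activation."""
    return make_graph([("R", "M", "activation"), ("M", "E", "activation")])


@pytest.fixture
def diamond_graph():
    """R -> A -> E and R -> B -> E, all activation."""
    return make_graph([("R", "A", "activation"), ("R", "B", "activation"),
                       ("A", "E", "activation"), ("B", "E", "activation")])


def unit_matrix(values, samples=None):
    """GeneExpressionMatrix on the unit scale from {gene: row} dict."""
    df = pd.DataFrame(values).T
    if samples is not None:
        df.columns = samples
    else:
        df.columns = [f"s{i}" for i in range(df.shape[1])]
    return sc.GeneExpressionMatrix(df.astype(float), scale="unit")
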