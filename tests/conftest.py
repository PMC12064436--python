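import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mixedfci.data import MixedDataset, VariableMeta
from mixedfci.graphs import GroundTruthGraph


def make_graph(nodes, edges, outcome=None, latents=(), node_types=None):
    """Build a valid GroundTruthGraph from an edge list; tiers follow a
    topological order and the outcome defaults to the last observed sink."""
    roles = {n: ("latent" if n in latents else "observed") for n in nodes}
    g = nx.DiGraph(edges)
    g.add_nodes_from(nodes)
    tiers = {n: i for i, n in enumerate(nx.lexicographical_topological_sort(g))}
    if outcome is None:
        sinks = [n for n in nodes if roles[n] == "observed" and g.out_degree(n) == 0]
        outcome = sorted(sinks)[-1]
    return GroundTruthGraph(
        nodes=list(nodes),
        roles=roles,
        edges=list(edges),
        tiers=tiers,
        outcome=outcome,
        node_types=node_types or {n: 0 for n in nodes},
    )


def gaussian_dataset(columns: dict[str, np.ndarray]) -> MixedDataset:
    df = pd.DataFrame(columns)
    return MixedDataset(df, [VariableMeta(c) for c in df.columns])


@pytest.fixture
def chain_graph():
    return make_graph(["A", "B", "C"], [("A", "B"), ("B", "C")])


@pytest.fixture
def collider_graph():
    return make_graph(["A", "B", "C"], [("A", "C"), ("B", "C")])
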