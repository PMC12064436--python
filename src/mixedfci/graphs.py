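"""Ground-truth causal structures: tiered DAGs with latent confounders.

The ground truth for a simulated cohort is a DAG over observed and latent
nodes, organised in temporal tiers (tier 0 is exogenous — the age and sex
analogues — and the designated outcome sits alone in the last tier).  Latent
nodes are pure confounders: parentless, with at least two observed children.

This module also provides the exact conditional-independence oracle
(d-separation in the full DAG) and the latent projection onto a maximal
ancestral graph (MAG), which together serve as ground truth for the
constraint-based discovery stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .pag import ARROW, PAG, TAIL

OBSERVED = "observed"
LATENT = "latent"


@dataclass
class GroundTruthGraph:
    """Tiered DAG with observed/latent roles and a designated outcome.

    ``node_types`` maps each node to 0 (continuous) or the number of levels
    (categorical, >= 2); ``categories`` carries the gold risk-factor category
    used by the variable-dictionary generator ("none" for decoys).
    """

    nodes: list[str]
    roles: dict[str, str]
    edges: list[tuple[str, str]]
    tiers: dict[str, int]
    outcome: str
    node_types: dict[str, int] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        nodeset = set(self.nodes)
        if len(nodeset) != len(self.nodes):
            raise ValueError("duplicate node ids")
        for u, v in self.edges:
            if u not in nodeset or v not in nodeset:
                raise ValueError(f"edge ({u}, {v}) references unknown node")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("edge set is cyclic")
        for u, v in self.edges:
            if self.tiers[u] > self.tiers[v]:
                raise ValueError(f"edge ({u}, {v}) goes backwards in tiers")
        if self.outcome not in nodeset:
            raise ValueError("outcome not among nodes")
        if any(u == self.outcome for u, _ in self.edges):
            raise ValueError("outcome has outgoing edges")
        for n in self.nodes:
            if self.roles.get(n) not in (OBSERVED, LATENT):
                raise ValueError(f"node {n} lacks a role")
            if self.roles[n] == LATENT:
                if g.in_degree(n) > 0:
                    raise ValueError(f"latent node {n} has parents")
                if g.out_degree(n) < 2:
                    raise ValueError(f"latent node {n} has fewer than 2 children")

    # -- views ---------------------------------------------------------------
    @property
    def observed_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.roles[n] == OBSERVED]

    @property
    def latent_nodes(self) -> list[str]:
        return [n for n in self.nodes if self.roles[n] == LATENT]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> list[str]:
        return sorted(u for u, v in self.edges if v == node)

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def ancestors(self, node: str) -> set[str]:
        return nx.ancestors(self.to_networkx(), node)

    # -- serialization --------------------------------------------------------
    def write(self, edges_path, sidecar_path, weights: dict | None = None) -> None:
        with open(edges_path, "w") as fh:
            fh.write("cause\teffect\tweight\n")
            for u, v in self.edges:
                w = "" if weights is None else weights.get((u, v), "")
                fh.write(f"{u}\t{v}\t{w}\n")
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "nodes": self.nodes,
                    "roles": self.roles,
                    "tiers": self.tiers,
                    "outcome": self.outcome,
                    "node_types": self.node_types,
                    "categories": self.categories,
                },
                fh,
                indent=1,
            )

    @classmethod
    def read(cls, edges_path, sidecar_path) -> "GroundTruthGraph":
        with open(sidecar_path) as fh:
            side = json.load(fh)
        edges = []
        with open(edges_path) as fh:
            fh.readline()
            for line in fh:
                if line.strip():
                    u, v = line.split("\t")[:2]
                    edges.append((u, v.strip()))
        return cls(
            nodes=side["nodes"],
            roles=side["roles"],
            edges=edges,
            tiers={k: int(t) for k, t in side["tiers"].items()},
            outcome=side["outcome"],
            node_types={k: int(t) for k, t in side.get("node_types", {}).items()},
            categories=side.get("categories", {}),
        )


def dsep_oracle(graph: GroundTruthGraph, a: str, b: str, s: set[str] | frozenset[str]) -> bool:
    """True iff ``a`` ⫫ ``b`` | ``s`` by d-separation in the full DAG.

    ``a``, ``b`` and all of ``s`` must be observed; conditioning on latents is
    not an operation the downstream tests can perform.  d-separation in the
    full graph given only observed sets coincides with m-separation in the
    latent projection over the observed nodes.
    """
    if a == b:
        raise ValueError("a and b must differ")
    s = set(s)
    obs = set(graph.observed_nodes)
    for n in {a, b} | s:
        if n not in set(graph.nodes):
            raise KeyError(f"unknown node {n!r}")
        if n not in obs:
            raise ValueError(f"node {n!r} is not observed")
    if a in s or b in s:
        raise ValueError("conditioning set must exclude the tested pair")
    return nx.is_d_separator(graph.to_networkx(), {a}, {b}, s)


def true_mag(graph: GroundTruthGraph, over: list[str] | None = None) -> PAG:
    """Latent projection of the ground-truth DAG onto its observed nodes.

    Two observed nodes are adjacent in the MAG iff no observed set separates
    them; by a standard result it suffices to test the single canonical set
    D(a, b) = (An(a) ∪ An(b)) ∩ observed \\ {a, b}.  Marks follow ancestry:
    a tail at an endpoint iff that endpoint is an ancestor of the other.

    ``over`` projects onto a subset of the observed nodes (any observed node
    outside it is treated as unmeasured), e.g. the post-selection variable set.
    """
    obs = graph.observed_nodes if over is None else list(over)
    if not set(obs) <= set(graph.observed_nodes):
        raise ValueError("projection set must consist of observed nodes")
    g = graph.to_networkx()
    anc = {n: nx.ancestors(g, n) for n in obs}
    mag = PAG(sorted(obs))
    for a, b in combinations(sorted(obs), 2):
        d = (anc[a] | anc[b]) & set(obs) - {a, b}
        if nx.is_d_separator(g, {a}, {b}, d):
            continue
        mark_at_a = TAIL if a in anc[b] else ARROW
        mark_at_b = TAIL if b in anc[a] else ARROW
        mag.add_edge(a, b, mark_at_a=mark_at_a, mark_at_b=mark_at_b)
    return mag


def separable_by_some_observed_set(graph: GroundTruthGraph, a: str, b: str) -> bool:
    """Exhaustive-search companion to :func:`true_mag` (small graphs only)."""
    others = [n for n in graph.observed_nodes if n not in (a, b)]
    for k in range(len(others) + 1):
        for s in combinations(others, k):
            if dsep_oracle(graph, a, b, set(s)):
                return True
    return False
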