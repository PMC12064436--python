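"""Partial ancestral graphs: endpoint-marked mixed graphs over observed variables.

A PAG edge between ``a`` and ``b`` carries one mark at each endpoint.  The mark
stored at ``b`` describes what the edge says about ``b``'s ancestral relation to
``a``: an arrowhead means ``b`` is not an ancestor of ``a``, a tail means it is,
and a circle leaves the question open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

CIRCLE = "o"
ARROW = ">"
TAIL = "-"
MARKS = (CIRCLE, ARROW, TAIL)


@dataclass
class PAG:
    """Endpoint-marked graph.

    ``marks[(a, b)]`` is the mark at ``b`` on the a–b edge; both orderings of an
    adjacent pair are always present.
    """

    nodes: list[str]
    marks: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        for (a, b), m in self.marks.items():
            if m not in MARKS:
                raise ValueError(f"unknown endpoint mark {m!r} on {(a, b)}")
            if a == b:
                raise ValueError(f"self edge on {a}")
            if (b, a) not in self.marks:
                raise ValueError(f"edge {a}-{b} missing its reverse mark")

    # -- construction -----------------------------------------------------
    def add_edge(self, a: str, b: str, mark_at_a: str = CIRCLE, mark_at_b: str = CIRCLE) -> None:
        if a == b:
            raise ValueError("self edges are not allowed")
        self.marks[(b, a)] = mark_at_a
        self.marks[(a, b)] = mark_at_b

    def remove_edge(self, a: str, b: str) -> None:
        del self.marks[(a, b)]
        del self.marks[(b, a)]

    def set_mark(self, a: str, b: str, mark: str) -> None:
        """Set the mark at ``b`` on the a–b edge."""
        if (a, b) not in self.marks:
            raise KeyError(f"{a} and {b} are not adjacent")
        if mark not in MARKS:
            raise ValueError(f"unknown mark {mark!r}")
        self.marks[(a, b)] = mark

    # -- queries ----------------------------------------------------------
    def is_adjacent(self, a: str, b: str) -> bool:
        return (a, b) in self.marks

    def mark_at(self, a: str, b: str) -> str:
        """Mark at ``b`` on the a–b edge."""
        return self.marks[(a, b)]

    def neighbors(self, a: str) -> list[str]:
        return sorted(b for (x, b) in self.marks if x == a)

    def edges(self) -> Iterator[tuple[str, str]]:
        """Unordered adjacent pairs, each once, lexicographically."""
        seen = sorted({tuple(sorted(p)) for p in self.marks})
        return iter(seen)  # type: ignore[arg-type]

    def n_edges(self) -> int:
        return len(self.marks) // 2

    def adjacencies(self) -> set[frozenset[str]]:
        return {frozenset(p) for p in self.marks}

    def copy(self) -> "PAG":
        return PAG(list(self.nodes), dict(self.marks))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PAG):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and self.marks == other.marks


def pag_ancestors(pag: PAG, node: str) -> set[str]:
    """Nodes of which ``node`` is a *definite* ancestor in the PAG.

    Follows only fully directed edges (tail at the source, arrowhead at the
    target); circle marks are never treated as tails.
    """
    if node not in pag.nodes:
        raise KeyError(f"unknown node {node!r}")
    reached: set[str] = set()
    frontier = [node]
    while frontier:
        u = frontier.pop()
        for v in pag.neighbors(u):
            if v in reached or v == node:
                continue
            if pag.mark_at(v, u) == TAIL and pag.mark_at(u, v) == ARROW:
                reached.add(v)
                frontier.append(v)
    return reached


def directed_parents(pag: PAG, node: str) -> set[str]:
    """Nodes with a fully directed edge into ``node`` (tail at source, arrow at node)."""
    return {
        v
        for v in pag.neighbors(node)
        if pag.mark_at(node, v) == TAIL and pag.mark_at(v, node) == ARROW
    }


# -- serialization --------------------------------------------------------

def write_pag_tsv(pag: PAG, path) -> None:
    """Four-column endpoint notation: node1, mark_at_node1, mark_at_node2, node2."""
    with open(path, "w") as fh:
        fh.write("node1\tmark_at_node1\tmark_at_node2\tnode2\n")
        for a, b in pag.edges():
            fh.write(f"{a}\t{pag.mark_at(b, a)}\t{pag.mark_at(a, b)}\t{b}\n")


def read_pag_tsv(path, nodes: Iterable[str] | None = None) -> PAG:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("node1"):
            raise ValueError("missing PAG TSV header")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    names = set()
    for a, _, _, b in rows:
        names.update((a, b))
    pag = PAG(sorted(names | set(nodes or ())))
    for a, m1, m2, b in rows:
        pag.add_edge(a, b, mark_at_a=m1, mark_at_b=m2)
    return pag


def write_pag_graphml(pag: PAG, path) -> None:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(pag.nodes)
    for a, b in pag.edges():
        g.add_edge(a, b, mark_at_node1=pag.mark_at(b, a), mark_at_node2=pag.mark_at(a, b))
    nx.write_graphml(g, path)
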