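"""Consensus networks: equal-weight pooling of PAGs across imputed datasets.

An *edge instance* is an unordered variable pair together with its oriented
endpoint-mark pair.  Each of the m per-imputation PAGs votes for the instances
it contains; an instance enters the threshold-t view when its agreement
fraction reaches at least t (the study's 30% / 50% / 100% tiers).  Agreement
is mark-level by default — the same pair with different marks counts as
distinct, conflicting instances — with an adjacency-only mode for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graphs import GroundTruthGraph, true_mag
from .pag import ARROW, CIRCLE, PAG, TAIL

#: Canonical instance key: (node1, node2, mark_at_node1, mark_at_node2) with
#: node1 < node2.
Instance = tuple[str, str, str, str]


def _instances(pag: PAG, mode: str) -> set[Instance]:
    out = set()
    for a, b in pag.edges():
        if mode == "adjacency":
            out.add((a, b, "*", "*"))
        else:
            out.add((a, b, pag.mark_at(b, a), pag.mark_at(a, b)))
    return out


@dataclass
class PooledNetwork:
    nodes: list[str]
    records: dict[Instance, int]
    m: int
    mode: str = "marks"
    thresholds: list[float] = field(default_factory=list)

    def fraction(self, instance: Instance) -> float:
        return self.records.get(instance, 0) / self.m

    def view(self, threshold: float) -> set[Instance]:
        """Instances whose agreement fraction is >= threshold."""
        if not 0.0 < threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")
        return {inst for inst, c in self.records.items() if c / self.m >= threshold}

    def conflicts(self) -> dict[tuple[str, str], list[Instance]]:
        """Pairs carried by more than one mark-variant across the m PAGs."""
        by_pair: dict[tuple[str, str], list[Instance]] = {}
        for inst in self.records:
            by_pair.setdefault((inst[0], inst[1]), []).append(inst)
        return {p: sorted(v) for p, v in by_pair.items() if len(v) > 1}

    def view_pag(self, threshold: float) -> PAG:
        """Threshold view as a PAG; conflicting variants of a pair are all
        reported side by side, so the PAG keeps the highest-agreement variant
        (ties broken to the more cautious, circle-rich variant)."""
        pag = PAG(list(self.nodes))
        chosen: dict[tuple[str, str], Instance] = {}
        rank = {CIRCLE: 0, TAIL: 1, ARROW: 2}
        for inst in sorted(self.view(threshold)):
            key = (inst[0], inst[1])
            if key not in chosen:
                chosen[key] = inst
                continue
            cur = chosen[key]
            if (self.records[inst], -(rank.get(inst[2], 0) + rank.get(inst[3], 0))) > (
                self.records[cur],
                -(rank.get(cur[2], 0) + rank.get(cur[3], 0)),
            ):
                chosen[key] = inst
        for (a, b), inst in chosen.items():
            if self.mode == "adjacency":
                pag.add_edge(a, b)
            else:
                pag.add_edge(a, b, mark_at_a=inst[2], mark_at_b=inst[3])
        return pag

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node1\tmark1\tmark2\tnode2\tcount\tfraction\tthreshold_flags\n")
            for inst in sorted(self.records):
                frac = self.fraction(inst)
                flags = ",".join(str(t) for t in self.thresholds if frac >= t)
                fh.write(
                    f"{inst[0]}\t{inst[2]}\t{inst[3]}\t{inst[1]}\t"
                    f"{self.records[inst]}\t{frac:.4f}\t{flags}\n"
                )


def pool_pags(pags: list[PAG], thresholds: list[float] = (0.3, 0.5, 1.0), mode: str = "marks") -> PooledNetwork:
    """Count identical edge instances across PAGs (equal weight per dataset)."""
    if not pags:
        raise ValueError("need at least one PAG")
    nodeset = set(pags[0].nodes)
    for p in pags[1:]:
        if set(p.nodes) != nodeset:
            raise ValueError("all PAGs must share the node set")
    for t in thresholds:
        if not 0.0 < t <= 1.0:
            raise ValueError("thresholds must lie in (0, 1]")
    if mode not in ("marks", "adjacency"):
        raise ValueError(f"unknown agreement mode {mode!r}")
    records: dict[Instance, int] = {}
    for p in pags:
        for inst in _instances(p, mode):
            records[inst] = records.get(inst, 0) + 1
    return PooledNetwork(
        nodes=sorted(nodeset),
        records=records,
        m=len(pags),
        mode=mode,
        thresholds=sorted(thresholds),
    )


def extract_outcome_subnetwork(
    pooled: PooledNetwork,
    outcome: str,
    threshold: float,
    max_steps: int = 2,
) -> PooledNetwork:
    """Outcome-centred subnetwork of a threshold view.

    Keeps the edges lying on some path of at most ``max_steps`` edges ending at
    the outcome whose marks are compatible with influence flowing towards the
    outcome: each step needs an arrowhead into the path's successor and a
    non-arrow (tail or circle) at the predecessor side.  The outcome node is
    always retained.
    """
    if outcome not in pooled.nodes:
        raise KeyError(f"outcome {outcome!r} not in the pooled network")
    view = pooled.view(threshold)
    pag = PAG(list(pooled.nodes))
    for a, b, m1, m2 in view:
        if not pag.is_adjacent(a, b):
            pag.add_edge(a, b, mark_at_a=m1, mark_at_b=m2)
    kept: set[Instance] = set()
    depth = {outcome: 0}
    frontier = [outcome]
    while frontier:
        w = frontier.pop(0)
        if depth[w] >= max_steps:
            continue
        for inst in sorted(view):
            a, b, m1, m2 = inst
            for pred, succ, mp, ms in ((a, b, m1, m2), (b, a, m2, m1)):
                if succ != w:
                    continue
                if ms != ARROW or mp == ARROW:
                    continue  # needs arrowhead into successor, non-arrow at predecessor
                kept.add(inst)
                if pred not in depth or depth[pred] > depth[w] + 1:
                    depth[pred] = depth[w] + 1
                    frontier.append(pred)
    records = {inst: pooled.records[inst] for inst in kept}
    nodes = sorted({outcome} | {n for inst in kept for n in inst[:2]})
    return PooledNetwork(nodes=nodes, records=records, m=pooled.m, mode=pooled.mode, thresholds=pooled.thresholds)


@dataclass
class RecoveryReport:
    adjacency_precision: float
    adjacency_recall: float
    orientation_accuracy: float
    n_edges: int
    n_true_edges: int

    def as_dict(self) -> dict:
        return {
            "adjacency_precision": self.adjacency_precision,
            "adjacency_recall": self.adjacency_recall,
            "orientation_accuracy": self.orientation_accuracy,
            "n_edges": self.n_edges,
            "n_true_edges": self.n_true_edges,
        }


def compare_to_truth(pooled: PooledNetwork, truth: GroundTruthGraph, threshold: float) -> RecoveryReport:
    """Adjacency precision/recall of a threshold view against the true MAG, and
    the fraction of claimed arrowheads consistent with true non-ancestry.

    An empty view has precision 1.0 by convention (no false claims).
    The truth is projected onto the pooled network's node set, so variables
    dropped before analysis are treated as unmeasured.
    """
    over = [n for n in pooled.nodes if n in set(truth.observed_nodes)]
    mag = true_mag(truth, over=over)
    true_adj = {frozenset(p) for p in mag.adjacencies()}
    view = pooled.view(threshold)
    found_adj = {frozenset((a, b)) for a, b, _, _ in view}
    tp = len(found_adj & true_adj)
    precision = tp / len(found_adj) if found_adj else 1.0
    recall = tp / len(true_adj) if true_adj else 1.0

    g = truth.to_networkx()
    import networkx as nx

    anc = {n: nx.ancestors(g, n) for n in truth.observed_nodes}
    n_arrows = 0
    n_consistent = 0
    for a, b, m1, m2 in view:
        for node, other, mark in ((a, b, m1), (b, a, m2)):
            if mark == ARROW:
                n_arrows += 1
                if node not in anc[other]:  # arrow at `node`: not an ancestor of other
                    n_consistent += 1
    orientation = n_consistent / n_arrows if n_arrows else 1.0
    return RecoveryReport(
        adjacency_precision=precision,
        adjacency_recall=recall,
        orientation_accuracy=orientation,
        n_edges=len(found_adj),
        n_true_edges=len(true_adj),
    )
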