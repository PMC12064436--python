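"""FCI-MAX: constraint-based causal discovery tolerant of latent confounders.

The algorithm takes any conditional-independence provider (a dataset-backed
nested-model test or the exact d-separation oracle) and produces a partial
ancestral graph:

1. *Adjacency phase* — PC-style edge elimination starting from an optional
   prior skeleton (e.g. a fitted mixed-graphical-model skeleton; the prior can
   only restrict, never add, adjacencies).  At each conditioning-set size the
   whole batch of tests is corrected by Benjamini–Hochberg before any edge is
   removed.  A possible-d-sep sweep then re-tests surviving edges against
   subsets of the Possible-D-SEP sets, as required for adjacency correctness
   under latent confounding.
2. *Orientation phase* — unshielded triples are oriented as colliders by the
   MAX rule: the separating set with the highest p-value among all recorded
   and searched candidates decides, which is the defining feature of the
   FCI-MAX variant.  Zhang's orientation rules R1–R4 and R8–R10 then run to a
   fixed point (R5–R7 are omitted: the pipeline assumes no selection bias).
3. *Background knowledge* — forbidden cause→effect pairs and temporal tiers
   are enforced by placing an arrowhead at the forbidden cause's endpoint
   before rule propagation; a rule that later contradicts a knowledge-forced
   mark raises a conflict error naming the edge and rule.

Everything is deterministic: nodes are processed in lexicographic order and
candidate separating sets in (size, lexicographic) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .citest import CITestResult, fdr_adjust
from .mgm import Skeleton
from .pag import ARROW, CIRCLE, PAG, TAIL


class KnowledgeConflictError(RuntimeError):
    """Background knowledge contradicts a data-forced orientation."""


@dataclass
class Knowledge:
    """Forbidden cause→effect pairs plus temporal tiers (a later-tier node may
    not cause an earlier-tier one).  ``forbid_all_from`` marks sinks such as
    the outcome: never a cause of anything."""

    forbidden: set[tuple[str, str]] = field(default_factory=set)
    tiers: dict[str, int] = field(default_factory=dict)
    forbid_all_from: set[str] = field(default_factory=set)

    def forbids(self, cause: str, effect: str) -> bool:
        if (cause, effect) in self.forbidden or cause in self.forbid_all_from:
            return True
        tc, te = self.tiers.get(cause), self.tiers.get(effect)
        return tc is not None and te is not None and tc > te


class _FciState:
    def __init__(self, ci, nodes, alpha, max_cond_size, pdsep_pool_cap=None):
        self.ci = ci
        self.nodes = sorted(nodes)
        self.alpha = alpha
        self.max_cond = len(self.nodes) - 2 if max_cond_size is None else max_cond_size
        self.pdsep_pool_cap = pdsep_pool_cap
        self.adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        # pair -> list of (sepset, raw p) judged independent
        self.sepsets: dict[tuple[str, str], list[tuple[frozenset, float]]] = {}
        self.log: list[CITestResult] = []
        self._ms_cache: dict[tuple[str, str], frozenset | None] = {}

    def pair(self, a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    def edges(self) -> list[tuple[str, str]]:
        return [(a, b) for a in self.nodes for b in sorted(self.adj[a]) if a < b]

    # -- batched testing with per-size FDR ---------------------------------
    def run_batch(self, queries: dict[tuple[tuple[str, str], frozenset], None]) -> set[tuple[str, str]]:
        """Run a batch of CI queries, BH-adjust, record separating sets.
        Returns the pairs judged independent by at least one query."""
        keys = sorted(queries, key=lambda k: (k[0], sorted(k[1])))
        results = [self.ci(p[0], p[1], s) for p, s in keys]
        adjusted = fdr_adjust(results, self.alpha)
        self.log.extend(adjusted)
        separated: set[tuple[str, str]] = set()
        for (pairkey, s), res in zip(keys, adjusted):
            if res.testable and res.adjusted_p > self.alpha:
                self.sepsets.setdefault(pairkey, []).append((s, res.p_value))
                separated.add(pairkey)
        return separated

    # -- max-p separating set ----------------------------------------------
    def max_sepset(self, a: str, b: str) -> frozenset | None:
        """Separating set of (a, b) with the maximum p-value, searching the
        current adjacency neighborhoods in addition to anything recorded.
        Memoized; the cache is reset whenever adjacencies change."""
        pairkey = self.pair(a, b)
        if pairkey in self._ms_cache:
            return self._ms_cache[pairkey]
        candidates: dict[frozenset, float] = {}
        seen = set()
        for size in range(self.max_cond + 1):
            for side in pairkey:
                other = pairkey[1] if side == pairkey[0] else pairkey[0]
                nbrs = sorted(self.adj[side] - {pairkey[0], pairkey[1]})
                if len(nbrs) < size:
                    continue
                for s in combinations(nbrs, size):
                    fs = frozenset(s)
                    if fs in seen:
                        continue
                    seen.add(fs)
                    res = self.ci(pairkey[0], pairkey[1], fs)
                    if res.testable and res.p_value > self.alpha:
                        candidates[fs] = res.p_value
        for s, p in self.sepsets.get(pairkey, []):
            candidates.setdefault(s, p)
        if not candidates:
            self._ms_cache[pairkey] = None
            return None
        # deterministic argmax: highest p, ties to the smallest then
        # lexicographically first set
        ordered = sorted(candidates, key=lambda s: (len(s), tuple(sorted(s))))
        best = ordered[0]
        for s in ordered[1:]:
            if candidates[s] > candidates[best]:
                best = s
        self._ms_cache[pairkey] = best
        return best

    def remove_edge(self, a: str, b: str) -> None:
        self.adj[a].discard(b)
        self.adj[b].discard(a)
        self._ms_cache.clear()


def _initial_adjacency(state: _FciState, initial_skeleton: Skeleton | None) -> None:
    for a, b in combinations(state.nodes, 2):
        if initial_skeleton is None or initial_skeleton.is_adjacent(a, b):
            state.adj[a].add(b)
            state.adj[b].add(a)


def _adjacency_phase(state: _FciState) -> None:
    for depth in range(state.max_cond + 1):
        queries: dict = {}
        for a, b in state.edges():
            seen_local = set()
            for side, other in ((a, b), (b, a)):
                nbrs = sorted(state.adj[side] - {a, b})
                if len(nbrs) < depth:
                    continue
                for s in combinations(nbrs, depth):
                    fs = frozenset(s)
                    if fs not in seen_local:
                        seen_local.add(fs)
                        queries[((a, b), fs)] = None
        if not queries:
            break
        for a, b in state.run_batch(queries):
            state.remove_edge(a, b)


def _preliminary_colliders(state: _FciState) -> PAG:
    pag = PAG(state.nodes)
    for a, b in state.edges():
        pag.add_edge(a, b)
    _orient_max_colliders(state, pag, knowledge=None, strict=False)
    return pag


def _possible_dsep(pag: PAG, x: str) -> list[str]:
    """Possible-D-SEP(x): nodes reachable along paths where every interior
    vertex is either a collider or part of a shielded triple."""
    reached: set[tuple[str, str]] = set()
    frontier = [(x, v) for v in pag.neighbors(x)]
    reached.update(frontier)
    while frontier:
        prev, cur = frontier.pop()
        for nxt in pag.neighbors(cur):
            if nxt == prev or (cur, nxt) in reached:
                continue
            collider = pag.mark_at(prev, cur) == ARROW and pag.mark_at(nxt, cur) == ARROW
            shielded = pag.is_adjacent(prev, nxt)
            if collider or shielded:
                reached.add((cur, nxt))
                frontier.append((cur, nxt))
    return sorted({v for _, v in reached if v != x})


def _pdsep_phase(state: _FciState) -> None:
    pag = _preliminary_colliders(state)
    pdsep = {x: _possible_dsep(pag, x) for x in state.nodes}
    if state.pdsep_pool_cap is not None:
        # keep the cap nodes closest in the current adjacency graph (then
        # lexicographic) — a tractability bound for large variable sets
        for x in state.nodes:
            dist = {x: 0}
            frontier = [x]
            while frontier:
                u = frontier.pop(0)
                for v in sorted(state.adj[u]):
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        frontier.append(v)
            ranked = sorted(pdsep[x], key=lambda v: (dist.get(v, len(state.nodes)), v))
            pdsep[x] = sorted(ranked[: state.pdsep_pool_cap])
    for size in range(state.max_cond + 1):
        queries: dict = {}
        for a, b in state.edges():
            seen_local = set()
            for side in (a, b):
                pool = [v for v in pdsep[side] if v not in (a, b)]
                if len(pool) < size:
                    continue
                for s in combinations(pool, size):
                    fs = frozenset(s)
                    if fs not in seen_local:
                        seen_local.add(fs)
                        queries[((a, b), fs)] = None
        if not queries:
            break
        for a, b in state.run_batch(queries):
            state.remove_edge(a, b)


# -- orientation -----------------------------------------------------------

def _set_mark(pag: PAG, a: str, b: str, mark: str, rule: str) -> bool:
    """Set the mark at ``b`` on a–b; returns True if it changed.

    A definite mark is never overwritten: contradicting a knowledge-forced
    mark raises a conflict error; contradicting an earlier rule-set mark keeps
    the earlier mark (first definite orientation wins, deterministically).
    """
    cur = pag.mark_at(a, b)
    if cur == mark:
        return False
    if cur != CIRCLE:
        if (a, b) in getattr(pag, "knowledge_marks", set()):
            raise KnowledgeConflictError(
                f"rule {rule} wants mark {mark!r} at {b} on edge {a}-{b}, "
                f"but background knowledge fixed it to {cur!r}"
            )
        return False
    pag.set_mark(a, b, mark)
    return True


def _apply_knowledge(pag: PAG, knowledge: Knowledge | None) -> None:
    pag.knowledge_marks = set()  # type: ignore[attr-defined]
    if knowledge is None:
        return
    for a, b in pag.edges():
        for cause, effect in ((a, b), (b, a)):
            if knowledge.forbids(cause, effect):
                # an arrowhead at the forbidden cause: it cannot be an ancestor
                pag.set_mark(effect, cause, ARROW)
                pag.knowledge_marks.add((effect, cause))  # type: ignore[attr-defined]


def _orient_max_colliders(state: _FciState, pag: PAG, knowledge: Knowledge | None, strict: bool = True) -> None:
    for c in pag.nodes:
        nbrs = pag.neighbors(c)
        for a, b in combinations(nbrs, 2):
            if pag.is_adjacent(a, b):
                continue
            sep = state.max_sepset(a, b)
            if sep is None or c in sep:
                continue
            for x in (a, b):
                if pag.mark_at(x, c) != ARROW:
                    if strict:
                        _set_mark(pag, x, c, ARROW, rule="max-collider")
                    elif pag.mark_at(x, c) == CIRCLE:
                        pag.set_mark(x, c, ARROW)


def _is_pd_edge(pag: PAG, u: str, v: str) -> bool:
    """Edge u–v traversable as possibly-directed u → v (no arrow back at u, no
    tail at v)."""
    return pag.mark_at(v, u) != ARROW and pag.mark_at(u, v) != TAIL


def _uncovered_pd_paths_from(pag: PAG, a: str, target: str) -> list[list[str]]:
    """All uncovered possibly-directed paths from ``a`` to ``target`` of length
    >= 2 edges (DFS; graphs here are sparse)."""
    out: list[list[str]] = []

    def rec(path: list[str]) -> None:
        cur = path[-1]
        for nxt in pag.neighbors(cur):
            if nxt in path:
                continue
            if not _is_pd_edge(pag, cur, nxt):
                continue
            if len(path) >= 2 and pag.is_adjacent(path[-2], nxt):
                continue  # covered triple
            if nxt == target:
                if len(path) >= 2:
                    out.append(path + [nxt])
                continue
            rec(path + [nxt])

    rec([a])
    return out


def _rules_pass(state: _FciState, pag: PAG) -> bool:
    changed = False
    edges = list(pag.edges())

    # R1 / R2 / R3 over ordered triples
    for b in pag.nodes:
        for a in pag.neighbors(b):
            for c in pag.neighbors(b):
                if c == a:
                    continue
                # R1: a *-> b o-* c, a and c nonadjacent  =>  b -> c
                if (
                    not pag.is_adjacent(a, c)
                    and pag.mark_at(a, b) == ARROW
                    and pag.mark_at(c, b) == CIRCLE
                ):
                    changed |= _set_mark(pag, c, b, TAIL, "R1")
                    changed |= _set_mark(pag, b, c, ARROW, "R1")
                # R2: (a -> b *-> c) or (a *-> b -> c), a *-o c  =>  a *-> c
                if pag.is_adjacent(a, c) and pag.mark_at(a, c) == CIRCLE:
                    chain1 = (
                        pag.mark_at(b, a) == TAIL
                        and pag.mark_at(a, b) == ARROW
                        and pag.mark_at(b, c) == ARROW
                    )
                    chain2 = (
                        pag.mark_at(a, b) == ARROW
                        and pag.mark_at(c, b) == TAIL
                        and pag.mark_at(b, c) == ARROW
                    )
                    if chain1 or chain2:
                        changed |= _set_mark(pag, a, c, ARROW, "R2")
    # R3: a *-> b <-* c, a *-o d o-* c, a,c nonadjacent, d *-o b  =>  d *-> b
    for b in pag.nodes:
        into_b = [x for x in pag.neighbors(b) if pag.mark_at(x, b) == ARROW]
        circ_b = [d for d in pag.neighbors(b) if pag.mark_at(d, b) == CIRCLE]
        for a, c in combinations(sorted(into_b), 2):
            if pag.is_adjacent(a, c):
                continue
            for d in circ_b:
                if (
                    pag.is_adjacent(a, d)
                    and pag.is_adjacent(c, d)
                    and pag.mark_at(a, d) == CIRCLE
                    and pag.mark_at(c, d) == CIRCLE
                ):
                    changed |= _set_mark(pag, d, b, ARROW, "R3")
    # R4: discriminating paths
    changed |= _rule_r4(state, pag)
    # R8/R9/R10 act on a o-> c edges
    for a, c in edges:
        for x, y in ((a, c), (c, a)):
            if not pag.is_adjacent(x, y):
                continue
            if not (pag.mark_at(y, x) == CIRCLE and pag.mark_at(x, y) == ARROW):
                continue  # need x o-> y
            # R8: x -> b -> y or x -o b -> y  =>  tail at x
            fired = False
            for b in pag.neighbors(x):
                if b == y or not pag.is_adjacent(b, y):
                    continue
                first_ok = pag.mark_at(b, x) == TAIL and pag.mark_at(x, b) in (ARROW, CIRCLE)
                second_ok = pag.mark_at(y, b) == TAIL and pag.mark_at(b, y) == ARROW
                if first_ok and second_ok:
                    changed |= _set_mark(pag, y, x, TAIL, "R8")
                    fired = True
                    break
            if fired:
                continue
            # R9: uncovered p.d. path <x, b, ..., y> with b not adjacent to y
            paths = _uncovered_pd_paths_from(pag, x, y)
            if any(not pag.is_adjacent(p[1], y) for p in paths):
                changed |= _set_mark(pag, y, x, TAIL, "R9")
                continue
            # R10: two uncovered p.d. paths from x to parents b, d of y with
            # distinct, nonadjacent first steps
            parents = [
                b
                for b in pag.neighbors(y)
                if b != x and pag.mark_at(y, b) == TAIL and pag.mark_at(b, y) == ARROW
            ]
            first_steps: dict[str, set[str]] = {}
            for b in parents:
                if pag.is_adjacent(x, b) and _is_pd_edge(pag, x, b):
                    first_steps.setdefault(b, set()).add(b)
                for p in _uncovered_pd_paths_from(pag, x, b):
                    first_steps.setdefault(b, set()).add(p[1])
            for b, d in combinations(sorted(first_steps), 2):
                hit = False
                for m1 in sorted(first_steps[b]):
                    for m2 in sorted(first_steps[d]):
                        if m1 != m2 and not pag.is_adjacent(m1, m2) and m1 != y and m2 != y:
                            changed |= _set_mark(pag, y, x, TAIL, "R10")
                            hit = True
                            break
                    if hit:
                        break
                if hit:
                    break
    return changed


def _rule_r4(state: _FciState, pag: PAG) -> bool:
    """Discriminating-path rule.  For a path <d, ..., a, b, c> where every
    vertex between d and b is a collider on the path and a parent of c, and d
    is not adjacent to c: if b lies in the max-p separating set of (d, c),
    orient b -> c; otherwise orient a <-> b <-> c."""
    changed = False
    for b in pag.nodes:
        for c in pag.neighbors(b):
            if pag.mark_at(c, b) != CIRCLE:
                continue
            for a in pag.neighbors(b):
                if a in (b, c) or not pag.is_adjacent(a, c):
                    continue
                # a must be a collider on the path towards b and a parent of c
                if pag.mark_at(b, a) != ARROW:
                    continue
                if not (pag.mark_at(c, a) == TAIL and pag.mark_at(a, c) == ARROW):
                    continue
                d = _find_discriminating_origin(pag, a, b, c)
                if d is None:
                    continue
                sep = state.max_sepset(d, c)
                if sep is not None and b in sep:
                    changed |= _set_mark(pag, c, b, TAIL, "R4")
                    changed |= _set_mark(pag, b, c, ARROW, "R4")
                else:
                    changed |= _set_mark(pag, b, a, ARROW, "R4")
                    changed |= _set_mark(pag, a, b, ARROW, "R4")
                    changed |= _set_mark(pag, c, b, ARROW, "R4")
                    changed |= _set_mark(pag, b, c, ARROW, "R4")
    return changed


def _find_discriminating_origin(pag: PAG, a: str, b: str, c: str) -> str | None:
    """Walk backwards from ``a`` through colliders that are parents of ``c``
    until a vertex not adjacent to ``c`` (the origin d) is found."""
    visited = {a, b, c}
    frontier = [a]
    while frontier:
        last = frontier.pop(0)
        for t in sorted(pag.neighbors(last)):
            if t in visited:
                continue
            if pag.mark_at(t, last) != ARROW:  # t *-> last required
                continue
            if not pag.is_adjacent(t, c):
                return t
            # t must itself be a collider-parent of c to extend the path
            if pag.mark_at(last, t) == ARROW and pag.mark_at(c, t) == TAIL and pag.mark_at(t, c) == ARROW:
                visited.add(t)
                frontier.append(t)
    return None


def fci_max(
    ci,
    nodes: list[str],
    initial_skeleton: Skeleton | None = None,
    knowledge: Knowledge | None = None,
    alpha: float = 0.05,
    max_cond_size: int | None = 3,
    pdsep: bool = True,
    pdsep_pool_cap: int | None = None,
) -> PAG:
    """Run FCI-MAX; see the module docstring for the phases.

    ``ci`` is any callable ``(a, b, S) -> CITestResult``.  ``max_cond_size``
    of None means unlimited (exact search; use with the oracle on small
    graphs).  ``pdsep_pool_cap`` bounds the Possible-D-SEP pool per node on
    large problems (None = no bound).  The returned PAG also carries the CI
    audit log as ``pag.ci_log``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    state = _FciState(ci, nodes, alpha, max_cond_size, pdsep_pool_cap)
    _initial_adjacency(state, initial_skeleton)
    _adjacency_phase(state)
    if pdsep:
        _pdsep_phase(state)

    pag = PAG(state.nodes)
    for a, b in state.edges():
        pag.add_edge(a, b)
    _apply_knowledge(pag, knowledge)
    _orient_max_colliders(state, pag, knowledge, strict=True)
    while _rules_pass(state, pag):
        pass
    pag.ci_log = state.log  # type: ignore[attr-defined]
    return pag
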