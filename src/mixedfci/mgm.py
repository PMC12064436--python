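"""Sparse mixed graphical models over continuous + categorical variables.

The model is pairwise: unit-variance Gaussian conditionals for continuous
nodes and multinomial-logistic conditionals for categorical nodes, with
shared symmetric interaction parameters — a scalar per continuous pair, a
per-level vector per continuous–categorical pair, and a level×level block per
categorical pair.  Fitting minimizes the joint negative log-pseudolikelihood
(sum of node conditionals) plus a group-lasso penalty per edge block, by
proximal gradient descent with backtracking; blocks whose subgradient falls
below the penalty are exactly zero, and the surviving blocks define the
undirected skeleton handed to the causal-discovery stage.

Categorical variables are one-hot coded without a dropped reference level;
the group penalty resolves the softmax shift invariance (the minimum-norm
representative of each block is centred), which plays the role of a
sum-to-zero identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .data import MixedDataset, one_hot


@dataclass
class Skeleton:
    nodes: list[str]
    adjacency: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for pair in self.adjacency:
            if len(pair) != 2:
                raise ValueError("adjacency entries must be unordered pairs")
            if not pair <= set(self.nodes):
                raise ValueError(f"pair {set(pair)} references unknown nodes")

    def is_adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.adjacency

    def n_edges(self) -> int:
        return len(self.adjacency)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node1\tnode2\n")
            for pair in sorted(tuple(sorted(p)) for p in self.adjacency):
                fh.write(f"{pair[0]}\t{pair[1]}\n")

    def write_graphml(self, path) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(sorted(p)) for p in self.adjacency)
        nx.write_graphml(g, path)


@dataclass
class MGMParams:
    cont_names: list[str]
    cat_names: list[str]
    cat_levels: dict[str, int]
    cont_cont: np.ndarray  # pc × pc symmetric, zero diagonal
    cont_cat: np.ndarray  # pc × L_total
    cat_cat: np.ndarray  # L_total × L_total, symmetric, zero diagonal blocks
    node_potentials: dict[str, np.ndarray]
    lam: tuple[float, float, float]
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True

    def slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for name in self.cat_names:
            stop = start + self.cat_levels[name]
            out[name] = slice(start, stop)
            start = stop
        return out

    def save(self, path) -> None:
        """NPZ archive of the fitted parameters (for reproducibility audits)."""
        np.savez(
            path,
            cont_names=np.array(self.cont_names),
            cat_names=np.array(self.cat_names),
            cat_levels=np.array([self.cat_levels[n] for n in self.cat_names]),
            cont_cont=self.cont_cont,
            cont_cat=self.cont_cat,
            cat_cat=self.cat_cat,
            alpha=self.node_potentials["_alpha"],
            theta=self.node_potentials["_theta"],
            lam=np.array(self.lam),
        )

    @classmethod
    def load(cls, path) -> "MGMParams":
        z = np.load(path, allow_pickle=False)
        cat_names = [str(n) for n in z["cat_names"]]
        return cls(
            cont_names=[str(n) for n in z["cont_names"]],
            cat_names=cat_names,
            cat_levels={n: int(l) for n, l in zip(cat_names, z["cat_levels"])},
            cont_cont=z["cont_cont"],
            cont_cat=z["cont_cat"],
            cat_cat=z["cat_cat"],
            node_potentials={"_alpha": z["alpha"], "_theta": z["theta"]},
            lam=tuple(float(v) for v in z["lam"]),
        )

    def block_norm(self, a: str, b: str) -> float:
        """Norm of the full interaction block of an unordered pair."""
        sl = self.slices()
        ci = {n: i for i, n in enumerate(self.cont_names)}
        if a in ci and b in ci:
            return abs(float(self.cont_cont[ci[a], ci[b]]))
        if a in ci:
            return float(np.linalg.norm(self.cont_cat[ci[a], sl[b]]))
        if b in ci:
            return float(np.linalg.norm(self.cont_cat[ci[b], sl[a]]))
        return float(np.linalg.norm(self.cat_cat[sl[a], sl[b]]))


class _Design:
    def __init__(self, data: MixedDataset):
        self.cont_names = data.continuous_names
        self.cat_names = data.categorical_names
        self.cat_levels = {n: data.meta_for(n).n_levels for n in self.cat_names}
        self.x = data.values[self.cont_names].to_numpy() if self.cont_names else np.empty((data.n_samples, 0))
        blocks, self.slices, start = [], {}, 0
        for name in self.cat_names:
            lv = self.cat_levels[name]
            blocks.append(one_hot(data.values[name].to_numpy(), lv))
            self.slices[name] = slice(start, start + lv)
            start += lv
        self.z = np.hstack(blocks) if blocks else np.empty((data.n_samples, 0))
        self.n = data.n_samples
        if not np.isfinite(self.x).all():
            bad = [n for i, n in enumerate(self.cont_names) if not np.isfinite(self.x[:, i]).all()]
            raise FloatingPointError(f"non-finite values in column(s) {bad}")


def _smooth_objective(d: _Design, alpha, theta, b, p, phi, want_grad: bool):
    n = d.n
    mu = alpha[None, :] + d.x @ b + d.z @ p.T
    r = mu - d.x
    val = 0.5 * float((r * r).sum()) / n

    q = np.empty_like(d.z)
    for name in d.cat_names:
        sl = d.slices[name]
        scores = theta[sl][None, :] + d.x @ p[:, sl] + d.z @ phi[:, sl]
        scores = scores - scores.max(axis=1, keepdims=True)
        exps = np.exp(scores)
        probs = exps / exps.sum(axis=1, keepdims=True)
        zsl = d.z[:, sl]
        val -= float((zsl * np.log(probs + 1e-300)).sum()) / n
        q[:, sl] = (probs - zsl) / n
    if not want_grad:
        return val, None
    g_alpha = r.sum(axis=0) / n
    g_b = (d.x.T @ r + r.T @ d.x) / n
    np.fill_diagonal(g_b, 0.0)
    g_theta = q.sum(axis=0)
    g_p = (r.T @ d.z) / n + d.x.T @ q
    ztq = d.z.T @ q
    g_phi = ztq + ztq.T
    for name in d.cat_names:
        sl = d.slices[name]
        g_phi[sl, sl] = 0.0
    return val, (g_alpha, g_theta, g_b, g_p, g_phi)


def _penalty(d: _Design, b, p, phi, lam) -> float:
    lcc, lcd, ldd = lam
    val = lcc * float(np.abs(np.triu(b, 1)).sum())
    for name in d.cat_names:
        sl = d.slices[name]
        val += lcd * float(np.linalg.norm(p[:, sl], axis=1).sum())
    for qn, rn in combinations(d.cat_names, 2):
        val += ldd * float(np.linalg.norm(phi[d.slices[qn], d.slices[rn]]))
    return val


def _prox(d: _Design, b, p, phi, lam, step):
    lcc, lcd, ldd = lam
    bb = np.sign(b) * np.maximum(np.abs(b) - step * lcc, 0.0)
    np.fill_diagonal(bb, 0.0)
    pp = p.copy()
    for name in d.cat_names:
        sl = d.slices[name]
        blk = pp[:, sl]
        norms = np.linalg.norm(blk, axis=1, keepdims=True)
        shrink = np.maximum(1.0 - step * lcd / np.maximum(norms, 1e-300), 0.0)
        pp[:, sl] = blk * shrink
    ff = phi.copy()
    for qn, rn in combinations(d.cat_names, 2):
        sq, sr = d.slices[qn], d.slices[rn]
        blk = ff[sq, sr]
        norm = np.linalg.norm(blk)
        factor = max(1.0 - step * ldd / max(norm, 1e-300), 0.0)
        ff[sq, sr] = blk * factor
        ff[sr, sq] = ff[sq, sr].T
    return bb, pp, ff


def _as_triple(lam) -> tuple[float, float, float]:
    """Expand a scalar lambda to the (cont-cont, cont-cat, cat-cat) triple.

    One-hot indicator columns have roughly half the standard deviation of a
    standardized continuous column, so a shared scalar over-penalizes blocks
    with categorical sides; the default weighting scales the penalty by 2/3
    per categorical side.  An explicit triple overrides this.
    """
    if np.isscalar(lam):
        lam = (float(lam), 2.0 * float(lam) / 3.0, 4.0 * float(lam) / 9.0)
    lam = tuple(float(v) for v in lam)
    if len(lam) != 3 or any(v <= 0 for v in lam):
        raise ValueError("lambda must be a positive scalar or positive triple")
    return lam  # type: ignore[return-value]


def mgm_fit(
    data: MixedDataset,
    lam,
    max_iter: int = 500,
    tol: float = 1e-5,
    warm_start: MGMParams | None = None,
) -> MGMParams:
    """Penalized pseudolikelihood fit by monotone proximal gradient descent."""
    if not data.is_complete():
        raise ValueError("MGM requires complete data — impute first")
    if data.n_samples < 10:
        raise ValueError("need at least 10 samples")
    lam = _as_triple(lam)
    d = _Design(data)
    pc, lt = d.x.shape[1], d.z.shape[1]
    if warm_start is not None:
        alpha = warm_start.node_potentials["_alpha"].copy()
        theta = warm_start.node_potentials["_theta"].copy()
        b, p, phi = warm_start.cont_cont.copy(), warm_start.cont_cat.copy(), warm_start.cat_cat.copy()
    else:
        alpha, theta = np.zeros(pc), np.zeros(lt)
        b, p, phi = np.zeros((pc, pc)), np.zeros((pc, lt)), np.zeros((lt, lt))

    step = 1.0
    fval, grads = _smooth_objective(d, alpha, theta, b, p, phi, want_grad=True)
    total = fval + _penalty(d, b, p, phi, lam)
    if not np.isfinite(total):
        raise FloatingPointError("non-finite objective at initialization")
    trace = [total]
    converged = False
    for _ in range(max_iter):
        ga, gt, gb, gp, gphi = grads
        while True:
            na = alpha - step * ga
            nt = theta - step * gt
            nb, np_, nphi = _prox(d, b - step * gb, p - step * gp, phi - step * gphi, lam, step)
            fnew, _ = _smooth_objective(d, na, nt, nb, np_, nphi, want_grad=False)
            # B and Phi store each tied symmetric parameter twice; count once
            diff = (
                float(((na - alpha) * ga).sum())
                + float(((nt - theta) * gt).sum())
                + float(((nb - b) * gb).sum()) / 2.0
                + float(((np_ - p) * gp).sum())
                + float(((nphi - phi) * gphi).sum()) / 2.0
            )
            sq = (
                float(((na - alpha) ** 2).sum())
                + float(((nt - theta) ** 2).sum())
                + float(((nb - b) ** 2).sum()) / 2.0
                + float(((np_ - p) ** 2).sum())
                + float(((nphi - phi) ** 2).sum()) / 2.0
            )
            if fnew <= fval + diff + sq / (2 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-12:
                break
        alpha, theta, b, p, phi = na, nt, nb, np_, nphi
        fval, grads = _smooth_objective(d, alpha, theta, b, p, phi, want_grad=True)
        new_total = fval + _penalty(d, b, p, phi, lam)
        if not np.isfinite(new_total):
            raise FloatingPointError("objective became non-finite (degenerate column?)")
        trace.append(min(new_total, trace[-1]))
        if abs(total - new_total) <= tol * max(1.0, abs(total)):
            total = new_total
            converged = True
            break
        total = new_total
        step = min(step * 1.25, 10.0)

    if not converged:
        import warnings

        gnorm = float(np.sqrt(sum(float((g * g).sum()) for g in grads)))
        warnings.warn(f"MGM fit hit max_iter={max_iter} (gradient norm {gnorm:.3g})", RuntimeWarning)
    return MGMParams(
        cont_names=d.cont_names,
        cat_names=d.cat_names,
        cat_levels=d.cat_levels,
        cont_cont=b,
        cont_cat=p,
        cat_cat=phi,
        node_potentials={"_alpha": alpha, "_theta": theta},
        lam=lam,
        objective_trace=trace,
        converged=converged,
    )


def mgm_skeleton(params: MGMParams, zero_tol: float = 1e-8) -> Skeleton:
    """Undirected skeleton: an edge wherever a pair's interaction block norm
    exceeds ``zero_tol``."""
    nodes = sorted(params.cont_names + params.cat_names)
    adjacency = {
        frozenset((a, b))
        for a, b in combinations(nodes, 2)
        if params.block_norm(a, b) > zero_tol
    }
    return Skeleton(nodes=nodes, adjacency=adjacency)


def _pseudo_bic(data: MixedDataset, params: MGMParams) -> float:
    d = _Design(data)
    fval, _ = _smooth_objective(
        d,
        params.node_potentials["_alpha"],
        params.node_potentials["_theta"],
        params.cont_cont,
        params.cont_cat,
        params.cat_cat,
        want_grad=False,
    )
    df = len(params.cont_names) + sum(params.cat_levels.values())
    nodes = sorted(params.cont_names + params.cat_names)
    sl = params.slices()
    for a, b in combinations(nodes, 2):
        if params.block_norm(a, b) <= 1e-8:
            continue
        size = 1
        if a in sl:
            size *= params.cat_levels[a]
        if b in sl:
            size *= params.cat_levels[b]
        df += size
    return 2.0 * data.n_samples * fval + df * np.log(data.n_samples)


def select_lambda(
    data: MixedDataset,
    grid: list[float],
    method: str = "bic",
    subsample_ratio: float = 0.75,
    n_subsamples: int = 20,
    seed: int = 0,
    instability_target: float = 0.05,
) -> float:
    """Regularization selection over an ascending grid.

    ``bic`` minimizes the pseudolikelihood BIC of the full-data path.
    ``stars`` computes per-pair selection frequencies over subsample fits and
    picks the smallest lambda whose (sparse-side monotonized) edge instability
    2·p̂·(1−p̂) averaged over pairs stays ≤ the target.
    """
    if not grid:
        raise ValueError("empty lambda grid")
    grid = [float(g) for g in grid]
    if grid != sorted(grid):
        raise ValueError("grid must be ascending")
    if len(grid) == 1:
        return grid[0]
    if method == "bic":
        best, best_bic, warm = grid[0], np.inf, None
        for lam in reversed(grid):  # sparse → dense with warm starts
            warm = mgm_fit(data, lam, warm_start=warm)
            bic = _pseudo_bic(data, warm)
            if bic < best_bic - 1e-9:
                best, best_bic = lam, bic
        return best
    if method != "stars":
        raise ValueError(f"unknown selection method {method!r}")
    if n_subsamples < 5:
        raise ValueError("stars needs at least 5 subsamples")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 21]))
    nodes = sorted(data.names)
    pairs = list(combinations(nodes, 2))
    counts = np.zeros((len(grid), len(pairs)))
    b = max(10, int(round(subsample_ratio * data.n_samples)))
    for _ in range(n_subsamples):
        idx = rng.choice(data.n_samples, size=min(b, data.n_samples), replace=False)
        sub = MixedDataset(data.values.iloc[idx].reset_index(drop=True), list(data.meta))
        warm = None
        for gi in range(len(grid) - 1, -1, -1):
            warm = mgm_fit(sub, grid[gi], warm_start=warm)
            skel = mgm_skeleton(warm)
            for pi, (a, c) in enumerate(pairs):
                if skel.is_adjacent(a, c):
                    counts[gi, pi] += 1
    phat = counts / n_subsamples
    instability = (2 * phat * (1 - phat)).mean(axis=1)
    monotone = np.maximum.accumulate(instability[::-1])[::-1]  # sup over sparser lambdas
    ok = np.where(monotone <= instability_target)[0]
    return grid[int(ok[0])] if len(ok) else grid[-1]
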