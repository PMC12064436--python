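"""Mixed-data conditional-independence tests with FDR correction.

The test of a ⫫ b | S is a nested-model comparison chosen by the target's
type: an exact F-test between nested linear models for a continuous target,
and a chi-square likelihood-ratio test between nested multinomial-logistic
models for a categorical target.  The statistic is symmetrized by testing in
both directions and keeping the larger p-value (conservative).  Batches of
tests are corrected by Benjamini–Hochberg; the independence decision is
``adjusted_p > alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._glm import fit_mnlogit
from .data import MixedDataset, one_hot
from .graphs import GroundTruthGraph, dsep_oracle


@dataclass(frozen=True)
class CITestResult:
    pair: tuple[str, str]  # lexicographically ordered
    cond_set: frozenset[str]
    statistic: float
    dof: int
    p_value: float
    adjusted_p: float | None = None
    testable: bool = True

    def __post_init__(self) -> None:
        if self.pair[0] in self.cond_set or self.pair[1] in self.cond_set:
            raise ValueError("conditioning set must exclude the tested pair")


def fdr_adjust(results: list[CITestResult], alpha: float = 0.05) -> list[CITestResult]:
    """Benjamini–Hochberg step-up over the batch; sets ``adjusted_p``."""
    if not results:
        raise ValueError("empty batch")
    pvals = np.array([r.p_value for r in results])
    _, adjusted, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return [replace(r, adjusted_p=float(q)) for r, q in zip(results, adjusted)]


class DataCI:
    """Dataset-backed CI provider.

    Heavily cached for the discovery loops: continuous-target F-tests are
    solved from the precomputed Gram matrix of the full design (cost is
    independent of n per query), and multinomial log-likelihoods are cached by
    (target, predictor set) with warm-started Newton refits, so nested nulls
    are shared across queries.
    """

    def __init__(self, data: MixedDataset, cat_test: str = "score"):
        if not data.is_complete():
            raise ValueError("CI tests need complete (imputed) data")
        if cat_test not in ("score", "lr"):
            raise ValueError(f"unknown categorical test {cat_test!r}")
        self.cat_test = cat_test
        self.data = data
        self.n = data.n_samples
        self._features: dict[str, np.ndarray] = {}
        self._targets: dict[str, tuple[np.ndarray, bool, int]] = {}
        self._cols: dict[str, np.ndarray] = {}
        blocks = [np.ones((self.n, 1))]
        start = 1
        for m in data.meta:
            col = data.values[m.name].to_numpy()
            if m.is_categorical:
                feats = one_hot(col, m.n_levels)[:, 1:]
                self._targets[m.name] = (col.astype(int), True, m.n_levels)
            else:
                feats = col[:, None]
                self._targets[m.name] = (col, False, 0)
            self._features[m.name] = feats
            blocks.append(feats)
            self._cols[m.name] = np.arange(start, start + feats.shape[1])
            start += feats.shape[1]
        design = np.hstack(blocks)
        self._gram = design.T @ design
        self._cache: dict[tuple[tuple[str, str], frozenset[str]], CITestResult] = {}
        self._ll_cache: dict[tuple[str, frozenset[str]], tuple] = {}
        self._xmat_cache: dict[tuple[str, ...], np.ndarray] = {}
        # per categorical target: (codes remapped to observed levels, levels,
        # one-hot indicator of the remapped codes)
        self._encoded: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for m in data.meta:
            if m.is_categorical:
                y = self._targets[m.name][0]
                present = np.unique(y)
                remap = {lvl: i for i, lvl in enumerate(present)}
                yy = np.array([remap[v] for v in y])
                ind = np.zeros((self.n, len(present)))
                ind[np.arange(self.n), yy] = 1.0
                self._encoded[m.name] = (yy, present, ind)

    # -- nested-model tests -------------------------------------------------
    def _xmat(self, names: list[str]) -> np.ndarray:
        key = tuple(names)
        if key not in self._xmat_cache:
            if not names:
                self._xmat_cache[key] = np.empty((self.n, 0))
            else:
                self._xmat_cache[key] = np.hstack([self._features[n] for n in names])
        return self._xmat_cache[key]

    def _rss(self, target: str, predictors: list[str]) -> tuple[float, int]:
        """Residual sum of squares of target ~ intercept + predictors, from the
        Gram matrix; returns (rss, number of design columns incl. intercept)."""
        idx = np.concatenate([[0]] + [self._cols[p] for p in predictors]).astype(int)
        yi = self._cols[target]
        gxx = self._gram[np.ix_(idx, idx)]
        gxy = self._gram[np.ix_(idx, yi)][:, 0]
        gyy = float(self._gram[yi[0], yi[0]])
        jitter = 1e-10 * max(1.0, np.trace(gxx) / len(idx))
        try:
            beta = np.linalg.solve(gxx + jitter * np.eye(len(idx)), gxy)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(gxx, gxy, rcond=None)
        return max(gyy - float(gxy @ beta), 0.0), len(idx)

    def _fit_cat(self, target: str, predictors: frozenset[str]):
        """Cached multinomial fit of target ~ predictors; returns
        (loglik, coef, classes).  Warm-started from a nested cached fit."""
        key = (target, predictors)
        if key in self._ll_cache:
            return self._ll_cache[key]
        y, _, n_levels = self._targets[target]
        plist = sorted(predictors)
        x = self._xmat(plist)
        warm = None
        # warm start from a cached fit on one predictor fewer
        for drop in plist:
            sub = predictors - {drop}
            if (target, sub) in self._ll_cache:
                _, warm_coef, _ = self._ll_cache[(target, sub)]
                if warm_coef.size:
                    beta0 = np.zeros((x.shape[1] + 1, warm_coef.shape[1]))
                    beta0[0] = warm_coef[0]
                    r_new, r_old = 1, 1
                    for p in plist:
                        width = self._features[p].shape[1]
                        if p != drop:
                            beta0[r_new : r_new + width] = warm_coef[r_old : r_old + width]
                            r_old += width
                        r_new += width
                    warm = beta0
                break
        yy, present, _ = self._encoded[target]
        ll, coef, classes = fit_mnlogit(x, y, n_levels, warm_start=warm, pre_encoded=(yy, present))
        self._ll_cache[key] = (ll, coef, classes)
        return ll, coef, classes

    def _score_test_cat(self, target: str, added: str, s: list[str]) -> tuple[float, int, float]:
        """Rao score test for adding ``added`` to the multinomial model
        target ~ s: needs only the cached null fit."""
        y, _, n_levels = self._targets[target]
        _, coef, classes = self._fit_cat(target, frozenset(s))
        lp = len(classes)
        if lp < 2:
            return 0.0, 0, 1.0
        from ._glm import add_intercept, mnlogit_probs

        x0 = self._xmat(sorted(s))
        w = self._features[added]
        probs = mnlogit_probs(x0, coef)
        _, _, ind = self._encoded[target]
        resid = ind[:, 1:] - probs[:, 1:]  # n × m
        x1 = np.hstack([add_intercept(x0), w])
        k1 = x1.shape[1]
        q = w.shape[1]
        m = lp - 1
        u = (w.T @ resid).ravel(order="F")  # q*m score vector
        info = np.empty((k1 * m, k1 * m))
        for a in range(m):
            pa = probs[:, a + 1]
            for b in range(a, m):
                pb = probs[:, b + 1]
                wt = pa * ((1.0 if a == b else 0.0) - pb)
                blk = x1.T @ (x1 * wt[:, None])
                info[a * k1 : (a + 1) * k1, b * k1 : (b + 1) * k1] = blk
                if b != a:
                    info[b * k1 : (b + 1) * k1, a * k1 : (a + 1) * k1] = blk
        w_rows = np.concatenate([np.arange(a * k1 + k1 - q, (a + 1) * k1) for a in range(m)])
        r_rows = np.setdiff1d(np.arange(k1 * m), w_rows)
        i_ww = info[np.ix_(w_rows, w_rows)]
        i_wr = info[np.ix_(w_rows, r_rows)]
        i_rr = info[np.ix_(r_rows, r_rows)]
        jit = 1e-8 * np.eye(len(r_rows))
        cond_info = i_ww - i_wr @ np.linalg.solve(i_rr + jit, i_wr.T)
        try:
            stat = float(u @ np.linalg.solve(cond_info + 1e-8 * np.eye(len(u)), u))
        except np.linalg.LinAlgError:
            return np.inf, q * m, 0.0
        stat = max(stat, 0.0)
        dof = q * m
        return stat, dof, float(stats.chi2.sf(stat, dof))

    def _test_direction(self, target: str, added: str, s: list[str]) -> tuple[float, int, float, bool]:
        y, is_cat, n_levels = self._targets[target]
        q = self._features[added].shape[1]
        if is_cat:
            k1 = 1 + sum(self._features[p].shape[1] for p in s) + q
            resid_dof = self.n - k1 * (n_levels - 1)
            if resid_dof <= 0:
                return np.inf, 0, 0.0, False
            if self.cat_test == "score":
                stat, dof, p = self._score_test_cat(target, added, sorted(s))
                return stat, dof, p, True
            ll0, _, classes = self._fit_cat(target, frozenset(s))
            ll1, _, _ = self._fit_cat(target, frozenset(s) | {added})
            dof = q * (len(classes) - 1)
            if dof == 0:
                return 0.0, 0, 1.0, True
            lr = max(0.0, 2.0 * (ll1 - ll0))
            return lr, dof, float(stats.chi2.sf(lr, dof)), True
        rss0, _ = self._rss(target, sorted(s))
        rss1, k1 = self._rss(target, sorted(s) + [added])
        resid_dof = self.n - k1
        if resid_dof <= 0:
            return np.inf, 0, 0.0, False
        if rss1 <= 1e-12 * max(rss0, 1.0):
            return np.inf, q, 0.0, True
        f = max(0.0, (rss0 - rss1) / q / (rss1 / resid_dof))
        return f, q, float(stats.f.sf(f, q, resid_dof)), True

    def __call__(self, a: str, b: str, s) -> CITestResult:
        if a == b:
            raise ValueError("a and b must differ")
        pair = tuple(sorted((a, b)))
        cond = frozenset(s)
        key = (pair, cond)
        if key in self._cache:
            return self._cache[key]
        slist = sorted(cond)
        a_cat = self._targets[pair[0]][1]
        b_cat = self._targets[pair[1]][1]
        directions = [(pair[1], pair[0])]
        if a_cat or b_cat:  # for two continuous variables both F-tests coincide
            directions.append((pair[0], pair[1]))
        best = None
        for target, added in directions:
            stat, dof, p, ok = self._test_direction(target, added, slist)
            if not ok:
                # untestable → conservatively dependent, flagged
                res = CITestResult(pair, cond, float("nan"), 0, 0.0, testable=False)
                self._cache[key] = res
                return res
            if best is None or p > best[2]:
                best = (stat, dof, p)
        res = CITestResult(pair, cond, best[0], best[1], best[2])
        self._cache[key] = res
        return res


def ci_test(data: MixedDataset, a: str, b: str, s=()) -> CITestResult:
    """One-shot conditional-independence test on a complete dataset.

    Convenience wrapper over :class:`DataCI`; build a ``DataCI`` once when
    running many queries against the same data.
    """
    return DataCI(data)(a, b, s)


class OracleCI:
    """Exact CI provider backed by d-separation in a ground-truth DAG.

    Independence yields p = 1, dependence p = 0, so any alpha in (0, 1)
    recovers the oracle's verdicts and the MAX-p separating set is exact.
    """

    def __init__(self, graph: GroundTruthGraph):
        self.graph = graph
        self._cache: dict[tuple[tuple[str, str], frozenset[str]], CITestResult] = {}

    def __call__(self, a: str, b: str, s) -> CITestResult:
        pair = tuple(sorted((a, b)))
        cond = frozenset(s)
        key = (pair, cond)
        if key not in self._cache:
            sep = dsep_oracle(self.graph, pair[0], pair[1], cond)
            self._cache[key] = CITestResult(pair, cond, 0.0, 0, 1.0 if sep else 0.0)
        return self._cache[key]


def write_ci_log(results: list[CITestResult], path, alpha: float = 0.05) -> None:
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tcond_set\tstatistic\tdof\tp_value\tadjusted_p\tdecision\n")
        for r in results:
            q = "" if r.adjusted_p is None else f"{r.adjusted_p:.6g}"
            dec_p = r.adjusted_p if r.adjusted_p is not None else r.p_value
            decision = "independent" if (r.testable and dec_p > alpha) else "dependent"
            fh.write(
                f"{r.pair[0]}\t{r.pair[1]}\t{','.join(sorted(r.cond_set))}\t"
                f"{r.statistic:.6g}\t{r.dof}\t{r.p_value:.6g}\t{q}\t{decision}\n"
            )
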