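"""Internal least-squares and multinomial-logistic fits.

Small, dependency-light model fits tuned for the pipeline's hot loops (CI
tests run thousands of nested fits per dataset).  A tiny ridge term keeps the
multinomial fit finite under quasi-separation; it is orders of magnitude below
the statistical noise of any test built on these likelihoods.
"""

from __future__ import annotations

import numpy as np

_RIDGE = 1e-6


def add_intercept(x: np.ndarray) -> np.ndarray:
    return np.hstack([np.ones((x.shape[0], 1)), x])


def fit_ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS with intercept; returns (coef, residual sum of squares)."""
    xd = add_intercept(x)
    coef, _, _, _ = np.linalg.lstsq(xd, y, rcond=None)
    resid = y - xd @ coef
    return coef, float(resid @ resid)


def fit_mnlogit(
    x: np.ndarray,
    y: np.ndarray,
    n_levels: int,
    max_iter: int = 60,
    tol: float = 1e-9,
    warm_start: np.ndarray | None = None,
    pre_encoded: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Maximum-likelihood multinomial logit (reference class 0) by Newton.

    Levels absent from ``y`` are collapsed away before fitting.  Returns
    ``(loglik, coef, class_map)`` where ``coef`` is (k+1) × (L'-1) for the L'
    observed levels and ``class_map`` maps fitted columns back to level codes.
    """
    y = np.asarray(y, dtype=int)
    if pre_encoded is not None:
        yy, present = pre_encoded
    else:
        present = np.unique(y)
        remap = {lvl: i for i, lvl in enumerate(present)}
        yy = np.array([remap[v] for v in y])
    lp = len(present)
    xd = add_intercept(np.asarray(x, dtype=float))
    n, k = xd.shape
    if lp < 2:
        return 0.0, np.zeros((k, 0)), present
    m = lp - 1
    beta = np.zeros((k, m))
    if warm_start is not None and warm_start.shape == (k, m):
        beta = warm_start.copy()

    def nll(b: np.ndarray) -> tuple[float, np.ndarray]:
        scores = np.hstack([np.zeros((n, 1)), xd @ b])
        scores -= scores.max(axis=1, keepdims=True)
        exps = np.exp(scores)
        probs = exps / exps.sum(axis=1, keepdims=True)
        ll = np.log(probs[np.arange(n), yy] + 1e-300).sum()
        return -ll + 0.5 * _RIDGE * float((b * b).sum()), probs

    ind = np.zeros((n, lp))
    ind[np.arange(n), yy] = 1.0
    val, probs = nll(beta)
    for _ in range(max_iter):
        grad = xd.T @ (probs[:, 1:] - ind[:, 1:]) + _RIDGE * beta  # k × m
        gflat = grad.ravel(order="F")
        if np.linalg.norm(gflat) < tol * n:
            break
        # Hessian blocks H[(a,b)] = X' diag(p_a (δ_ab − p_b)) X
        hess = np.empty((k * m, k * m))
        for a in range(m):
            pa = probs[:, a + 1]
            for b in range(a, m):
                pb = probs[:, b + 1]
                w = pa * ((1.0 if a == b else 0.0) - pb)
                blk = xd.T @ (xd * w[:, None])
                hess[a * k : (a + 1) * k, b * k : (b + 1) * k] = blk
                if b != a:
                    hess[b * k : (b + 1) * k, a * k : (a + 1) * k] = blk
        hess[np.arange(k * m), np.arange(k * m)] += _RIDGE
        try:
            step = np.linalg.solve(hess, gflat).reshape((k, m), order="F")
        except np.linalg.LinAlgError:
            step = gflat.reshape((k, m), order="F") / (np.abs(hess).sum() / (k * m))
        t = 1.0
        for _ in range(30):
            cand = beta - t * step
            new_val, new_probs = nll(cand)
            if new_val <= val + 1e-12:
                beta, val, probs = cand, new_val, new_probs
                break
            t *= 0.5
        else:
            break
    loglik = -(val - 0.5 * _RIDGE * float((beta * beta).sum()))
    return loglik, beta, present


def mnlogit_probs(x: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """Class probabilities over the fitted (observed) levels."""
    xd = add_intercept(np.asarray(x, dtype=float))
    scores = np.hstack([np.zeros((xd.shape[0], 1)), xd @ coef])
    scores -= scores.max(axis=1, keepdims=True)
    exps = np.exp(scores)
    return exps / exps.sum(axis=1, keepdims=True)
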