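"""Missingness QC, standardization, and chained-equations multiple imputation.

Variables whose missing fraction exceeds the QC threshold (0.75 by default in
the pipeline) are dropped; continuous variables are standardized on observed
cells; MICE then produces m completed datasets, each from an independent
seed-derived chain.  The default conditional model is a random forest whose
imputations are drawn from a random terminal-node donor (predictive-mean-
matching-like behaviour); a parametric fallback (linear / multinomial-logistic
with stochastic draws) is available and much faster on large runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from ._glm import fit_mnlogit, fit_ols, mnlogit_probs
from .data import MixedDataset, one_hot

log = logging.getLogger(__name__)

#: Forest defaults: 10 trees with bootstrap resampling, classic mtry = sqrt(p),
#: a 5-observation leaf floor so every terminal node offers a donor pool, and a
#: per-tree subsample cap that keeps tree depth (and fit time) bounded on
#: cohort-sized inputs without touching the donor mechanism.
RF_KWARGS = dict(n_estimators=10, max_features="sqrt", min_samples_leaf=5, bootstrap=True, n_jobs=1)
RF_MAX_TRAIN = 800


@dataclass
class StandardizationParams:
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)


@dataclass
class ImputationSet:
    datasets: list[MixedDataset]
    m: int
    iterations: int
    seed: int
    model: str = "rf"
    visit_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.datasets) != self.m:
            raise ValueError("dataset count must equal m")


def qc_missing_rate(data: MixedDataset, threshold: float) -> MixedDataset:
    """Drop variables whose missing fraction exceeds ``threshold`` (strictly)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    keep, dropped = [], []
    for name in data.names:
        rate = data.missing_fraction(name)
        (dropped if rate > threshold else keep).append((name, rate))
    for name, rate in dropped:
        log.info("QC removed %s (missing rate %.3f > %.2f)", name, rate, threshold)
    if not keep:
        raise ValueError("missing-rate QC removed every variable")
    return data.select([n for n, _ in keep])


def standardize_continuous(data: MixedDataset) -> tuple[MixedDataset, StandardizationParams]:
    """Scale each continuous column to observed mean 0 / SD 1; categorical
    columns are untouched.  Returns the transform for later inversion."""
    values = data.values.copy()
    params = StandardizationParams()
    for name in data.continuous_names:
        obs = values[name].dropna()
        if obs.nunique() < 2:
            raise ValueError(f"continuous column {name!r} is degenerate (constant)")
        mu, sd = float(obs.mean()), float(obs.std(ddof=1))
        params.mean[name], params.sd[name] = mu, sd
        values[name] = (values[name] - mu) / sd
    return data.with_values(values, data.mask.copy()), params


def _design(values: pd.DataFrame, data: MixedDataset, exclude: str) -> np.ndarray:
    """Predictor matrix from all columns except ``exclude``; categorical
    predictors are one-hot encoded (full indicator — trees don't care, and the
    GLMs carry their own intercept so one column is redundant but harmless
    under the ridge safeguard)."""
    blocks = []
    for m in data.meta:
        if m.name == exclude:
            continue
        col = values[m.name].to_numpy()
        if m.is_categorical:
            blocks.append(one_hot(col, m.n_levels)[:, 1:])
        else:
            blocks.append(col[:, None])
    return np.hstack(blocks) if blocks else np.empty((len(values), 0))


def _rf_donor_draw(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_miss: np.ndarray,
    categorical: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Fit a forest and impute each missing row from a random donor in the
    terminal node of a randomly chosen tree."""
    cls = RandomForestClassifier if categorical else RandomForestRegressor
    max_samples = None if len(y_train) <= RF_MAX_TRAIN else RF_MAX_TRAIN
    rf = cls(random_state=int(rng.integers(2**31 - 1)), max_samples=max_samples, **RF_KWARGS)
    rf.fit(x_train, y_train.astype(int) if categorical else y_train)
    leaves_train = rf.apply(x_train)  # n_train × n_trees
    leaves_miss = rf.apply(x_miss)
    n_trees = leaves_train.shape[1]
    tree_pick = rng.integers(n_trees, size=len(x_miss))
    out = np.empty(len(x_miss))
    for t in range(n_trees):
        rows = np.where(tree_pick == t)[0]
        if not len(rows):
            continue
        order = np.argsort(leaves_train[:, t], kind="stable")
        sorted_leaves = leaves_train[order, t]
        for i in rows:
            leaf = leaves_miss[i, t]
            lo = np.searchsorted(sorted_leaves, leaf, side="left")
            hi = np.searchsorted(sorted_leaves, leaf, side="right")
            donor = order[rng.integers(lo, hi)] if hi > lo else rng.integers(len(y_train))
            out[i] = y_train[donor]
    return out


def _parametric_draw(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_miss: np.ndarray,
    categorical: bool,
    n_levels: int,
    rng: np.random.Generator,
) -> np.ndarray:
    from ._glm import add_intercept

    if categorical:
        _, coef, classes = fit_mnlogit(x_train, y_train, n_levels)
        if coef.shape[1] == 0:
            return np.full(len(x_miss), classes[0], dtype=float)
        probs = mnlogit_probs(x_miss, coef)
        u = rng.random(len(x_miss))
        idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        return classes[np.minimum(idx, len(classes) - 1)].astype(float)
    coef, rss = fit_ols(x_train, y_train)
    dof = max(len(y_train) - len(coef), 1)
    sigma = np.sqrt(rss / dof)
    return add_intercept(x_miss) @ coef + rng.normal(0.0, sigma, size=len(x_miss))


def mice_impute(
    data: MixedDataset,
    m: int,
    iterations: int = 5,
    model: str = "rf",
    seed: int = 0,
    exclude: tuple[str, ...] = (),
) -> ImputationSet:
    """Multiple imputation by chained equations.

    Variables are visited in decreasing-missingness order each iteration; each
    chain starts from marginal random draws and runs independently from a
    (seed, chain-index) stream, so results are reproducible regardless of
    execution order.  Variables in ``exclude`` are used as predictors but never
    imputed (they must be complete).
    """
    if m < 1 or iterations < 1:
        raise ValueError("m and iterations must be >= 1")
    if model not in ("rf", "parametric"):
        raise ValueError(f"unknown imputation model {model!r}")
    for name in data.names:
        if data.mask[name].all():
            raise ValueError(f"variable {name!r} has no observed values — QC first")
    for name in exclude:
        if data.missing_fraction(name) > 0:
            raise ValueError(f"excluded variable {name!r} has missing cells")

    incomplete = [n for n in data.names if data.missing_fraction(n) > 0 and n not in exclude]
    visit = sorted(incomplete, key=lambda n: (-data.missing_fraction(n), n))
    datasets = []
    for chain in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11, chain]))
        values = data.values.copy()
        # initial fill: marginal draws from observed cells
        for name in incomplete:
            miss = data.mask[name].to_numpy()
            obs_vals = data.values[name].dropna().to_numpy()
            values.loc[miss, name] = rng.choice(obs_vals, size=int(miss.sum()), replace=True)
        if visit:
            for _ in range(iterations):
                for name in visit:
                    miss = data.mask[name].to_numpy()
                    x_all = _design(values, data, exclude=name)
                    y_obs = data.values[name].to_numpy()[~miss]
                    meta = data.meta_for(name)
                    draw = _rf_donor_draw if model == "rf" else _parametric_draw
                    kwargs = {} if model == "rf" else {"n_levels": meta.n_levels}
                    values.loc[miss, name] = draw(
                        x_all[~miss], y_obs, x_all[miss], meta.is_categorical, rng=rng, **kwargs
                    )
        completed = MixedDataset(values, list(data.meta), mask=pd.DataFrame(False, index=values.index, columns=values.columns))
        datasets.append(completed)
    return ImputationSet(datasets=datasets, m=m, iterations=iterations, seed=seed, model=model, visit_order=visit)
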