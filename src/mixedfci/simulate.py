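"""Synthetic cohort generator.

Emulates a baseline epidemiological cohort: a tiered causal DAG with latent
confounders, mixed continuous/categorical variables generated by
linear-Gaussian and multinomial-logistic mechanisms, a rare-ish 3-level
outcome (none / diagnosed late / diagnosed early), MCAR or MAR missingness up
to high per-variable rates, and a free-text variable dictionary whose labels
are built from risk-factor category lexicons so the embedding-based selection
stage can be scored against a gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CATEGORICAL, CONTINUOUS, MixedDataset, VariableMeta
from .graphs import LATENT, OBSERVED, GroundTruthGraph

AGE = "age"
SEX = "sex"
OUTCOME = "dementia"
OUTCOME_LEVELS = 3  # none / diagnosed >2y / diagnosed <=2y post-baseline

#: Small controlled lexicon of risk-factor categories.  Labels for synthetic
#: variables are drawn from these word lists; "none" is the decoy category.
DEFAULT_LEXICON: dict[str, list[str]] = {
    "smoking": ["smoking", "cigarette", "tobacco", "smoker", "nicotine"],
    "alcohol": ["alcohol", "drinking", "wine", "beer", "spirits"],
    "diet": ["diet", "vegetable", "fruit", "nutrition", "intake"],
    "physical activity": ["exercise", "walking", "physical", "activity", "sport"],
    "sleep": ["sleep", "insomnia", "snoring", "nap", "sleeplessness"],
    "hearing loss": ["hearing", "deafness", "tinnitus", "audiometry"],
    "diabetes": ["diabetes", "glucose", "insulin", "glycated", "hba1c"],
    "hypertension": ["hypertension", "blood", "pressure", "systolic", "diastolic"],
    "cholesterol": ["cholesterol", "lipid", "ldl", "hdl", "statin"],
    "depression": ["depression", "mood", "sadness", "antidepressant"],
    "social engagement": ["social", "friends", "loneliness", "visits"],
    "education": ["education", "qualification", "school", "degree"],
    "none": ["questionnaire", "assessment", "device", "date", "centre"],
}

#: Filler tokens mixed into every label; none of them belong to any category.
FILLER_TOKENS = [
    "ever",
    "usual",
    "frequency",
    "self",
    "reported",
    "baseline",
    "measure",
    "status",
    "level",
    "history",
]


@dataclass
class StructuralParams:
    """Mechanisms attached to a ground-truth graph.

    ``edge_weights`` hold the linear coefficient of each edge (used directly
    for continuous children and as the scale of the per-level coefficient
    vector for categorical children).  ``categorical_mechanisms[child]`` maps
    each parent to a per-level coefficient vector, plus an ``"_intercept"``
    entry.  ``noise_sd`` is the Gaussian noise SD of each continuous node.
    """

    edge_weights: dict[tuple[str, str], float]
    categorical_mechanisms: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)

    def validate(self, graph: GroundTruthGraph) -> None:
        for e in graph.edges:
            u, v = e
            if graph.node_types.get(v, 0) >= 2:
                if v not in self.categorical_mechanisms or u not in self.categorical_mechanisms[v]:
                    raise ValueError(f"missing categorical mechanism for edge {e}")
            elif e not in self.edge_weights:
                raise ValueError(f"missing weight for edge {e}")
        for n, sd in self.noise_sd.items():
            if sd <= 0:
                raise ValueError(f"noise_sd for {n} must be positive")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def generate_ground_truth(
    n_observed: int,
    n_latent: int,
    expected_degree: float,
    n_tiers: int,
    seed: int,
    frac_categorical: float = 0.25,
    min_outcome_parents: int = 0,
) -> GroundTruthGraph:
    """Random tiered DAG with pure-confounder latents.

    Tier 0 is exogenous and holds the age and sex analogues; the outcome sits
    alone in the last tier.  Edges are sampled forwards along a fixed
    tier-consistent order with probability calibrated to the requested
    expected degree; no edges run within tier 0 or into it.  Each latent picks
    two or more observed children outside tier 0.
    """
    if n_observed < 3:
        raise ValueError("need at least 3 observed nodes (age, sex, outcome)")
    if n_tiers < 2:
        raise ValueError("need at least 2 tiers")
    if n_latent >= n_observed:
        raise ValueError("n_latent must be smaller than n_observed")

    rng = _rng(seed, 0)
    n_middle = n_observed - 3
    width = max(1, len(str(max(n_middle, 1))))
    middle = [f"x{i + 1:0{width}d}" for i in range(n_middle)]
    nodes = [AGE, SEX, *middle, OUTCOME]

    tiers = {AGE: 0, SEX: 0, OUTCOME: n_tiers - 1}
    middle_tiers = list(range(1, n_tiers - 1)) or [0]
    for m in middle:
        tiers[m] = int(rng.choice(middle_tiers))

    node_types = {AGE: 0, SEX: 2, OUTCOME: OUTCOME_LEVELS}
    for m in middle:
        if rng.random() < frac_categorical:
            node_types[m] = int(rng.choice([2, 2, 3]))
        else:
            node_types[m] = 0

    categories = {AGE: "none", SEX: "none", OUTCOME: "none"}
    cat_names = [c for c in DEFAULT_LEXICON if c != "none"]
    for i, m in enumerate(middle):
        # roughly one decoy in five; the rest cycle through the lexicon
        if rng.random() < 0.2:
            categories[m] = "none"
        else:
            categories[m] = cat_names[i % len(cat_names)]

    order = sorted(nodes, key=lambda n: (tiers[n], n))
    allowed = []
    for i, u in enumerate(order):
        for v in order[i + 1 :]:
            if tiers[v] == 0:  # exogenous tier takes no edges at all
                continue
            if tiers[u] <= tiers[v]:
                allowed.append((u, v))
    p_edge = 0.0
    if allowed and expected_degree > 0:
        p_edge = min(1.0, expected_degree * n_observed / (2.0 * len(allowed)))
    edges = [e for e in allowed if rng.random() < p_edge]

    outcome_parents = [u for u, v in edges if v == OUTCOME]
    if len(outcome_parents) < min_outcome_parents:
        candidates = [u for u in order if u != OUTCOME and u not in outcome_parents]
        extra = rng.choice(
            len(candidates), size=min_outcome_parents - len(outcome_parents), replace=False
        )
        edges.extend((candidates[i], OUTCOME) for i in sorted(extra))

    roles = {n: OBSERVED for n in nodes}
    latent_targets = [n for n in middle + [OUTCOME] if tiers[n] > 0]
    if n_latent > 0 and len(latent_targets) < 2:
        raise ValueError("not enough non-exogenous observed nodes for latent confounders")
    latents = []
    for j in range(n_latent):
        name = f"u{j + 1}"
        kids = rng.choice(len(latent_targets), size=2, replace=False)
        kids = [latent_targets[k] for k in sorted(kids)]
        latents.append(name)
        roles[name] = LATENT
        node_types[name] = 0
        categories[name] = "none"
        tiers[name] = min(tiers[k] for k in kids)
        edges.extend((name, k) for k in kids)

    return GroundTruthGraph(
        nodes=nodes + latents,
        roles=roles,
        edges=sorted(edges),
        tiers=tiers,
        outcome=OUTCOME,
        node_types=node_types,
        categories=categories,
    )


def make_structural_params(
    graph: GroundTruthGraph,
    seed: int,
    weight_range: tuple[float, float] = (0.4, 0.9),
    noise_sd: float = 1.0,
    outcome_intercepts: tuple[float, ...] | None = None,
) -> StructuralParams:
    """Draw mechanisms: edge weights uniform on ±[lo, hi], centred per-level
    coefficient patterns for categorical children, unit Gaussian noise.

    Weights in ±[0.4, 0.9] keep effects detectable at cohort sizes of a few
    thousand without being near-deterministic.
    """
    rng = _rng(seed, 1)
    lo, hi = weight_range
    weights: dict[tuple[str, str], float] = {}
    cat_mech: dict[str, dict[str, np.ndarray]] = {}
    noise: dict[str, float] = {}

    for n in graph.nodes:
        levels = graph.node_types.get(n, 0)
        if levels >= 2:
            icpt = np.zeros(levels)
            if n == graph.outcome:
                icpt = np.array(outcome_intercepts) if outcome_intercepts else np.array([1.0, 0.0, -0.5])
            cat_mech[n] = {"_intercept": icpt}
        else:
            noise[n] = noise_sd

    for u, v in graph.edges:
        w = float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))
        weights[(u, v)] = w
        levels = graph.node_types.get(v, 0)
        if levels >= 2:
            pattern = rng.normal(size=levels)
            pattern -= pattern.mean()
            norm = np.linalg.norm(pattern)
            if norm > 0:
                pattern = pattern / norm * np.sqrt(levels)
            cat_mech[v][u] = w * pattern
    params = StructuralParams(edge_weights=weights, categorical_mechanisms=cat_mech, noise_sd=noise)
    params.validate(graph)
    return params


def _parent_signal(graph: GroundTruthGraph, parent: str, column: np.ndarray) -> np.ndarray:
    """Numeric contribution of a parent: identity for continuous, centred
    linear level scores for categorical parents."""
    levels = graph.node_types.get(parent, 0)
    if levels < 2:
        return column
    centre = (levels - 1) / 2.0
    scale = max(centre, 1.0)
    return (column - centre) / scale


def sample_dataset(
    graph: GroundTruthGraph,
    params: StructuralParams,
    n_samples: int,
    seed: int,
) -> MixedDataset:
    """Ancestral sampling in topological order.

    Continuous nodes are linear in their parents' signals plus Gaussian noise;
    categorical nodes are multinomial-logistic in them.  Latent columns are
    generated but dropped from the returned table.
    """
    params.validate(graph)
    rng = _rng(seed, 2)
    cols: dict[str, np.ndarray] = {}
    for node in graph.topological_order():
        parents = graph.parents(node)
        levels = graph.node_types.get(node, 0)
        if levels >= 2:
            mech = params.categorical_mechanisms[node]
            logits = np.tile(mech["_intercept"], (n_samples, 1))
            for p in parents:
                sig = _parent_signal(graph, p, cols[p])
                logits = logits + np.outer(sig, mech[p])
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(n_samples)
            cols[node] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(float)
        else:
            val = rng.normal(0.0, params.noise_sd[node], size=n_samples)
            for p in parents:
                val = val + params.edge_weights[(p, node)] * _parent_signal(graph, p, cols[p])
            cols[node] = val

    obs = graph.observed_nodes
    values = pd.DataFrame({n: cols[n] for n in obs}, columns=obs)
    meta = [
        VariableMeta(
            name=n,
            label=n,
            vtype=CATEGORICAL if graph.node_types.get(n, 0) >= 2 else CONTINUOUS,
            n_levels=graph.node_types.get(n, 0),
            category=graph.categories.get(n),
        )
        for n in obs
    ]
    return MixedDataset(values, meta)


def inject_missingness(
    data: MixedDataset,
    rates: dict[str, float],
    mechanism: str = "mcar",
    driver: str | None = None,
    seed: int = 0,
) -> MixedDataset:
    """Blank out cells at the requested per-variable rates.

    ``mechanism="mcar"`` draws independent Bernoulli masks.  ``mechanism="mar"``
    makes the missingness probability increase across quartiles of a fully
    observed driver variable (quartile multipliers 0.4/0.8/1.2/1.6 around the
    requested mean rate).
    """
    for name, r in rates.items():
        if not 0.0 <= r < 1.0:
            raise ValueError(f"rate for {name} must lie in [0, 1)")
        if name not in data.names:
            raise KeyError(f"unknown variable {name!r}")
    if mechanism not in ("mcar", "mar"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if mechanism == "mar":
        if driver is None or driver not in data.names:
            raise ValueError("MAR needs a driver variable present in the data")
        if data.missing_fraction(driver) > 0:
            raise ValueError("MAR driver must be fully observed")
        dcol = data.values[driver].to_numpy()
        quart = np.searchsorted(np.quantile(dcol, [0.25, 0.5, 0.75]), dcol, side="right")
        multipliers = np.array([0.4, 0.8, 1.2, 1.6])

    rng = _rng(seed, 3)
    mask = data.mask.copy()
    out_meta = list(data.meta)
    for name in data.names:
        r = rates.get(name, 0.0)
        if r == 0.0:
            continue
        if mechanism == "mcar":
            p = np.full(data.n_samples, r)
        else:
            p = np.minimum(r * multipliers[quart], 0.99)
        hit = rng.random(data.n_samples) < p
        mask[name] = mask[name] | hit
    ds = MixedDataset(data.values.copy(), out_meta, mask)
    for name in data.names:
        ds.update_meta(name, missing_rate=ds.missing_fraction(name))
    return ds


def generate_variable_dictionary(
    graph: GroundTruthGraph,
    lexicon: dict[str, list[str]] | None = None,
    seed: int = 0,
    n_category_words: int = 2,
    n_fillers: int = 2,
) -> list[VariableMeta]:
    """Free-text labels for every observed node, built from its gold category's
    lexicon words plus neutral filler tokens (decoys draw from the "none" list)."""
    lexicon = dict(lexicon or DEFAULT_LEXICON)
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    if "none" not in lexicon:
        raise ValueError('lexicon must include a "none" decoy category')
    rng = _rng(seed, 4)
    meta = []
    for n in graph.observed_nodes:
        cat = graph.categories.get(n, "none")
        if cat not in lexicon:
            raise ValueError(f"category {cat!r} missing from lexicon")
        words = list(lexicon[cat])
        k = min(n_category_words, len(words))
        chosen = [words[i] for i in sorted(rng.choice(len(words), size=k, replace=False))]
        fillers = [FILLER_TOKENS[i] for i in sorted(rng.choice(len(FILLER_TOKENS), size=n_fillers, replace=False))]
        label_tokens = chosen + fillers
        rng.shuffle(label_tokens)
        levels = graph.node_types.get(n, 0)
        meta.append(
            VariableMeta(
                name=n,
                label=" ".join(label_tokens),
                vtype=CATEGORICAL if levels >= 2 else CONTINUOUS,
                n_levels=levels,
                category=None if cat == "none" else cat,
            )
        )
    return meta
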