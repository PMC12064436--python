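"""End-to-end orchestration: simulate → select → QC/impute → per-imputation
MGM skeleton + FCI-MAX → pool → report.

The configuration is a plain nested dict (YAML/JSON-friendly) validated
strictly against the known schema; every stage draws its randomness from the
single top-level seed through per-operation streams, so a re-run with the same
config is bit-identical.  Each per-imputation discovery is independent of
execution order.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import textsel
from .citest import DataCI
from .data import MixedDataset, VariableMeta, write_dictionary_tsv
from .fci import Knowledge, fci_max
from .graphs import GroundTruthGraph
from .impute import ImputationSet, mice_impute, qc_missing_rate, standardize_continuous
from .mgm import Skeleton, mgm_fit, mgm_skeleton, select_lambda
from .pag import PAG, write_pag_tsv
from .pooling import PooledNetwork, RecoveryReport, compare_to_truth, extract_outcome_subnetwork, pool_pags
from .simulate import (
    DEFAULT_LEXICON,
    generate_ground_truth,
    generate_variable_dictionary,
    inject_missingness,
    make_structural_params,
    sample_dataset,
)

_SCHEMA: dict[str, dict] = {
    "seed": None,
    "outdir": None,
    "simulation": {
        "n_observed": 30,
        "n_latent": 3,
        "expected_degree": 2.0,
        "n_tiers": 3,
        "n_samples": 3000,
        "frac_categorical": 0.2,
        "min_outcome_parents": 2,
        "missing_rate": 0.2,
        "missing_mechanism": "mcar",
        "missing_driver": None,
    },
    "selection": {
        "enabled": True,
        "threshold": 0.6,
        "combine": "any",
        "top_k": None,
        "phrases": None,  # default: lexicon categories
    },
    "imputation": {
        "qc_threshold": 0.75,
        "m": 50,
        "iterations": 5,
        "model": "rf",
        "standardize_first": True,
    },
    "skeleton": {
        "enabled": True,
        "lam": 0.15,
        "grid": None,
        "method": "bic",
    },
    "discovery": {
        "alpha": 0.05,
        "max_cond_size": 3,
        "pdsep": True,
        "pdsep_pool_cap": 8,
    },
    "pooling": {
        "thresholds": [0.3, 0.5, 1.0],
        "mode": "marks",
        "subnetwork_max_steps": 2,
    },
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int
    outdir: str | None = None
    simulation: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    imputation: dict = field(default_factory=dict)
    skeleton: dict = field(default_factory=dict)
    discovery: dict = field(default_factory=dict)
    pooling: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("config requires a seed")
        blocks = {}
        for key, defaults in _SCHEMA.items():
            if defaults is None:
                continue
            block = dict(defaults)
            extra = set(raw.get(key, {})) - set(defaults)
            if extra:
                raise ConfigError(f"unknown key(s) in {key!r}: {sorted(extra)}")
            block.update(raw.get(key, {}))
            blocks[key] = block
        cfg = cls(seed=int(raw["seed"]), outdir=raw.get("outdir"), **blocks)
        pool = cfg.pooling["thresholds"]
        if any(not 0.0 < t <= 1.0 for t in pool):
            raise ConfigError("pooling thresholds must lie in (0, 1]")
        if cfg.imputation["m"] < 1:
            raise ConfigError("imputation m must be >= 1")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "simulation": self.simulation,
            "selection": self.selection,
            "imputation": self.imputation,
            "skeleton": self.skeleton,
            "discovery": self.discovery,
            "pooling": self.pooling,
        }


@dataclass
class PipelineResult:
    config: PipelineConfig
    graph: GroundTruthGraph | None
    dictionary: list[VariableMeta]
    selection_results: list
    selection_report: object | None
    analysis_variables: list[str]
    imputations: ImputationSet
    skeletons: list[Skeleton]
    pags: list[PAG]
    pooled: PooledNetwork
    subnetworks: dict[float, PooledNetwork]
    recovery: dict[float, RecoveryReport]
    manifest: dict

    def report_text(self) -> str:
        return write_report(self)


def _manifest(config: PipelineConfig, counts: dict) -> dict:
    blob = json.dumps(config.to_dict(), sort_keys=True)
    versions = {"python": sys.version.split()[0], "numpy": np.__version__}
    from . import __version__

    versions["mixedfci"] = __version__
    return {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        "versions": versions,
        "counts": counts,
    }


def run_pipeline(
    config: PipelineConfig,
    dataset: MixedDataset | None = None,
    dictionary: list[VariableMeta] | None = None,
    graph: GroundTruthGraph | None = None,
) -> PipelineResult:
    """Execute all stages.  When ``dataset`` is given the simulation stage is
    skipped and ground-truth-based recovery reports are only produced if
    ``graph`` is also supplied."""
    seed = config.seed
    sim = config.simulation

    # -- stage 1: simulate -------------------------------------------------
    if dataset is None:
        graph = generate_ground_truth(
            n_observed=sim["n_observed"],
            n_latent=sim["n_latent"],
            expected_degree=sim["expected_degree"],
            n_tiers=sim["n_tiers"],
            seed=seed,
            frac_categorical=sim["frac_categorical"],
            min_outcome_parents=sim["min_outcome_parents"],
        )
        params = make_structural_params(graph, seed=seed)
        dataset = sample_dataset(graph, params, sim["n_samples"], seed=seed)
        rates = {
            n: sim["missing_rate"]
            for n in dataset.names
            if n not in (graph.outcome, "age", "sex")
        }
        dataset = inject_missingness(
            dataset,
            rates,
            mechanism=sim["missing_mechanism"],
            driver=sim["missing_driver"],
            seed=seed,
        )
        dictionary = generate_variable_dictionary(graph, DEFAULT_LEXICON, seed=seed)
    elif dictionary is None:
        dictionary = list(dataset.meta)
    outcome = graph.outcome if graph is not None else dataset.names[-1]

    # -- stage 2: embedding-based selection --------------------------------
    sel = config.selection
    results, report = [], None
    keep = list(dataset.names)
    if sel["enabled"]:
        phrases = sel["phrases"] or [c for c in DEFAULT_LEXICON if c != "none"]
        vocab = sorted({t for mdd in dictionary for t in textsel.preprocess_text(mdd.label)})
        backends = [
            textsel.HashEmbeddingBackend(DEFAULT_LEXICON, extra_vocabulary=vocab),
            textsel.DocHashEmbeddingBackend(DEFAULT_LEXICON, extra_vocabulary=vocab),
        ]
        results = textsel.score_variables(dictionary, phrases, backends)
        rule = (
            textsel.SelectionRule(top_k=sel["top_k"])
            if sel["top_k"]
            else textsel.SelectionRule(threshold=sel["threshold"], combine=sel["combine"])
        )
        results = textsel.select_variables(results, rule)
        gold: dict[str, set[str]] = {}
        for mdd in dictionary:
            if mdd.category:
                gold.setdefault(mdd.category, set()).add(mdd.name)
        if gold:
            report = textsel.evaluate_selection(results, gold)
        selected = {r.variable for r in results if r.selected}
        # age, sex and the outcome are always carried into the analysis
        keep = [n for n in dataset.names if n in selected | {"age", "sex", outcome}]
        dataset = dataset.select(keep)

    # -- stage 3: QC, standardization, imputation ---------------------------
    imp = config.imputation
    dataset = qc_missing_rate(dataset, imp["qc_threshold"])
    if imp["standardize_first"]:
        dataset, _ = standardize_continuous(dataset)
    exclude = tuple(n for n in (outcome,) if n in dataset.names and dataset.missing_fraction(n) == 0)
    imputations = mice_impute(
        dataset, m=imp["m"], iterations=imp["iterations"], model=imp["model"], seed=seed, exclude=exclude
    )

    # -- stage 4+5: per-imputation skeleton + FCI-MAX ------------------------
    tiers = (
        {n: graph.tiers[n] for n in dataset.names}
        if graph is not None
        else {n: (0 if n in ("age", "sex") else 1) for n in dataset.names} | {outcome: 2}
    )
    knowledge = Knowledge(tiers={n: (0 if tiers[n] == 0 else 1) for n in dataset.names} | {outcome: 2}, forbid_all_from={outcome})
    skel_cfg, disc = config.skeleton, config.discovery
    skeletons, pags = [], []
    lam = skel_cfg["lam"]
    if skel_cfg["enabled"] and skel_cfg["grid"]:
        lam = select_lambda(imputations.datasets[0], skel_cfg["grid"], method=skel_cfg["method"], seed=seed)
    for completed in imputations.datasets:
        skeleton = None
        if skel_cfg["enabled"]:
            skeleton = mgm_skeleton(mgm_fit(completed, lam))
            skeletons.append(skeleton)
        ci = DataCI(completed)
        pags.append(
            fci_max(
                ci,
                completed.names,
                initial_skeleton=skeleton,
                knowledge=knowledge,
                alpha=disc["alpha"],
                max_cond_size=disc["max_cond_size"],
                pdsep=disc["pdsep"],
                pdsep_pool_cap=disc["pdsep_pool_cap"],
            )
        )

    # -- stage 6: pooling ----------------------------------------------------
    pool_cfg = config.pooling
    pooled = pool_pags(pags, thresholds=pool_cfg["thresholds"], mode=pool_cfg["mode"])
    subnetworks = {
        t: extract_outcome_subnetwork(pooled, outcome, t, max_steps=pool_cfg["subnetwork_max_steps"])
        for t in pool_cfg["thresholds"]
    }
    recovery = {}
    if graph is not None:
        recovery = {t: compare_to_truth(pooled, graph, t) for t in pool_cfg["thresholds"]}

    counts = {
        "n_variables_analyzed": len(dataset.names),
        "n_selected": report.n_selected if report else len(keep),
        "m": imputations.m,
        "skeleton_edges": [s.n_edges() for s in skeletons],
        "pag_edges": [p.n_edges() for p in pags],
        "pooled_edges_per_threshold": {str(t): len(pooled.view(t)) for t in pool_cfg["thresholds"]},
    }
    result = PipelineResult(
        config=config,
        graph=graph,
        dictionary=dictionary,
        selection_results=results,
        selection_report=report,
        analysis_variables=list(dataset.names),
        imputations=imputations,
        skeletons=skeletons,
        pags=pags,
        pooled=pooled,
        subnetworks=subnetworks,
        recovery=recovery,
        manifest=_manifest(config, counts),
    )
    if config.outdir:
        write_artifacts(result, Path(config.outdir))
    return result


def write_report(result: PipelineResult) -> str:
    """Deterministic human-readable run summary."""
    lines = ["== Causal-network pipeline report =="]
    rep = result.selection_report
    if rep is not None:
        lines.append(
            f"selection: {rep.n_selected} variables selected; category coverage "
            f"{len(rep.covered_categories)}/{len(rep.evaluable_categories)} "
            f"(accuracy {rep.accuracy:.3f})"
        )
    lines.append(f"analysis variables: {len(result.analysis_variables)}")
    lines.append(f"imputations: m={result.imputations.m} (model={result.imputations.model})")
    if result.skeletons:
        sizes = [s.n_edges() for s in result.skeletons]
        lines.append(f"skeleton edges per imputation: {sizes}")
    lines.append(f"PAG edges per imputation: {[p.n_edges() for p in result.pags]}")
    outcome = result.graph.outcome if result.graph is not None else "outcome"
    for t in sorted(result.subnetworks):
        view = result.pooled.view(t)
        lines.append(f"pooled edges at >= {int(round(t * 100))}%: {len(view)}")
        sub = result.subnetworks[t]
        if not sub.records:
            lines.append(f"  outcome subnetwork: no edges at this threshold")
            continue
        direct, mediated = [], []
        for a, b, m1, m2 in sorted(sub.records):
            txt = f"{a} {m1}-{m2} {b} ({sub.records[(a, b, m1, m2)]}/{sub.m})"
            (direct if outcome in (a, b) else mediated).append(txt)
        lines.append(f"  direct influences on {outcome}: " + ("; ".join(direct) or "none"))
        if mediated:
            lines.append(f"  mediated pathways: " + "; ".join(mediated))
    for t, rec in sorted(result.recovery.items()):
        lines.append(
            f"recovery vs truth at >= {int(round(t * 100))}%: precision "
            f"{rec.adjacency_precision:.3f}, recall {rec.adjacency_recall:.3f}, "
            f"orientation accuracy {rec.orientation_accuracy:.3f}"
        )
    return "\n".join(lines) + "\n"


def write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result.graph is not None:
        result.graph.write(outdir / "true_graph_edges.tsv", outdir / "true_graph_meta.json")
    write_dictionary_tsv(result.dictionary, outdir / "dictionary.tsv")
    if result.selection_results:
        textsel.write_scores_tsv(result.selection_results, outdir / "selection_scores.tsv")
    for i, pag in enumerate(result.pags):
        write_pag_tsv(pag, outdir / f"pag_{i:03d}.tsv")
    result.pooled.write_tsv(outdir / "pooled_network.tsv")
    for t, sub in result.subnetworks.items():
        sub.write_tsv(outdir / f"outcome_subnetwork_{int(round(t * 100))}.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(write_report(result))
    if result.recovery:
        with open(outdir / "recovery.json", "w") as fh:
            json.dump({str(t): r.as_dict() for t, r in result.recovery.items()}, fh, indent=1, sort_keys=True)
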