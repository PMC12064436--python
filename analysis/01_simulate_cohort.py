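"""Simulate a baseline cohort with known causal ground truth.

Generates a 20-variable tiered causal graph with 2 latent confounders, draws
n = 2000 participants from linear-Gaussian / multinomial-logistic mechanisms,
injects 20% MCAR missingness on every non-exogenous covariate, and writes the
cohort, the ground-truth graph and the free-text variable dictionary under
results/cohort/.
"""

from pathlib import Path

from mixedfci.data import write_dictionary_tsv
from mixedfci.simulate import (
    DEFAULT_LEXICON,
    generate_ground_truth,
    generate_variable_dictionary,
    inject_missingness,
    make_structural_params,
    sample_dataset,
)

SEED = 20250927
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    graph = generate_ground_truth(
        n_observed=20, n_latent=2, expected_degree=2.0, n_tiers=3,
        seed=SEED, min_outcome_parents=2,
    )
    params = make_structural_params(graph, seed=SEED)
    data = sample_dataset(graph, params, n_samples=2000, seed=SEED)
    rates = {n: 0.2 for n in data.names if n not in ("age", "sex", graph.outcome)}
    data = inject_missingness(data, rates, seed=SEED)
    dictionary = generate_variable_dictionary(graph, DEFAULT_LEXICON, seed=SEED)

    graph.write(OUT / "true_graph_edges.tsv", OUT / "true_graph_meta.json", weights=params.edge_weights)
    data.to_csv(OUT / "cohort.csv")
    write_dictionary_tsv(dictionary, OUT / "dictionary.tsv")

    print(f"cohort: {data.n_samples} participants x {data.n_variables} variables")
    print(f"true graph: {len(graph.edges)} edges, outcome parents: {graph.parents(graph.outcome)}")
    print(f"overall missing fraction: {data.mask.values.mean():.3f}")
    print(f"wrote {OUT}/cohort.csv, true_graph_*.{{tsv,json}}, dictionary.tsv")


if __name__ == "__main__":
    main()
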