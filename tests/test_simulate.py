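"""Synthetic cohort generator: sampling moments, missingness, dictionary."""

import numpy as np
import pytest

from mixedfci.data import CATEGORICAL
from mixedfci.simulate import (
    DEFAULT_LEXICON,
    StructuralParams,
    generate_ground_truth,
    generate_variable_dictionary,
    inject_missingness,
    make_structural_params,
    sample_dataset,
)

from conftest import make_graph


class TestGenerateGroundTruth:
    def test_zero_density_forces_empty_edge_set(self):
        g = generate_ground_truth(3, 0, 0.0, 2, seed=1)
        assert len(g.nodes) == 3 and g.edges == []

    def test_same_seed_reproduces_edge_list(self):
        g1 = generate_ground_truth(10, 2, 2.0, 3, seed=7)
        g2 = generate_ground_truth(10, 2, 2.0, 3, seed=7)
        assert g1.edges == g2.edges and g1.tiers == g2.tiers

    def test_different_seed_changes_structure(self):
        g1 = generate_ground_truth(12, 2, 2.0, 3, seed=7)
        g2 = generate_ground_truth(12, 2, 2.0, 3, seed=8)
        assert g1.edges != g2.edges

    def test_too_many_latents_rejected(self):
        with pytest.raises(ValueError):
            generate_ground_truth(5, 5, 1.0, 3, seed=0)

    def test_min_outcome_parents_enforced(self):
        g = generate_ground_truth(15, 0, 0.5, 3, seed=3, min_outcome_parents=2)
        assert len(g.parents(g.outcome)) >= 2


class TestSampleDataset:
    def test_independent_nodes_are_uncorrelated(self):
        g = make_graph(["A", "B", "C"], [])
        params = make_structural_params(g, seed=0)
        ds = sample_dataset(g, params, 10000, seed=0)
        corr = ds.values.corr().to_numpy()
        off = corr[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.03)

    def test_single_edge_matches_closed_form_correlation(self):
        # weight 1, unit noise both: corr = 1/sqrt(2)
        g = make_graph(["A", "B"], [("A", "B")])
        params = StructuralParams(edge_weights={("A", "B"): 1.0}, noise_sd={"A": 1.0, "B": 1.0})
        ds = sample_dataset(g, params, 20000, seed=1)
        corr = ds.values.corr().loc["A", "B"]
        assert abs(corr - 1 / np.sqrt(2)) < 0.02

    def test_zero_samples_keeps_metadata(self):
        g = generate_ground_truth(6, 0, 1.0, 3, seed=2)
        params = make_structural_params(g, seed=2)
        ds = sample_dataset(g, params, 0, seed=2)
        assert ds.n_samples == 0 and ds.names == g.observed_nodes

    def test_latent_columns_not_returned(self):
        g = generate_ground_truth(8, 2, 1.5, 3, seed=4)
        ds = sample_dataset(g, make_structural_params(g, seed=4), 50, seed=4)
        assert set(ds.names) == set(g.observed_nodes)

    def test_categorical_outcome_has_three_levels(self):
        g = generate_ground_truth(8, 1, 1.5, 3, seed=5)
        ds = sample_dataset(g, make_structural_params(g, seed=5), 4000, seed=5)
        out = ds.values[g.outcome].dropna()
        assert ds.meta_for(g.outcome).vtype == CATEGORICAL
        assert set(out.unique()) == {0.0, 1.0, 2.0}

    def test_missing_mechanism_rejected(self):
        g = make_graph(["A", "B"], [("A", "B")])
        params = StructuralParams(edge_weights={}, noise_sd={"A": 1.0, "B": 1.0})
        with pytest.raises(ValueError, match="missing"):
            sample_dataset(g, params, 10, seed=0)


class TestInjectMissingness:
    @pytest.fixture
    def dataset(self):
        g = make_graph(["A", "B", "C"], [])
        return sample_dataset(g, make_structural_params(g, seed=0), 10000, seed=0)

    def test_zero_rates_leave_mask_empty(self, dataset):
        out = inject_missingness(dataset, {"A": 0.0}, seed=1)
        assert not out.mask.values.any()

    def test_realized_rate_concentrates_near_request(self, dataset):
        out = inject_missingness(dataset, {"B": 0.75}, seed=1)
        assert 0.73 <= out.missing_fraction("B") <= 0.77

    def test_mar_missingness_monotone_in_driver_quartile(self, dataset):
        out = inject_missingness(dataset, {"B": 0.3}, mechanism="mar", driver="A", seed=2)
        drv = dataset.values["A"]
        q = np.searchsorted(np.quantile(drv, [0.25, 0.5, 0.75]), drv, side="right")
        rates = [out.mask["B"].to_numpy()[q == i].mean() for i in range(4)]
        assert rates == sorted(rates)
        assert rates[3] > rates[0] + 0.1

    def test_rate_of_one_rejected(self, dataset):
        with pytest.raises(ValueError):
            inject_missingness(dataset, {"A": 1.0}, seed=0)

    def test_observed_values_untouched(self, dataset):
        out = inject_missingness(dataset, {"C": 0.4}, seed=3)
        obs = ~out.mask["C"].to_numpy()
        assert np.allclose(out.values["C"].to_numpy()[obs], dataset.values["C"].to_numpy()[obs])


class TestVariableDictionary:
    def test_labels_draw_from_category_lexicon(self):
        g = generate_ground_truth(20, 0, 1.0, 3, seed=9)
        dic = generate_variable_dictionary(g, DEFAULT_LEXICON, seed=9)
        for meta in dic:
            cat = meta.category or "none"
            words = set(meta.label.split())
            assert words & set(DEFAULT_LEXICON[cat])

    def test_decoys_have_no_category(self):
        g = generate_ground_truth(30, 0, 1.0, 3, seed=10)
        dic = generate_variable_dictionary(g, seed=10)
        decoys = [m for m in dic if m.category is None]
        assert decoys  # age, sex, outcome are always decoys

    def test_same_seed_same_labels(self):
        g = generate_ground_truth(12, 0, 1.0, 3, seed=11)
        d1 = generate_variable_dictionary(g, seed=11)
        d2 = generate_variable_dictionary(g, seed=11)
        assert [m.label for m in d1] == [m.label for m in d2]

    def test_missing_category_rejected(self):
        g = generate_ground_truth(12, 0, 1.0, 3, seed=12)
        with pytest.raises(ValueError):
            generate_variable_dictionary(g, {"none": ["x"]}, seed=0)
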