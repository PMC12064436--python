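"""Equal-weight pooling of PAGs, threshold views, and the outcome subnetwork."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixedfci.pag import ARROW, CIRCLE, TAIL, PAG
from mixedfci.pooling import compare_to_truth, extract_outcome_subnetwork, pool_pags
from mixedfci.simulate import generate_ground_truth
from mixedfci.graphs import true_mag

from conftest import make_graph


def pag_with(nodes, edges):
    """edges: list of (a, b, mark_at_a, mark_at_b)."""
    pag = PAG(list(nodes))
    for a, b, m1, m2 in edges:
        pag.add_edge(a, b, mark_at_a=m1, mark_at_b=m2)
    return pag


NODES = ["t", "v", "w", "x"]


class TestPooling:
    def test_unanimous_instance_survives_the_100_percent_view(self):
        pags = [pag_with(NODES, [("x", "t", TAIL, ARROW)]) for _ in range(50)]
        pooled = pool_pags(pags, thresholds=[1.0])
        assert ("t", "x", ARROW, TAIL) in pooled.view(1.0)

    def test_40_percent_instance_kept_at_30_dropped_at_50(self):
        hit = pag_with(NODES, [("x", "t", TAIL, ARROW)])
        miss = pag_with(NODES, [])
        pooled = pool_pags([hit] * 20 + [miss] * 30, thresholds=[0.3, 0.5])
        inst = ("t", "x", ARROW, TAIL)
        assert inst in pooled.view(0.3)
        assert inst not in pooled.view(0.5)

    def test_single_pag_identity_at_every_threshold(self):
        pag = pag_with(NODES, [("v", "w", CIRCLE, ARROW), ("w", "x", TAIL, ARROW)])
        pooled = pool_pags([pag], thresholds=[0.3, 0.5, 1.0])
        for t in (0.3, 0.5, 1.0):
            assert pooled.view_pag(t) == pag

    def test_mark_level_agreement_distinguishes_conflicting_variants(self):
        a = pag_with(NODES, [("v", "w", CIRCLE, ARROW)])
        b = pag_with(NODES, [("v", "w", TAIL, ARROW)])
        pooled = pool_pags([a, a, b], thresholds=[0.3])
        assert pooled.records[("v", "w", CIRCLE, ARROW)] == 2
        assert pooled.records[("v", "w", TAIL, ARROW)] == 1
        assert ("v", "w") in pooled.conflicts()

    def test_adjacency_mode_merges_variants(self):
        a = pag_with(NODES, [("v", "w", CIRCLE, ARROW)])
        b = pag_with(NODES, [("v", "w", TAIL, ARROW)])
        pooled = pool_pags([a, b], mode="adjacency")
        assert pooled.records[("v", "w", "*", "*")] == 2

    def test_permutation_invariance(self):
        r = np.random.default_rng(0)
        pags = []
        for _ in range(6):
            edges = []
            if r.random() < 0.7:
                edges.append(("v", "w", CIRCLE, ARROW))
            if r.random() < 0.5:
                edges.append(("w", "x", TAIL, ARROW))
            pags.append(pag_with(NODES, edges))
        p1 = pool_pags(pags)
        p2 = pool_pags(pags[::-1])
        assert p1.records == p2.records

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError):
            pool_pags([PAG(["a"]), PAG(["b"])])

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=20))
    def test_threshold_views_nested(self, membership):
        hit = pag_with(NODES, [("v", "w", CIRCLE, ARROW)])
        miss = pag_with(NODES, [])
        pooled = pool_pags([hit if b else miss for b in membership])
        for t1, t2 in [(0.2, 0.5), (0.3, 0.9), (0.5, 1.0)]:
            assert pooled.view(t2) <= pooled.view(t1)


class TestOutcomeSubnetwork:
    def test_isolated_outcome_keeps_only_itself(self):
        pooled = pool_pags([pag_with(NODES, [("v", "w", CIRCLE, ARROW)])])
        sub = extract_outcome_subnetwork(pooled, "t", 0.5)
        assert sub.nodes == ["t"] and not sub.records

    def test_direct_cause_retained(self):
        pooled = pool_pags([pag_with(NODES, [("x", "t", TAIL, ARROW)])])
        sub = extract_outcome_subnetwork(pooled, "t", 1.0)
        assert ("t", "x", ARROW, TAIL) in sub.records

    def test_path_length_filter(self):
        pags = [pag_with(NODES, [("v", "w", CIRCLE, ARROW), ("w", "t", TAIL, ARROW)])]
        pooled = pool_pags(pags)
        two = extract_outcome_subnetwork(pooled, "t", 1.0, max_steps=2)
        assert len(two.records) == 2
        one = extract_outcome_subnetwork(pooled, "t", 1.0, max_steps=1)
        assert set(one.records) == {("t", "w", ARROW, TAIL)}

    def test_edges_pointing_away_from_outcome_excluded(self):
        # arrow into v from t's side: not influence toward the outcome
        pooled = pool_pags([pag_with(NODES, [("t", "v", TAIL, ARROW)])])
        sub = extract_outcome_subnetwork(pooled, "t", 1.0)
        assert not sub.records


class TestCompareToTruth:
    def test_perfect_recovery_scores_one(self):
        g = generate_ground_truth(8, 1, 1.5, 3, seed=3)
        mag = true_mag(g)
        pooled = pool_pags([mag])
        rep = compare_to_truth(pooled, g, 1.0)
        assert rep.adjacency_precision == 1.0 and rep.adjacency_recall == 1.0
        assert rep.orientation_accuracy == 1.0

    def test_empty_network_convention(self):
        g = generate_ground_truth(8, 1, 1.5, 3, seed=3)
        pooled = pool_pags([PAG(sorted(g.observed_nodes))])
        rep = compare_to_truth(pooled, g, 0.5)
        assert rep.adjacency_precision == 1.0 and rep.adjacency_recall == 0.0

    def test_random_guessing_precision_near_truth_density(self):
        g = generate_ground_truth(10, 0, 2.0, 3, seed=5)
        mag = true_mag(g)
        density = mag.n_edges() / (10 * 9 / 2)
        r = np.random.default_rng(5)
        precisions = []
        from itertools import combinations

        for _ in range(40):
            pag = PAG(sorted(g.observed_nodes))
            pairs = list(combinations(sorted(g.observed_nodes), 2))
            for i in r.choice(len(pairs), size=mag.n_edges(), replace=False):
                pag.add_edge(*pairs[i], mark_at_a=CIRCLE, mark_at_b=CIRCLE)
            precisions.append(compare_to_truth(pool_pags([pag]), g, 1.0).adjacency_precision)
        assert np.mean(precisions) == pytest.approx(density, abs=0.1)
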