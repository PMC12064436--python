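"""Text preprocessing, embedding backends, cosine scoring and selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixedfci.data import VariableMeta
from mixedfci.simulate import DEFAULT_LEXICON, generate_ground_truth, generate_variable_dictionary
from mixedfci.textsel import (
    DocHashEmbeddingBackend,
    HashEmbeddingBackend,
    SelectionRule,
    cosine_similarity,
    embed_phrase,
    evaluate_selection,
    load_word2vec_text,
    preprocess_text,
    score_variables,
    select_variables,
)


class TestPreprocess:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Ever had bowel cancer screening?", ["ever", "bowel", "cancer", "screening"]),
            ("", []),
            ("SMOKING", ["smoking"]),
            ("alcohol intake (per week)", ["alcohol", "intake", "week"]),
        ],
    )
    def test_lowercase_punctuation_stopwords(self, raw, expected):
        assert preprocess_text(raw) == expected


class TestCosine:
    def test_identity_is_one(self):
        v = np.array([0.3, -2.0, 1.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_half_rotation_closed_form(self):
        assert cosine_similarity([1, 0], [1, 1]) == pytest.approx(np.sqrt(2) / 2, abs=1e-5)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=3), st.floats(0.01, 100))
    def test_symmetric_and_scale_invariant(self, u, c):
        v = [1.0, 2.0, -0.5]
        if np.linalg.norm(u) < 1e-6:
            return
        assert cosine_similarity(u, v) == pytest.approx(cosine_similarity(v, u))
        assert cosine_similarity(np.array(u) * c, v) == pytest.approx(cosine_similarity(u, v), abs=1e-9)


class TestEmbedding:
    @pytest.fixture
    def backend(self):
        return HashEmbeddingBackend(DEFAULT_LEXICON, extra_vocabulary=["widget"])

    def test_single_token_is_its_own_vector(self, backend):
        assert np.allclose(embed_phrase(["smoking"], backend), backend.lookup("smoking"))

    def test_mean_of_two_fixture_vectors(self):
        class TwoVec(HashEmbeddingBackend):
            def __init__(self):
                self.name = "two"
                self.dimension = 2
                self._vectors = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}

        assert np.allclose(embed_phrase(["a", "b"], TwoVec()), [0.5, 0.5])

    def test_out_of_vocabulary_tokens_skipped_in_mean(self, backend):
        with_oov = embed_phrase(["smoking", "zzzunknown"], backend)
        assert np.allclose(with_oov, backend.lookup("smoking"))

    def test_all_oov_is_unscorable(self, backend):
        assert embed_phrase(["zzz", "qqq"], backend) is None
        assert embed_phrase([], backend) is None

    def test_same_category_tokens_cluster(self, backend):
        sim_within = cosine_similarity(backend.lookup("smoking"), backend.lookup("cigarette"))
        sim_across = cosine_similarity(backend.lookup("smoking"), backend.lookup("alcohol"))
        assert sim_within > 0.7 > sim_across

    def test_word2vec_text_roundtrip(self, tmp_path):
        path = tmp_path / "vecs.txt"
        path.write_text("2 3\nfoo 1.0 0.0 0.0\nbar 0.0 1.0 0.0\n")
        be = load_word2vec_text(path)
        assert be.dimension == 3
        assert np.allclose(be.lookup("foo"), [1, 0, 0])
        assert be.lookup("baz") is None


def _fixture_setup(seed=11, n=40):
    graph = generate_ground_truth(n, 3, 2.0, 3, seed=seed)
    dictionary = generate_variable_dictionary(graph, seed=seed)
    phrases = [c for c in DEFAULT_LEXICON if c != "none"]
    vocab = sorted({t for m in dictionary for t in preprocess_text(m.label)})
    backends = [
        HashEmbeddingBackend(DEFAULT_LEXICON, extra_vocabulary=vocab),
        DocHashEmbeddingBackend(DEFAULT_LEXICON, extra_vocabulary=vocab),
    ]
    gold = {}
    for m in dictionary:
        if m.category:
            gold.setdefault(m.category, set()).add(m.name)
    return dictionary, phrases, backends, gold


class TestScoring:
    def test_category_label_matches_its_phrase(self):
        dictionary, phrases, backends, _ = _fixture_setup()
        results = score_variables(dictionary, phrases, backends)
        by_name = {r.variable: r for r in results}
        for meta in dictionary:
            if meta.category:
                assert by_name[meta.name].best_phrase == meta.category

    def test_scores_bounded_and_deterministic(self):
        dictionary, phrases, backends, _ = _fixture_setup()
        r1 = score_variables(dictionary, phrases, backends)
        r2 = score_variables(dictionary, phrases, backends)
        for a, b in zip(r1, r2):
            assert a.scores == b.scores
            assert all(-1.0 <= s <= 1.0 + 1e-12 for s in a.scores.values())

    def test_identical_text_scores_one_on_word_backend(self):
        dictionary = [VariableMeta("v", label="smoking")]
        _, _, backends, _ = _fixture_setup()
        results = score_variables(dictionary, ["smoking"], [backends[0]])
        assert results[0].scores[backends[0].name] == pytest.approx(1.0)

    def test_unscorable_variable_flagged_not_dropped(self):
        dictionary = [VariableMeta("v", label="zzzz qqqq")]
        _, phrases, backends, _ = _fixture_setup()
        results = score_variables(dictionary, phrases, backends)
        assert len(results) == 1 and not results[0].scorable and not results[0].selected


class TestSelection:
    def test_threshold_above_one_selects_nothing(self):
        dictionary, phrases, backends, _ = _fixture_setup()
        results = score_variables(dictionary, phrases, backends)
        out = select_variables(results, SelectionRule(threshold=1.1))
        assert not any(r.selected for r in out)

    def test_threshold_below_minus_one_selects_all_scorable(self):
        dictionary, phrases, backends, _ = _fixture_setup()
        results = score_variables(dictionary, phrases, backends)
        out = select_variables(results, SelectionRule(threshold=-1.1))
        assert all(r.selected for r in out if r.scorable)

    def test_top_k_bounded_by_phrase_count(self):
        dictionary, phrases, backends, _ = _fixture_setup()
        results = score_variables(dictionary, phrases, backends)
        out = select_variables(results, SelectionRule(top_k=1))
        assert sum(r.selected for r in out) <= len(phrases)

    def test_selection_monotone_in_threshold(self):
        dictionary, phrases, backends, _ = _fixture_setup()
        results = score_variables(dictionary, phrases, backends)
        chosen = []
        for thr in (0.2, 0.4, 0.6, 0.8):
            out = select_variables(results, SelectionRule(threshold=thr))
            chosen.append({r.variable for r in out if r.selected})
        for lo, hi in zip(chosen[1:], chosen):
            assert lo <= hi

    def test_contradictory_rule_rejected(self):
        with pytest.raises(ValueError):
            SelectionRule(threshold=0.5, top_k=3)
        with pytest.raises(ValueError):
            SelectionRule()


class TestEvaluation:
    def test_coverage_accuracy_formula(self):
        # 40 gold categories, 10 excluded from QC, 24 covered -> 24/30 = 0.80
        gold = {f"cat{i:02d}": {f"v{i:02d}"} for i in range(40)}
        excluded = {f"cat{i:02d}" for i in range(30, 40)}
        from mixedfci.textsel import SelectionResult

        selected = [
            SelectionResult(f"v{i:02d}", "p", {}, selected=True) for i in range(24)
        ]
        report = evaluate_selection(selected, gold, excluded)
        assert report.accuracy == pytest.approx(24 / 30) == pytest.approx(0.80)

    def test_full_and_zero_coverage(self):
        from mixedfci.textsel import SelectionResult

        gold = {"a": {"v1"}, "b": {"v2"}}
        all_sel = [SelectionResult("v1", "p", {}, selected=True), SelectionResult("v2", "p", {}, selected=True)]
        assert evaluate_selection(all_sel, gold).accuracy == 1.0
        none_sel = [SelectionResult("v9", "p", {}, selected=True)]
        assert evaluate_selection(none_sel, gold).accuracy == 0.0

    def test_all_excluded_is_undefined(self):
        with pytest.raises(ValueError):
            evaluate_selection([], {"a": {"v"}}, {"a"})

    def test_fixture_self_consistency_accuracy(self):
        """Labels built from category lexicons are recovered by the fixture
        embedding at the calibrated threshold."""
        dictionary, phrases, backends, gold = _fixture_setup(seed=11)
        results = select_variables(
            score_variables(dictionary, phrases, backends), SelectionRule(threshold=0.6)
        )
        report = evaluate_selection(results, gold)
        assert report.accuracy >= 0.9
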