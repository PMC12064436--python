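"""Mixed graphical model: penalized pseudolikelihood fit and skeleton."""

import numpy as np
import pandas as pd
import pytest

from mixedfci.data import MixedDataset, VariableMeta
from mixedfci.mgm import mgm_fit, mgm_skeleton, select_lambda

from conftest import gaussian_dataset


def chain_dataset(n, p, seed, weight=0.6):
    r = np.random.default_rng(seed)
    cols = {}
    x = r.normal(size=n)
    cols["v00"] = x
    for i in range(1, p):
        x = weight * x + r.normal(size=n)
        cols[f"v{i:02d}"] = x
    df = pd.DataFrame(cols)
    df = (df - df.mean()) / df.std()
    return MixedDataset(df, [VariableMeta(c) for c in df.columns])


def mixed_dataset(n, seed):
    r = np.random.default_rng(seed)
    a = r.normal(size=n)
    c = (r.random(n) < 1 / (1 + np.exp(-1.6 * a))).astype(float)
    b = r.normal(size=n)
    df = pd.DataFrame({"a": (a - a.mean()) / a.std(), "b": (b - b.mean()) / b.std(), "c": c})
    return MixedDataset(
        df, [VariableMeta("a"), VariableMeta("b"), VariableMeta("c", vtype="categorical", n_levels=2)]
    )


CHAIN_EDGES = {frozenset((f"v{i:02d}", f"v{i + 1:02d}")) for i in range(9)}


class TestMgmFit:
    def test_dominating_lambda_zeroes_all_blocks(self):
        params = mgm_fit(chain_dataset(500, 5, 0), 1e3)
        sk = mgm_skeleton(params)
        assert sk.n_edges() == 0

    def test_independent_variables_have_zero_block(self):
        r = np.random.default_rng(1)
        ds = gaussian_dataset({"a": r.normal(size=2000), "b": r.normal(size=2000)})
        params = mgm_fit(ds, 0.15)
        assert params.block_norm("a", "b") == 0.0

    def test_strong_dependence_survives_penalty(self):
        r = np.random.default_rng(2)
        x = r.normal(size=2000)
        y = 0.8 * x + r.normal(size=2000)
        df = pd.DataFrame({"x": x, "y": y})
        df = (df - df.mean()) / df.std()
        params = mgm_fit(MixedDataset(df, [VariableMeta("x"), VariableMeta("y")]), 0.1)
        assert params.block_norm("x", "y") > 0.0

    def test_objective_monotone_nonincreasing(self):
        params = mgm_fit(chain_dataset(800, 6, 3), 0.1)
        trace = np.array(params.objective_trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_mixed_pair_detected_and_independent_pair_excluded(self):
        params = mgm_fit(mixed_dataset(2000, 4), 0.1)
        sk = mgm_skeleton(params)
        assert sk.is_adjacent("a", "c")
        assert not sk.is_adjacent("b", "c") and not sk.is_adjacent("a", "b")

    def test_label_equivariance_under_column_permutation(self):
        ds = chain_dataset(1000, 5, 5)
        perm = ["v03", "v00", "v04", "v02", "v01"]
        sk1 = mgm_skeleton(mgm_fit(ds, 0.12))
        sk2 = mgm_skeleton(mgm_fit(ds.select(perm), 0.12))
        assert sk1.adjacency == sk2.adjacency

    def test_incomplete_data_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan] * 10, "b": np.arange(20.0)})
        ds = MixedDataset(df, [VariableMeta("a"), VariableMeta("b")])
        with pytest.raises(ValueError, match="complete"):
            mgm_fit(ds, 0.1)

    def test_chain_recovery_at_calibrated_lambda(self):
        sk = mgm_skeleton(mgm_fit(chain_dataset(2000, 10, 7), 0.15))
        assert CHAIN_EDGES <= sk.adjacency
        assert len(sk.adjacency - CHAIN_EDGES) <= 1

    def test_edge_count_monotone_along_lambda_path(self):
        ds = chain_dataset(1500, 8, 8)
        counts = [mgm_skeleton(mgm_fit(ds, lam)).n_edges() for lam in (0.05, 0.1, 0.2, 0.4, 0.8)]
        # tolerate rare non-monotone steps from pseudolikelihood non-convexity
        violations = sum(b > a for a, b in zip(counts, counts[1:]))
        assert violations == 0


class TestSerialization:
    def test_params_npz_roundtrip(self, tmp_path):
        ds = mixed_dataset(400, 12)
        params = mgm_fit(ds, 0.1)
        from mixedfci.mgm import MGMParams

        params.save(tmp_path / "p.npz")
        loaded = MGMParams.load(tmp_path / "p.npz")
        assert loaded.cat_levels == params.cat_levels
        assert np.allclose(loaded.cont_cont, params.cont_cont)
        assert np.allclose(loaded.cont_cat, params.cont_cat)
        assert mgm_skeleton(loaded).adjacency == mgm_skeleton(params).adjacency

    def test_skeleton_tsv_and_graphml(self, tmp_path):
        sk = mgm_skeleton(mgm_fit(mixed_dataset(400, 13), 0.1))
        sk.write_tsv(tmp_path / "s.tsv")
        sk.write_graphml(tmp_path / "s.graphml")
        lines = (tmp_path / "s.tsv").read_text().splitlines()
        assert lines[0] == "node1\tnode2" and len(lines) == 1 + sk.n_edges()


class TestSelectLambda:
    def test_single_grid_value_returned(self):
        ds = chain_dataset(300, 4, 9)
        assert select_lambda(ds, [0.2]) == 0.2

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_lambda(chain_dataset(300, 4, 9), [])

    def test_stars_on_independent_data_picks_sparse_lambda(self):
        r = np.random.default_rng(10)
        df = pd.DataFrame(r.normal(size=(1200, 6)), columns=[f"w{i}" for i in range(6)])
        ds = MixedDataset(df, [VariableMeta(c) for c in df.columns])
        lam = select_lambda(ds, [0.05, 0.1, 0.2, 0.4], method="stars", n_subsamples=8, seed=0)
        sk = mgm_skeleton(mgm_fit(ds, lam))
        assert sk.n_edges() <= 0.02 * 15 + 1  # at most ~2% of the 15 pairs

    def test_bic_recovers_chain(self):
        ds = chain_dataset(1500, 6, 11)
        lam = select_lambda(ds, [0.05, 0.1, 0.2, 0.4], method="bic")
        sk = mgm_skeleton(mgm_fit(ds, lam))
        true = {frozenset((f"v{i:02d}", f"v{i + 1:02d}")) for i in range(5)}
        assert true <= sk.adjacency
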