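"""Missingness QC, standardization, and chained-equations imputation."""

import numpy as np
import pandas as pd
import pytest

from mixedfci.data import MixedDataset, VariableMeta
from mixedfci.impute import mice_impute, qc_missing_rate, standardize_continuous
from mixedfci.simulate import inject_missingness

from conftest import gaussian_dataset


def bivariate(n=4000, corr=0.6, seed=0):
    r = np.random.default_rng(seed)
    x = r.normal(size=n)
    y = corr * x + np.sqrt(1 - corr**2) * r.normal(size=n)
    return gaussian_dataset({"x": x, "y": y})


class TestQC:
    def test_high_missing_variable_removed_at_threshold(self):
        ds = bivariate()
        ds = inject_missingness(ds, {"y": 0.8}, seed=1)
        out = qc_missing_rate(ds, 0.75)
        assert out.names == ["x"]

    def test_fully_observed_retained(self):
        out = qc_missing_rate(bivariate(), 0.75)
        assert out.names == ["x", "y"]

    def test_threshold_one_retains_everything(self):
        ds = inject_missingness(bivariate(), {"y": 0.9}, seed=1)
        assert qc_missing_rate(ds, 1.0).names == ["x", "y"]

    def test_all_removed_is_an_error(self):
        ds = inject_missingness(bivariate(n=2000), {"x": 0.5, "y": 0.5}, seed=2)
        with pytest.raises(ValueError):
            qc_missing_rate(ds, 0.1)


class TestStandardize:
    def test_closed_form_three_values(self):
        ds = gaussian_dataset({"a": np.array([1.0, 2.0, 3.0])})
        out, params = standardize_continuous(ds)
        assert np.allclose(out.values["a"], [-1.0, 0.0, 1.0])
        assert params.mean["a"] == pytest.approx(2.0) and params.sd["a"] == pytest.approx(1.0)

    def test_idempotent_up_to_float_tolerance(self):
        ds = bivariate(n=500)
        once, _ = standardize_continuous(ds)
        twice, _ = standardize_continuous(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12)

    def test_categorical_columns_bitwise_identical(self):
        r = np.random.default_rng(0)
        df = pd.DataFrame({"a": r.normal(size=100), "c": (r.random(100) < 0.5).astype(float)})
        ds = MixedDataset(df, [VariableMeta("a"), VariableMeta("c", vtype="categorical", n_levels=2)])
        out, _ = standardize_continuous(ds)
        assert (out.values["c"].to_numpy() == df["c"].to_numpy()).all()

    def test_statistics_use_observed_cells_only(self):
        ds = inject_missingness(bivariate(), {"y": 0.3}, seed=3)
        out, _ = standardize_continuous(ds)
        obs = out.values["y"].dropna()
        assert abs(obs.mean()) < 1e-12 and abs(obs.std(ddof=1) - 1) < 1e-12

    def test_degenerate_column_named_in_error(self):
        ds = gaussian_dataset({"flat": np.ones(50)})
        with pytest.raises(ValueError, match="flat"):
            standardize_continuous(ds)


class TestMice:
    def test_complete_input_returns_identical_copies(self):
        ds = bivariate(n=200)
        out = mice_impute(ds, m=3, seed=0)
        assert out.m == 3
        for d in out.datasets:
            assert np.allclose(d.values.to_numpy(), ds.values.to_numpy())

    def test_m_datasets_returned(self):
        ds = inject_missingness(bivariate(n=300), {"y": 0.2}, seed=1)
        out = mice_impute(ds, m=50, iterations=1, model="parametric", seed=0)
        assert out.m == 50 and len(out.datasets) == 50

    @pytest.mark.parametrize("model", ["rf", "parametric"])
    def test_completed_correlation_near_generative(self, model):
        ds = inject_missingness(bivariate(n=4000, corr=0.6, seed=4), {"y": 0.2}, seed=4)
        out = mice_impute(ds, m=10, iterations=5, model=model, seed=4)
        corr = np.mean([d.values.corr().loc["x", "y"] for d in out.datasets])
        assert abs(corr - 0.6) < 0.1

    def test_observed_cells_invariant_across_datasets(self):
        ds = inject_missingness(bivariate(n=1000, seed=5), {"x": 0.1, "y": 0.2}, seed=5)
        out = mice_impute(ds, m=4, iterations=2, seed=5)
        obs = ~ds.mask.to_numpy()
        for d in out.datasets:
            assert np.array_equal(d.values.to_numpy()[obs], ds.values.to_numpy()[obs])
            assert d.is_complete()

    def test_categorical_imputations_use_existing_levels(self):
        r = np.random.default_rng(6)
        x = r.normal(size=1500)
        c = (x + r.normal(size=1500) > 0).astype(float) + (x > 1.0)  # levels 0, 1, 2
        df = pd.DataFrame({"x": x, "c": c})
        ds = MixedDataset(df, [VariableMeta("x"), VariableMeta("c", vtype="categorical", n_levels=3)])
        ds = inject_missingness(ds, {"c": 0.3}, seed=6)
        for model in ("rf", "parametric"):
            out = mice_impute(ds, m=2, iterations=2, model=model, seed=6)
            for d in out.datasets:
                assert set(d.values["c"].unique()) <= {0.0, 1.0, 2.0}

    def test_chains_reproducible_given_seed(self):
        ds = inject_missingness(bivariate(n=500, seed=7), {"y": 0.25}, seed=7)
        a = mice_impute(ds, m=3, iterations=2, seed=9)
        b = mice_impute(ds, m=3, iterations=2, seed=9)
        for da, db in zip(a.datasets, b.datasets):
            assert np.array_equal(da.values.to_numpy(), db.values.to_numpy())

    def test_fully_missing_variable_rejected(self):
        df = pd.DataFrame({"x": np.arange(5.0), "y": [np.nan] * 5})
        ds = MixedDataset(df, [VariableMeta("x"), VariableMeta("y")])
        with pytest.raises(ValueError, match="QC"):
            mice_impute(ds, m=1, seed=0)

    def test_excluded_variable_with_missing_cells_rejected(self):
        ds = inject_missingness(bivariate(n=200), {"y": 0.2}, seed=8)
        with pytest.raises(ValueError, match="excluded"):
            mice_impute(ds, m=1, seed=0, exclude=("y",))

    def test_mcar_marginal_mean_preserved(self):
        ds = inject_missingness(bivariate(n=4000, seed=9), {"y": 0.3}, seed=9)
        out = mice_impute(ds, m=5, iterations=3, seed=9)
        obs_mean = ds.values["y"].dropna().mean()
        completed = np.mean([d.values["y"].mean() for d in out.datasets])
        assert abs(completed - obs_mean) < 0.08
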