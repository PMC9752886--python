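import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from drugfunnel.deg import (
    ExpressionMatrix,
    bh_adjust,
    call_up_degs,
    differential_expression,
    geo_channel_indicator,
    moderated_t,
    normalize,
)
from drugfunnel.errors import ConfigError, DataFormatError
from drugfunnel.synthetic import SimConfig, gen_expression_dataset

from conftest import make_matrix
from oracles import bh_brute


class TestExpressionMatrix:
    def test_requires_two_samples_per_group(self):
        with pytest.raises(ConfigError, match="fewer than 2"):
            make_matrix(np.zeros((3, 3)), n_normal=1)

    def test_rejects_duplicate_genes(self):
        with pytest.raises(DataFormatError, match="duplicate"):
            make_matrix(np.zeros((2, 4)), n_normal=2, genes=["a", "a"])

    def test_rejects_unknown_group_label(self):
        values = pd.DataFrame(np.zeros((2, 4)), index=["a", "b"], columns=list("wxyz"))
        groups = pd.Series(["normal", "normal", "tumor", "case"], index=list("wxyz"))
        with pytest.raises(DataFormatError, match="unknown group"):
            ExpressionMatrix(values=values, groups=groups)


class TestNormalize:
    def test_constant_matrix_unchanged(self):
        matrix = make_matrix(np.full((5, 4), 3.0), n_normal=2)
        out = normalize(matrix)
        assert np.allclose(out.values.to_numpy(), 3.0)

    def test_removes_per_sample_shift(self):
        rng = np.random.default_rng(0)
        base = rng.normal(7, 1, size=(200, 6))
        shifted = base.copy()
        shifted[:, 2] += 3.0
        out = normalize(make_matrix(shifted, n_normal=3))
        medians = out.values.median(axis=0).to_numpy()
        assert np.allclose(medians, medians[0], atol=1e-9)

    def test_planted_effect_survives_centering(self):
        cfg = SimConfig(seed=5, n_genes=200, n_true_risk=50, noise_sd=0.3, effect_size=2.5)
        universe = [f"G{i:04d}" for i in range(1, 201)]
        up = set(universe[:20])
        matrix = gen_expression_dataset(cfg, universe, up, n_normal=10, n_tumor=10)
        out = normalize(matrix)
        diff = out.samples_in("tumor").mean(axis=1) - out.samples_in("normal").mean(axis=1)
        assert diff.loc[sorted(up)].mean() == pytest.approx(2.5, abs=0.3)

    def test_linear_scale_gets_log_transformed(self):
        matrix = make_matrix(np.full((3, 4), 1023.0), n_normal=2)
        out = normalize(matrix)
        assert np.allclose(out.values.to_numpy(), 10.0)

    def test_nonfinite_raises_naming_sample(self):
        values = np.zeros((3, 4))
        values[1, 2] = np.inf
        with pytest.raises(DataFormatError, match="s2"):
            normalize(make_matrix(values, n_normal=2))


class TestModeratedT:
    def test_hand_computed_example(self):
        # means 5 vs 1 with unit pooled variance in both groups
        values = np.array([[0.0, 1.0, 2.0, 4.0, 5.0, 6.0]])
        result = moderated_t(make_matrix(values, n_normal=3), prior_df=4.0, prior_var=1.0)
        row = result.iloc[0]
        assert row["logFC"] == pytest.approx(4.0)
        assert row["s2"] == pytest.approx(1.0)
        assert row["s2_shrunk"] == pytest.approx(1.0)
        assert row["t"] == pytest.approx(4.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
        assert row["df"] == pytest.approx(8.0)
        assert row["p"] == pytest.approx(2 * stats.t.sf(4.0 / np.sqrt(2.0 / 3.0), 8))

    def test_zero_prior_reduces_to_pooled_t(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(50, 12))
        matrix = make_matrix(values, n_normal=5)
        result = moderated_t(matrix, prior_df=0.0)
        t_ref, p_ref = stats.ttest_ind(values[:, 5:], values[:, :5], axis=1, equal_var=True)
        np.testing.assert_allclose(result["t"].to_numpy(), t_ref, rtol=1e-12)
        np.testing.assert_allclose(result["p"].to_numpy(), p_ref, rtol=1e-10)

    def test_huge_prior_forces_shared_unit_variance(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(30, 10))
        matrix = make_matrix(values, n_normal=5)
        result = moderated_t(matrix, prior_df=1e9, prior_var=1.0)
        logfc = values[:, 5:].mean(axis=1) - values[:, :5].mean(axis=1)
        np.testing.assert_allclose(
            result["t"].to_numpy(), logfc / np.sqrt(1 / 5 + 1 / 5), rtol=1e-6
        )

    def test_degenerate_zero_variance_flagged(self, caplog):
        values = np.array([[0.0, 0.0, 0.0, 1.0, 1.0, 1.0]])
        with caplog.at_level("WARNING"):
            result = moderated_t(make_matrix(values, n_normal=3), prior_df=0.0)
        assert result.iloc[0]["p"] == np.finfo(float).tiny
        assert np.isinf(result.iloc[0]["t"])
        assert "zero shrunken variance" in caplog.text

    def test_negative_prior_df_rejected(self):
        with pytest.raises(ConfigError):
            moderated_t(make_matrix(np.zeros((2, 4)), n_normal=2), prior_df=-1.0)


class TestBHAdjust:
    def test_worked_example(self):
        out = bh_adjust([0.01, 0.04, 0.03, 0.005])
        np.testing.assert_allclose(out, [0.02, 0.04, 0.04, 0.02])

    def test_capped_at_one(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ConfigError, match="outside"):
            bh_adjust([0.5, 1.5])

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_brute_force(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_brute(p), rtol=1e-12, atol=1e-15)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_monotone(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestCallUpDegs:
    def make_result(self, rows):
        return pd.DataFrame(rows, columns=["adj_p", "logFC"], index=[f"g{i}" for i in range(len(rows))])

    def test_passing_gene_included(self):
        assert call_up_degs(self.make_result([(0.01, 2.5)])) == {"g0"}

    def test_fails_p_cutoff(self):
        assert call_up_degs(self.make_result([(0.06, 5.0)])) == set()

    def test_downregulated_excluded(self):
        result = self.make_result([(0.001, -4.0)])
        assert call_up_degs(result) == set()
        assert call_up_degs(result, absolute_logfc=True) == {"g0"}

    def test_exact_cutoffs_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            out = call_up_degs(self.make_result([(0.05, 3.0), (0.01, 2.0)]))
        assert out == set()
        assert "exact cutoff" in caplog.text

    def test_missing_columns(self):
        with pytest.raises(ConfigError):
            call_up_degs(pd.DataFrame({"logFC": [1.0]}))


class TestGeoIndicator:
    def test_union_rule(self):
        vec = geo_channel_indicator([{"a"}, {"b"}], ["a", "b", "c"])
        assert vec.tolist() == [1, 1, 0]

    def test_gene_outside_universe_ignored(self):
        vec = geo_channel_indicator([{"z"}], ["a", "b"])
        assert vec.tolist() == [0, 0]

    def test_requires_at_least_one_dataset(self):
        with pytest.raises(ConfigError):
            geo_channel_indicator([], ["a"])


class TestEndToEndRates:
    def test_planted_effect_fully_recovered(self):
        cfg = SimConfig(seed=7, n_genes=300, n_true_risk=100, effect_size=4.0, noise_sd=0.5)
        universe = [f"G{i:04d}" for i in range(1, 301)]
        up = set(universe[:40])
        matrix = gen_expression_dataset(cfg, universe, up, n_normal=10, n_tumor=10)
        table = differential_expression(matrix)
        called = set(table.index[table["up_flag"]])
        assert up <= called

    def test_null_rate_below_nominal(self):
        rates = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_genes=200, n_true_risk=0, effect_size=0.0, noise_sd=0.5)
            universe = [f"G{i:04d}" for i in range(1, 201)]
            matrix = gen_expression_dataset(cfg, universe, set(), n_normal=5, n_tumor=5)
            table = differential_expression(matrix)
            rates.append(table["up_flag"].mean())
        assert np.mean(rates) <= 0.05
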