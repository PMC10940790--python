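"""Environment pruning, RDA, permutation ANOVA and stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from poolscan.gea import (
    RDA,
    permutation_anova,
    prune_collinear,
    rda_fit,
    standardize_env,
    stepwise_select,
)


def env_frame(data, index=None):
    df = pd.DataFrame(data)
    if index is None:
        df.index = [f"P{i:02d}" for i in range(len(df))]
    return df


class TestStandardize:
    def test_closed_form(self):
        out = standardize_env(env_frame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["x"], [-1, 0, 1])

    def test_constant_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            out = standardize_env(env_frame({"x": [1, 2, 3], "c": [5, 5, 5]}))
        assert list(out.columns) == ["x"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        e = env_frame({"a": rng.normal(3, 2, 10), "b": rng.normal(0, 1, 10)})
        once = standardize_env(e)
        twice = standardize_env(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(),
                                   atol=1e-12)


class TestPrune:
    def test_duplicated_variable_one_removed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 15)
        env = standardize_env(env_frame({"a": x, "b": x, "y": rng.normal(0, 1, 15)}))
        rep = prune_collinear(env)
        assert len(rep.removed) == 1
        assert sorted(rep.retained) in (["a", "y"], ["b", "y"])

    def test_orthogonal_untouched(self):
        rng = np.random.default_rng(2)
        env = standardize_env(env_frame(
            {f"v{k}": rng.normal(0, 1, 40) for k in range(4)}
        ))
        rep = prune_collinear(env)
        assert rep.removed == []
        assert len(rep.retained) == 4

    def test_chain_vif_below_cut(self):
        # x, x+noise, y: one of the correlated pair must go, final VIFs < 5
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 15)
        env = standardize_env(env_frame({
            "x1": x, "x2": x + rng.normal(0, 0.1, 15),
            "y": rng.normal(0, 1, 15),
        }))
        rep = prune_collinear(env)
        assert len(rep.retained) == 2
        assert "y" in rep.retained
        from poolscan.gea import _vif_table

        assert (_vif_table(env[rep.retained]) < 5).all()

    def test_removals_logged(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 15)
        env = standardize_env(env_frame({"a": x, "b": x}))
        with pytest.warns(UserWarning, match="fewer than 2"):
            rep = prune_collinear(env)
        assert rep.removed[0]["stage"] == "pairwise_r"
        assert rep.removed[0]["value"] == pytest.approx(1.0)


class TestRda:
    def test_exact_linear_response_fully_constrained(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 12)
        load = rng.normal(0, 1, 30)
        Y = np.outer(x, load)
        model = rda_fit(Y, env_frame({"x": x}, index=range(12)))
        assert model.constrained_pct_ == pytest.approx(100.0, abs=1e-6)
        assert model.axis_variance_pct_[0] == pytest.approx(100.0, abs=1e-6)

    def test_constrained_plus_residual_is_total(self):
        rng = np.random.default_rng(6)
        Y = rng.uniform(0, 1, (15, 40))
        X = env_frame({f"v{k}": rng.normal(0, 1, 15) for k in range(3)})
        model = rda_fit(Y, X)
        assert model.constrained_ss_ + model.residual_ss_ == pytest.approx(
            model.total_ss_, rel=1e-9
        )

    def test_single_predictor_matches_per_snp_regression(self):
        # brute-force oracle: constrained SS equals the sum over SNPs of
        # each SNP's regression sum of squares on the predictor
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 10)
        Y = 0.3 * x[:, None] + rng.normal(0, 0.5, (10, 8))
        ss = 0.0
        xc = x - x.mean()
        for j in range(Y.shape[1]):
            y = Y[:, j] - Y[:, j].mean()
            beta = (xc @ y) / (xc @ xc)
            ss += ((beta * xc) ** 2).sum()
        model = rda_fit(Y, env_frame({"x": x}, index=range(10)))
        assert model.constrained_ss_ == pytest.approx(ss, rel=1e-10)

    def test_equivariant_to_pool_permutation(self):
        rng = np.random.default_rng(8)
        Y = rng.uniform(0, 1, (12, 20))
        X = env_frame({"a": rng.normal(0, 1, 12), "b": rng.normal(0, 1, 12)})
        m1 = rda_fit(Y, X)
        perm = rng.permutation(12)
        m2 = rda_fit(Y[perm], X.iloc[perm])
        # scores permute identically (up to axis sign)
        for a in range(m1.scores_.shape[1]):
            c = np.corrcoef(m1.scores_[perm, a], m2.scores_[:, a])[0, 1]
            assert abs(c) == pytest.approx(1.0, abs=1e-9)

    def test_rank_deficient_names_columns(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 12)
        X = env_frame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="dependent"):
            rda_fit(rng.uniform(0, 1, (12, 5)), X)

    def test_too_few_pools_fatal(self):
        with pytest.raises(ValueError, match="pools"):
            rda_fit(np.zeros((3, 4)), env_frame({"a": [1, 2, 3], "b": [2, 1, 4]},
                                                index=range(3)))


class TestPermutationAnova:
    def test_minimal_p_bound(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 15)
        Y = np.outer(x, rng.normal(0, 1, 20))  # perfect association
        model = rda_fit(Y, env_frame({"x": x}))
        out = permutation_anova(model, nperm=199, seed=0)
        assert out["overall_p"] == pytest.approx(1 / 200)

    def test_null_p_not_small(self):
        rng = np.random.default_rng(11)
        Y = rng.uniform(0, 1, (15, 30))
        X = env_frame({"a": rng.normal(0, 1, 15)})
        model = rda_fit(Y, X)
        out = permutation_anova(model, nperm=199, seed=1)
        assert out["overall_p"] > 0.05

    def test_type_one_error_calibrated(self):
        # empirical rejection rate at alpha=0.05 under the null
        rng = np.random.default_rng(12)
        hits = 0
        n_runs = 400
        for r in range(n_runs):
            Y = rng.uniform(0, 1, (15, 20))
            X = env_frame({"a": rng.normal(0, 1, 15),
                           "b": rng.normal(0, 1, 15)})
            model = rda_fit(Y, X)
            out = permutation_anova(model, nperm=99, seed=r)
            if out["overall_p"] <= 0.05:
                hits += 1
        assert 0.02 <= hits / n_runs <= 0.08

    def test_marginal_test_flags_true_variable(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 15)
        Y = 0.2 * x[:, None] + rng.normal(0, 0.05, (15, 25))
        X = env_frame({"signal": x, "noise": rng.normal(0, 1, 15)})
        out = permutation_anova(rda_fit(Y, X), nperm=199, seed=2)
        assert out["term_p"]["signal"] < 0.05
        # the noise variable's marginal F must be far weaker
        assert out["term_f"]["signal"] > 10 * out["term_f"]["noise"]

    def test_low_nperm_warns(self):
        rng = np.random.default_rng(14)
        model = rda_fit(rng.uniform(0, 1, (10, 5)),
                        env_frame({"a": rng.normal(0, 1, 10)}, index=range(10)))
        with pytest.warns(UserWarning, match="nperm"):
            permutation_anova(model, nperm=9, seed=0)


class TestStepwise:
    def test_single_true_variable_selected(self):
        hits = 0
        for r in range(30):
            rng = np.random.default_rng(100 + r)
            x = rng.normal(0, 1, 15)
            Y = 0.25 * x[:, None] + rng.normal(0, 0.08, (15, 25))
            X = env_frame({
                "signal": x,
                **{f"n{k}": rng.normal(0, 1, 15) for k in range(3)},
            })
            sel = stepwise_select(Y, X, iterations=199, seed=r)
            if sel == ["signal"]:
                hits += 1
        assert hits >= 27  # >= 90% of replicates

    def test_all_noise_rarely_selects(self):
        n_sel = 0
        for r in range(30):
            rng = np.random.default_rng(200 + r)
            Y = rng.uniform(0, 1, (15, 25))
            X = env_frame({f"n{k}": rng.normal(0, 1, 15) for k in range(3)})
            sel = stepwise_select(Y, X, iterations=99, seed=r)
            n_sel += len(sel) > 0
        # spurious entry happens at roughly the per-test alpha level
        assert n_sel <= 8

    def test_forced_single_variable_with_effect(self):
        rng = np.random.default_rng(15)
        x = rng.normal(0, 1, 15)
        Y = 0.3 * x[:, None] + rng.normal(0, 0.05, (15, 20))
        sel = stepwise_select(Y, env_frame({"only": x}), iterations=199, seed=0)
        assert sel == ["only"]
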