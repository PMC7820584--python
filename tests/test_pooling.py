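import numpy as np
import pandas as pd
import pytest

from mivip.pooling import (
    ImportanceMatrix,
    pool_importance,
    rank_matrix,
    rank_summary,
    round_half_up,
)

from _oracles import pool_brute_force


def random_matrix(rng, M=None, p=None):
    M = M or int(rng.integers(2, 11))
    p = p or int(rng.integers(2, 9))
    theta = rng.normal(size=(M, p)) * rng.uniform(0.1, 10)
    se = np.abs(rng.normal(size=(M, p)))
    return ImportanceMatrix(theta, [f"v{j}" for j in range(p)], "RF", se=se)


class TestPoolImportance:
    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            mat = random_matrix(rng)
            got = pool_importance(mat)
            exp = pool_brute_force(mat.theta, mat.se)
            for col in ("theta_bar", "W_bar", "B_bar", "V", "T"):
                np.testing.assert_allclose(got[col], exp[col], rtol=1e-12)

    def test_hand_example_two_imputations(self):
        mat = ImportanceMatrix(np.array([[1.0], [3.0]]), ["x"], "RF",
                               se=np.array([[1.0], [1.0]]))
        row = pool_importance(mat).iloc[0]
        assert row.theta_bar == pytest.approx(2.0)
        assert row.W_bar == pytest.approx(1.0)
        assert row.B_bar == pytest.approx(2.0)
        assert row.V == pytest.approx(4.0)
        assert row["T"] == pytest.approx(1.0)

    def test_constant_scores_have_no_between_variance(self):
        c, s = 3.0, 0.5
        mat = ImportanceMatrix(np.full((4, 1), c), ["x"], "RF",
                               se=np.full((4, 1), s))
        row = pool_importance(mat).iloc[0]
        assert row.B_bar == 0.0
        assert row.V == pytest.approx(s**2)
        assert row["T"] == pytest.approx(c / s)

    def test_scale_invariance_of_t(self):
        rng = np.random.default_rng(1)
        mat = random_matrix(rng, M=6, p=5)
        scaled = ImportanceMatrix(7.3 * mat.theta, mat.variable_names, "RF",
                                  se=7.3 * mat.se)
        np.testing.assert_allclose(
            pool_importance(mat)["T"], pool_importance(scaled)["T"], rtol=1e-12
        )

    def test_zero_variance_gives_zero_t(self):
        mat = ImportanceMatrix(np.zeros((3, 2)), ["a", "b"], "RF",
                               se=np.zeros((3, 2)))
        assert (pool_importance(mat)["T"] == 0.0).all()

    def test_preconditions(self):
        one = ImportanceMatrix(np.ones((1, 2)), ["a", "b"], "RF",
                               se=np.ones((1, 2)))
        with pytest.raises(ValueError, match="M >= 2"):
            pool_importance(one)
        no_se = ImportanceMatrix(np.ones((3, 2)), ["a", "b"], "GBM")
        with pytest.raises(ValueError, match="standard errors"):
            pool_importance(no_se)


class TestRankSummary:
    def test_always_top_variable_gets_null_interval(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, 1, size=(10, 6))
        theta[:, 0] = 5.0  # dominant in every imputation
        mat = ImportanceMatrix(theta, [f"v{j}" for j in range(6)], "RF")
        row = rank_summary(mat).set_index("variable").loc["v0"]
        assert (row.mean_rank, row.ci_low, row.ci_high) == (1, 1, 1)

    def test_alternating_pair_rounds_half_up(self):
        theta = np.array([[2.0, 1.0], [1.0, 2.0]] * 2)  # M=4, alternating
        mat = ImportanceMatrix(theta, ["a", "b"], "RF")
        s = rank_summary(mat).set_index("variable")
        assert s.loc["a", "mean_rank_raw"] == pytest.approx(1.5)
        assert s.loc["a", "mean_rank"] == 2
        assert (s.loc["a", "ci_low"], s.loc["a", "ci_high"]) == (1, 2)

    def test_single_imputation_degenerate(self):
        mat = ImportanceMatrix(np.array([[3.0, 1.0, 2.0]]), ["a", "b", "c"], "RF")
        s = rank_summary(mat).set_index("variable")
        assert list(s["mean_rank"]) == [1, 3, 2]
        assert (s["ci_low"] == s["mean_rank"]).all()

    def test_within_imputation_ranks_are_permutations(self):
        rng = np.random.default_rng(3)
        mat = random_matrix(rng, M=8, p=7)
        ranks = rank_matrix(mat)
        for row in ranks:
            assert sorted(row) == list(range(1, 8))

    def test_exact_ties_get_average_ranks(self):
        mat = ImportanceMatrix(np.array([[1.0, 1.0, 0.0]]), ["a", "b", "c"], "RF")
        np.testing.assert_allclose(rank_matrix(mat)[0], [1.5, 1.5, 3.0])

    def test_adding_constant_improves_mean_rank(self):
        rng = np.random.default_rng(4)
        mat = random_matrix(rng, M=6, p=5)
        bumped = ImportanceMatrix(mat.theta.copy(), mat.variable_names, "RF")
        bumped.theta[:, 2] += 10.0
        before = rank_summary(mat).set_index("variable").loc["v2", "mean_rank_raw"]
        after = rank_summary(bumped).set_index("variable").loc["v2", "mean_rank_raw"]
        assert after <= before


def test_round_half_up_convention():
    np.testing.assert_array_equal(round_half_up([1.5, 2.5, 2.4, -0.5]), [2, 3, 2, 0])


def test_planted_t_exceeds_null_t_across_seeds():
    """Pooled standardized scores separate a strong signal from nulls."""
    from mivip.forest import RFConfig, fit_rf_arrays, permutation_importance_oob
    from mivip.impute import multiply_impute
    from mivip.synthetic import generate_cohort, inject_missingness
    from conftest import small_spec

    wins = 0
    n_seeds = 20
    for seed in range(n_seeds):
        spec = small_spec(n=300, p_null=19, seed=seed, noise_sd=1.0)
        table = inject_missingness(generate_cohort(spec), seed=seed + 100)
        imp = multiply_impute(table, M=5, seed=seed + 200, n_trees=10, max_iter=2)
        theta = np.zeros((5, table.p))
        se = np.zeros_like(theta)
        for m, complete in enumerate(imp.tables):
            fit = fit_rf_arrays(
                complete.encode_numeric().to_numpy(), complete.outcome,
                table.predictor_names,
                RFConfig(n_trees=100, n_permutations=3, seed=seed + 300 + m),
            )
            res = permutation_importance_oob(fit)
            theta[m] = res["theta_hat"]
            se[m] = res["se"]
        pooled = pool_importance(
            ImportanceMatrix(theta, table.predictor_names, "RF", se=se)
        ).set_index("variable")
        t_signal = pooled.loc["signal", "T"]
        t_null_max = pooled.drop("signal")["T"].max()
        wins += t_signal > t_null_max
    assert wins >= 19  # >= 95% of seeds
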