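import numpy as np
import pandas as pd
import pytest

from mivip.forest import (
    RFConfig,
    calibration_line,
    fit_rf_arrays,
    fit_rf_oob,
    oob_pseudo_r2,
    permutation_importance_oob,
)

from _oracles import permutation_importance_brute_force


def planted_arrays(n=500, p=6, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X[:, 0] + rng.normal(scale=noise, size=n)
    return X, y, [f"x{j}" for j in range(p)]


class TestFit:
    def test_constant_outcome_gives_constant_oob_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 3))
        y = np.full(100, 4.2)
        fit = fit_rf_arrays(X, y, ["a", "b", "c"], RFConfig(n_trees=60, seed=0))
        ok = ~np.isnan(fit.oob_predictions)
        assert np.allclose(fit.oob_predictions[ok], 4.2)

    def test_same_seed_identical_oob_vector(self):
        X, y, names = planted_arrays()
        cfg = RFConfig(n_trees=80, seed=5)
        a = fit_rf_arrays(X, y, names, cfg)
        b = fit_rf_arrays(X, y, names, cfg)
        np.testing.assert_array_equal(a.oob_predictions, b.oob_predictions)

    def test_strong_signal_high_pseudo_r2(self):
        X, y, names = planted_arrays(noise=0.2)
        fit = fit_rf_arrays(X, y, names, RFConfig(n_trees=300, seed=2))
        assert oob_pseudo_r2(fit) > 0.8

    def test_table_interface_rejects_missing(self, masked_small_table):
        with pytest.raises(ValueError, match="complete"):
            fit_rf_oob(masked_small_table, RFConfig(n_trees=5))


class TestPseudoR2:
    def test_perfect_and_mean_predictions(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=50)
        fit = fit_rf_arrays(rng.normal(size=(50, 2)), y, ["a", "b"],
                            RFConfig(n_trees=30, seed=0))
        fit.oob_predictions = y.copy()
        assert oob_pseudo_r2(fit) == pytest.approx(1.0)
        fit.oob_predictions = np.full(50, y.mean())
        assert oob_pseudo_r2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_outcome_rejected(self):
        fit = fit_rf_arrays(np.random.default_rng(0).normal(size=(40, 2)),
                            np.zeros(40), ["a", "b"], RFConfig(n_trees=20, seed=0))
        with pytest.raises(ValueError, match="variance"):
            oob_pseudo_r2(fit)

    def test_pure_noise_outcome_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(300, 20))
            y = rng.normal(size=300)
            fit = fit_rf_arrays(X, y, [f"x{j}" for j in range(20)],
                                RFConfig(n_trees=120, seed=seed))
            vals.append(oob_pseudo_r2(fit))
        assert np.mean(vals) <= 0.1


class TestCalibrationLine:
    def test_identity_affine_and_attenuation(self):
        rng = np.random.default_rng(4)
        obs = rng.normal(size=200)
        i0, s0 = calibration_line(obs, obs)
        assert (i0, s0) == (pytest.approx(0, abs=1e-10), pytest.approx(1))
        i1, s1 = calibration_line(2 * obs + 3, obs)
        assert (i1, s1) == (pytest.approx(3), pytest.approx(2))
        shrunk = obs.mean() + 0.5 * (obs - obs.mean())
        _, s2 = calibration_line(shrunk, obs)
        assert s2 == pytest.approx(0.5)

    def test_direction_flip(self):
        rng = np.random.default_rng(5)
        obs = rng.normal(size=100)
        pred = 0.5 * obs + rng.normal(scale=0.1, size=100)
        _, fwd = calibration_line(pred, obs, "predicted_on_observed")
        _, rev = calibration_line(pred, obs, "observed_on_predicted")
        assert fwd != pytest.approx(rev)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            calibration_line(np.ones(10), np.ones(10))


class TestPermutationImportance:
    def test_null_variable_within_three_se_of_zero(self):
        X, y, names = planted_arrays(n=500)
        fit = fit_rf_arrays(X, y, names, RFConfig(n_trees=150, seed=6))
        imp = permutation_importance_oob(fit, K=5, seed=6).set_index("variable")
        for nm in names[1:]:
            row = imp.loc[nm]
            assert abs(row.theta_hat) <= 3 * max(row.se, 1e-12)

    def test_planted_variable_dominates(self):
        X, y, names = planted_arrays(n=500, noise=0.1)
        fit = fit_rf_arrays(X, y, names, RFConfig(n_trees=150, seed=7))
        imp = permutation_importance_oob(fit, K=5, seed=7).set_index("variable")
        top = imp.loc["x0"]
        for nm in names[1:]:
            row = imp.loc[nm]
            assert top.theta_hat > row.theta_hat + 3 * row.se

    def test_more_permutations_reduce_replicate_variance(self):
        X, y, names = planted_arrays(n=150, p=4, seed=8)
        fit = fit_rf_arrays(X, y, names, RFConfig(n_trees=60, seed=8))
        t1 = [permutation_importance_oob(fit, K=1, seed=s)["theta_hat"][0]
              for s in range(20)]
        t5 = [permutation_importance_oob(fit, K=5, seed=s)["theta_hat"][0]
              for s in range(20)]
        assert np.var(t5) < np.var(t1)

    def test_matches_brute_force_on_tiny_forest(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 2))
        y = X[:, 0] + 0.5 * rng.normal(size=12)
        fit = fit_rf_arrays(X, y, ["a", "b"], RFConfig(n_trees=2, seed=3))
        got = permutation_importance_oob(fit, K=2, seed=11).set_index("variable")
        expected = permutation_importance_brute_force(fit, K=2, seed=11)
        for nm in ("a", "b"):
            assert got.loc[nm, "theta_hat"] == pytest.approx(expected[nm][0], rel=1e-10)
            assert got.loc[nm, "se"] == pytest.approx(expected[nm][1], rel=1e-10)

    def test_evaluation_order_does_not_matter(self):
        X, y, names = planted_arrays(n=100, p=4)
        fit = fit_rf_arrays(X, y, names, RFConfig(n_trees=30, seed=10))
        fwd = permutation_importance_oob(fit, K=2, seed=1).set_index("variable")
        rev = permutation_importance_oob(
            fit, K=2, seed=1, variables=list(reversed(names))
        ).set_index("variable")
        pd.testing.assert_frame_equal(fwd.sort_index(), rev.sort_index())

    def test_constant_column_scores_exactly_zero(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(80, 3))
        X[:, 2] = 7.0
        y = X[:, 0]
        fit = fit_rf_arrays(X, y, ["a", "b", "const"], RFConfig(n_trees=40, seed=0))
        imp = permutation_importance_oob(fit, K=3, seed=0).set_index("variable")
        assert imp.loc["const", "theta_hat"] == 0.0
        assert imp.loc["const", "se"] == 0.0
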