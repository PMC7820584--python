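import numpy as np
import pandas as pd
import pytest

from mivip.cohort import CohortTable, VariableSpec
from mivip.synthetic import (
    CohortSpec,
    demo_spec,
    generate_cohort,
    inject_missingness,
    oracle_ranking,
    study_spec,
)

from conftest import small_spec


class TestGenerateCohort:
    def test_shape_and_dictionary_round_trip(self, tmp_path):
        spec = demo_spec(n_subjects=300, seed=7)
        table = generate_cohort(spec)
        assert table.n == 300
        assert table.p == 50
        assert table.data.shape == (300, 51)
        table.to_csv(tmp_path / "c.csv", tmp_path / "d.json")
        back = CohortTable.from_csv(tmp_path / "c.csv", tmp_path / "d.json")
        assert back.predictor_names == table.predictor_names
        assert [v.var_type for v in back.variables] == [v.var_type for v in table.variables]
        pd.testing.assert_frame_equal(
            back.data[table.data.columns], table.data, check_dtype=False
        )

    def test_zero_noise_single_effect_is_exact_affine(self):
        spec = CohortSpec(
            n_subjects=100,
            variables=[VariableSpec("x1", effect=3.0), VariableSpec("x2")],
            noise_sd=0.0, outcome_name="y", seed=5,
        )
        table = generate_cohort(spec)
        r = np.corrcoef(table.data["x1"], table.outcome)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-12

    def test_genotype_risk_allele_frequency(self):
        maf = 0.25
        spec = CohortSpec(
            n_subjects=10_000,
            variables=[VariableSpec("snp", var_type="genotype",
                                    alleles=("A", "G"), risk_allele="G", maf=maf)],
            outcome_name="y", seed=11,
        )
        table = generate_cohort(spec)
        freq = table.encode_numeric()["snp"].sum() / (2 * table.n)
        se = np.sqrt(maf * (1 - maf) / (2 * table.n))
        assert abs(freq - maf) < 3 * se

    def test_same_seed_bit_identical(self):
        spec = demo_spec(seed=3)
        a, b = generate_cohort(spec), generate_cohort(spec)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_null_variables_independent_of_outcome(self):
        spec = small_spec(n=10_000, p_null=5, missing_rate=0.0, seed=2)
        table = generate_cohort(spec)
        enc = table.encode_numeric()
        for name in [v.name for v in spec.variables if v.effect == 0.0]:
            r = np.corrcoef(enc[name], table.outcome)[0, 1]
            assert abs(r) < 2 * 3 / np.sqrt(table.n)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CohortSpec(
                n_subjects=10,
                variables=[VariableSpec("x"), VariableSpec("x")],
                outcome_name="y",
            )

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            CohortSpec(n_subjects=0, variables=[VariableSpec("x")], outcome_name="y")

    def test_study_scale_layout(self):
        spec = study_spec()
        table = generate_cohort(spec)
        assert table.n == 221
        assert table.p == 200  # 189 non-genetic + 11 SNPs -> 190 modeled after GRS
        domains = pd.Series([v.domain for v in spec.variables]).value_counts()
        assert domains["genetics"] == 11
        assert domains["diet"] == 80


class TestInjectMissingness:
    def test_zero_rates_identity(self, complete_small_table):
        out = inject_missingness(complete_small_table, seed=9)
        pd.testing.assert_frame_equal(out.data, complete_small_table.data)

    def test_mcar_rate_within_binomial_bound(self):
        spec = small_spec(n=5000, p_null=1, missing_rate=0.2, seed=4)
        table = inject_missingness(generate_cohort(spec), seed=5)
        frac = table.data["signal"].isna().mean()
        se = np.sqrt(0.2 * 0.8 / 5000)
        assert abs(frac - 0.2) < 3 * se

    def test_outcome_never_masked(self, masked_small_table):
        assert masked_small_table.data["y"].notna().all()

    def test_mar_marginal_rate_calibrated_and_driver_dependent(self):
        variables = [VariableSpec("driver", missing_rate=0.0),
                     VariableSpec("target", missing_rate=0.3)]
        spec = CohortSpec(n_subjects=8000, variables=variables, outcome_name="y", seed=6)
        table = inject_missingness(generate_cohort(spec), "MAR", seed=7,
                                   mar_driver="driver")
        mask = table.data["target"].isna().to_numpy()
        assert abs(mask.mean() - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 8000)
        z = table.data["driver"].to_numpy()
        assert z[mask].mean() > z[~mask].mean()  # monotone dependence

    def test_mar_driver_with_missingness_rejected(self, masked_small_table):
        with pytest.raises(ValueError, match="driver"):
            inject_missingness(masked_small_table, "MAR", seed=0, mar_driver="signal")

    def test_dictionary_consistency_after_injection(self, mixed_table):
        out = inject_missingness(mixed_table, seed=12)
        out.validate()
        # masked cells are the only missing entries beyond the original table
        assert out.missing_mask.to_numpy().sum() >= 0
        for v in out.variables:
            observed = out.data[v.name].dropna()
            if v.var_type == "categorical":
                assert set(observed) <= set(v.levels)
            elif v.var_type == "genotype":
                assert set("".join(observed)) <= set(v.alleles)


class TestOracleRanking:
    def test_effect_magnitude_order(self):
        spec = CohortSpec(
            n_subjects=10,
            variables=[VariableSpec("x1", effect=3), VariableSpec("x2", effect=1),
                       VariableSpec("x3"), VariableSpec("x4")],
            outcome_name="y",
        )
        assert oracle_ranking(spec)[:2] == ["x1", "x2"]

    def test_all_null_is_lexicographic_with_warning(self):
        spec = CohortSpec(
            n_subjects=10,
            variables=[VariableSpec("b"), VariableSpec("a")],
            outcome_name="y",
        )
        with pytest.warns(UserWarning, match="null"):
            assert oracle_ranking(spec) == ["a", "b"]

    def test_sign_tie_broken_lexicographically(self):
        spec = CohortSpec(
            n_subjects=10,
            variables=[VariableSpec("b", effect=2.0), VariableSpec("a", effect=-2.0)],
            outcome_name="y",
        )
        assert oracle_ranking(spec) == ["a", "b"]
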