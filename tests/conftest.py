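import numpy as np
import pandas as pd
import pytest

from mivip.cohort import CohortTable, VariableSpec
from mivip.synthetic import CohortSpec, generate_cohort, inject_missingness


def small_spec(n=200, p_null=8, seed=0, missing_rate=0.1, noise_sd=1.0):
    """Compact cohort: one strong planted continuous effect plus nulls."""
    variables = [
        VariableSpec("signal", effect=2.0, missing_rate=missing_rate),
    ] + [
        VariableSpec(f"null_{i:02d}", missing_rate=missing_rate)
        for i in range(p_null)
    ]
    return CohortSpec(
        n_subjects=n, variables=variables, noise_sd=noise_sd,
        outcome_name="y", seed=seed,
    )


@pytest.fixture
def complete_small_table():
    return generate_cohort(small_spec(missing_rate=0.0))


@pytest.fixture
def masked_small_table():
    return inject_missingness(generate_cohort(small_spec()), seed=1)


@pytest.fixture
def mixed_table():
    """Complete table with continuous, categorical and genotype columns."""
    variables = [
        VariableSpec("x_cont", effect=1.5, missing_rate=0.1),
        VariableSpec(
            "x_cat", var_type="categorical", levels=("a", "b", "c"),
            missing_rate=0.1,
        ),
        VariableSpec(
            "snp1", var_type="genotype", alleles=("G", "T"), risk_allele="T",
            maf=0.3, missing_rate=0.1,
        ),
        VariableSpec("x_null", missing_rate=0.1),
    ]
    spec = CohortSpec(n_subjects=150, variables=variables, noise_sd=0.5,
                      outcome_name="y", seed=3)
    return generate_cohort(spec)
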