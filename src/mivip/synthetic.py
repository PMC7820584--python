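"""Synthetic cohort generator with planted effects and controlled missingness.

Emulates a pediatric-obesity style cohort: a few hundred subjects, a mixed
bag of continuous questionnaire/nutrient variables, categorical items, and
an 11-SNP genotype panel, with one continuous outcome (BMI-like) generated
by an additive linear link on standardized predictor encodings plus
Gaussian noise.  Because effects are planted, the true importance ordering
is known (``oracle_ranking``), which is what makes the downstream
importance pipeline testable end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import (
    CATEGORICAL,
    CONTINUOUS,
    GENOTYPE,
    CohortTable,
    VariableSpec,
    genotype_string,
)

MCAR = "MCAR"
MAR = "MAR"


@dataclass
class CohortSpec:
    """Full recipe for one synthetic cohort.

    The outcome is ``outcome_mean + sum_j effect_j * z_j + N(0, noise_sd)``
    where ``z_j`` is the empirically standardized numeric encoding of
    predictor ``j`` (z-scored continuous values, z-scored ordinal category
    codes, risk-allele counts).  Standardizing makes ``|effect|`` comparable
    across variable types, so the oracle ranking is well defined.
    """

    n_subjects: int
    variables: list = field(default_factory=list)
    noise_sd: float = 1.0
    outcome_name: str = "bmi"
    outcome_mean: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({x for x in names if names.count(x) > 1})
            raise ValueError(f"duplicate variable names: {dupes}")
        if self.outcome_name in names:
            raise ValueError("outcome name collides with a predictor")


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a complete (pre-missingness) cohort table; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    cols = {}
    signal = np.zeros(n)
    for v in spec.variables:
        if v.var_type == CONTINUOUS:
            x = rng.normal(size=n)
            enc = x
            cols[v.name] = x
        elif v.var_type == CATEGORICAL:
            codes = rng.integers(0, len(v.levels), size=n)
            enc = codes.astype(float)
            cols[v.name] = np.array([v.levels[c] for c in codes], dtype=object)
        else:  # genotype: risk-allele count ~ Binomial(2, maf)
            counts = rng.binomial(2, v.maf, size=n)
            enc = counts.astype(float)
            other = v.alleles[0] if v.alleles[1] == v.risk_allele else v.alleles[1]
            cols[v.name] = np.array(
                [genotype_string(v.risk_allele, other, int(c)) for c in counts],
                dtype=object,
            )
        if v.effect != 0.0:
            sd = enc.std()
            if sd > 0:
                signal = signal + v.effect * (enc - enc.mean()) / sd
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
    cols[spec.outcome_name] = spec.outcome_mean + signal + noise
    df = pd.DataFrame(cols)
    return CohortTable(df, list(spec.variables), spec.outcome_name)


def inject_missingness(
    table: CohortTable,
    mechanism: str = MCAR,
    seed: int = 0,
    mar_driver: str | None = None,
) -> CohortTable:
    """Mask predictor cells at each variable's declared rate.

    MCAR masks cells independently.  MAR makes the masking probability of
    each target column a logistic function of one complete continuous
    covariate's z-score (slope 1), with the intercept calibrated so the
    marginal rate equals the declared rate.  The outcome is never masked.
    """
    if mechanism not in (MCAR, MAR):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    out = table.copy()
    rng = np.random.default_rng(seed)
    n = table.n

    if mechanism == MAR:
        if mar_driver is None:
            candidates = [
                v for v in table.variables
                if v.var_type == CONTINUOUS and v.missing_rate == 0.0
            ]
            if not candidates:
                raise ValueError("MAR needs a complete continuous driver column")
            mar_driver = candidates[0].name
        driver_spec = table.spec_for(mar_driver)
        col = table.data[mar_driver]
        if driver_spec.missing_rate > 0 or col.isna().any():
            raise ValueError("MAR driver column must be complete")
        z = (col - col.mean()) / col.std(ddof=0)
        z = z.to_numpy(dtype=float)

    for v in table.variables:
        rate = v.missing_rate
        if rate <= 0.0:
            continue
        if mechanism == MCAR or v.name == mar_driver:
            prob = np.full(n, rate)
        else:
            a = brentq(lambda a: expit(a + z).mean() - rate, -40.0, 40.0)
            prob = expit(a + z)
        mask = rng.random(n) < prob
        out.data.loc[mask, v.name] = np.nan
    return out


def oracle_ranking(spec: CohortSpec) -> list:
    """Ground-truth names sorted by descending |effect|, ties lexicographic."""
    if all(v.effect == 0.0 for v in spec.variables):
        warnings.warn("all variables are null; oracle ranking is lexicographic only")
    return [v.name for v in sorted(spec.variables, key=lambda v: (-abs(v.effect), v.name))]


def spec_to_yaml(spec: CohortSpec, path) -> None:
    """Serialize a CohortSpec to YAML."""
    import yaml
    from dataclasses import asdict

    payload = {
        "n_subjects": spec.n_subjects,
        "noise_sd": spec.noise_sd,
        "outcome_name": spec.outcome_name,
        "outcome_mean": spec.outcome_mean,
        "seed": spec.seed,
        "variables": [
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(var).items()}
            for var in spec.variables
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def spec_from_yaml(path) -> CohortSpec:
    """Load a CohortSpec from YAML."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    variables = [
        VariableSpec(**{**d, "levels": tuple(d.get("levels", ())),
                        "alleles": tuple(d.get("alleles", ()))})
        for d in payload.pop("variables")
    ]
    return CohortSpec(variables=variables, **payload)


# ---------------------------------------------------------------------------
# Ready-made specs
# ---------------------------------------------------------------------------

#: alleles / risk alleles used for synthetic genotype columns; risk alleles
#: are a fixture convention (arrays report genotypes, not risk orientation).
_PANEL_SNPS = [
    ("rs925946", ("G", "T"), "T", 0.26),
    ("rs7647305", ("C", "T"), "T", 0.18),
    ("rs7190492", ("A", "G"), "A", 0.38),
    ("rs10938397", ("A", "G"), "G", 0.46),
    ("rs368794", ("A", "T"), "T", 0.34),
    ("rs1137101", ("A", "G"), "G", 0.43),
    ("rs17782313", ("C", "T"), "C", 0.17),
    ("rs2568958", ("A", "G"), "G", 0.37),
    ("rs10913469", ("C", "T"), "C", 0.19),
    ("rs7903146", ("C", "T"), "T", 0.34),
    ("rs6548238", ("C", "T"), "T", 0.20),
]


def panel_variable_specs(missing_rate: float = 0.0) -> list:
    """VariableSpecs for the 11-SNP obesity genotype panel."""
    return [
        VariableSpec(
            name=snp, var_type=GENOTYPE, domain="genetics",
            alleles=alleles, risk_allele=risk, maf=maf,
            missing_rate=missing_rate,
        )
        for snp, alleles, risk, maf in _PANEL_SNPS
    ]


def demo_spec(
    n_subjects: int = 300,
    missing_rate: float = 0.10,
    noise_sd: float = 2.4,
    seed: int = 0,
) -> CohortSpec:
    """Test-scale cohort: 50 predictors, 3 planted strong continuous effects.

    The planted effects (2.0, 1.5, 1.0 on standardized encodings) against
    ``noise_sd=2.4`` put the forest's explainable variance near one half,
    similar to what a questionnaire-plus-genetics BMI model attains.
    """
    mr = missing_rate
    variables = [
        VariableSpec("relation_tei_tee", CONTINUOUS, "diet", effect=2.0, missing_rate=mr),
        VariableSpec("bmi_mother", CONTINUOUS, "social", effect=1.5, missing_rate=mr),
        VariableSpec("bmi_father", CONTINUOUS, "social", effect=1.0, missing_rate=mr),
    ]
    for i in range(30):
        variables.append(
            VariableSpec(f"nutrient_{i:02d}", CONTINUOUS, "diet", missing_rate=mr)
        )
    for i in range(6):
        k = 2 + i % 3
        variables.append(
            VariableSpec(
                f"habit_{i}", CATEGORICAL, "social",
                levels=tuple(f"lvl{j}" for j in range(k)), missing_rate=mr,
            )
        )
    for snp in panel_variable_specs(missing_rate=mr):
        variables.append(snp)
    return CohortSpec(
        n_subjects=n_subjects,
        variables=variables,
        noise_sd=noise_sd,
        outcome_name="bmi",
        outcome_mean=16.9,
        seed=seed,
    )


def study_spec(n_subjects: int = 221, seed: int = 0) -> CohortSpec:
    """Study-scale cohort: 221 subjects, 200 raw columns (189 + 11 SNPs).

    Domain mix mirrors a multidomain childhood-obesity survey: subject
    characteristics (3), genetics (11 SNPs, later collapsed to one GRS),
    physical/leisure activity (24), diet/food/nutrients (80), pregnancy and
    birth (39), social/health/demographic (43).  A handful of planted
    effects echo the kinds of variables such studies rank on top (energy
    balance, parental BMI, activity score, a genetic risk score loading
    spread over the panel).
    """
    planted = {
        "familiar_nutristatus_perception": 1.6,
        "relation_tei_tee": 1.4,
        "bmi_mother": 1.1,
        "bmi_father": 1.0,
        "mothers_meals": 0.7,
        "prot_pct_tei": 0.5,
        "ipac": 0.5,
    }
    variables = [
        VariableSpec("age", CONTINUOUS, "characteristics"),
        VariableSpec("sex", CATEGORICAL, "characteristics", levels=("girl", "boy")),
        VariableSpec("school_year", CATEGORICAL, "characteristics", levels=("first", "second")),
        VariableSpec(
            "familiar_nutristatus_perception", CATEGORICAL, "social",
            levels=("thin", "normal", "overweight"),
            effect=planted["familiar_nutristatus_perception"], missing_rate=0.05,
        ),
    ]
    # each panel SNP carries a small equal loading so the aggregate genetic
    # risk score is informative without any single SNP dominating
    for snp in panel_variable_specs(missing_rate=0.02):
        variables.append(
            VariableSpec(
                snp.name, GENOTYPE, "genetics", effect=0.12, missing_rate=0.02,
                alleles=snp.alleles, risk_allele=snp.risk_allele, maf=snp.maf,
            )
        )
    domains = [
        ("activity", 24, 0.08),
        ("diet", 80, 0.08),
        ("pregnancy_birth", 39, 0.10),
        ("social", 42, 0.06),  # 42 + nutristatus perception above = 43
    ]
    named = {
        "activity": ["ipac", "sleeping_hours", "tawh", "tee"],
        "diet": ["relation_tei_tee", "prot_pct_tei", "vitamin_d", "kidmed_index"],
        "pregnancy_birth": ["birth_weight", "breastfeeding_months"],
        "social": ["bmi_mother", "bmi_father", "mothers_meals", "mother_htg"],
    }
    rng = np.random.default_rng(12345)  # fixed: layout, not data
    for domain, count, mr in domains:
        names = list(named.get(domain, []))
        names += [f"{domain}_{i:02d}" for i in range(count - len(names))]
        for nm in names:
            if nm == "mother_htg":
                variables.append(
                    VariableSpec(nm, CATEGORICAL, domain, levels=("no", "yes"),
                                 effect=0.0, missing_rate=mr)
                )
            elif rng.random() < 0.15:
                k = int(rng.integers(2, 5))
                variables.append(
                    VariableSpec(nm, CATEGORICAL, domain,
                                 levels=tuple(f"lvl{j}" for j in range(k)),
                                 effect=planted.get(nm, 0.0), missing_rate=mr)
                )
            else:
                variables.append(
                    VariableSpec(nm, CONTINUOUS, domain,
                                 effect=planted.get(nm, 0.0), missing_rate=mr)
                )
    return CohortSpec(
        n_subjects=n_subjects,
        variables=variables,
        noise_sd=2.3,
        outcome_name="bmi",
        outcome_mean=16.9,
        seed=seed,
    )
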