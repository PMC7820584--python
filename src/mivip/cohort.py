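"""Typed cohort tables: subjects x mixed-type variables with one continuous outcome.

A :class:`CohortTable` is a thin wrapper around a :class:`pandas.DataFrame`
plus a data dictionary (:class:`VariableSpec` per column) declaring each
column's type and domain.  Missing cells are plain ``NaN``; the outcome
column is continuous and never missing.  The table knows how to encode
itself into a numeric matrix for tree models (continuous values pass
through, categorical levels become ordinal codes, genotypes become
risk-allele counts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
GENOTYPE = "genotype"
VAR_TYPES = (CONTINUOUS, CATEGORICAL, GENOTYPE)


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one predictor column.

    Parameters
    ----------
    name : str
        Column identifier, unique within a cohort.
    var_type : str
        One of ``continuous``, ``categorical``, ``genotype``.
    domain : str
        Free-form domain tag (``"diet"``, ``"social"``, ...).
    effect : float
        Signed contribution weight of the (standardized) encoded column to
        the simulated outcome; 0 marks a null variable.
    missing_rate : float
        Target marginal missingness rate in ``[0, 1)``.
    levels : tuple of str
        Categorical level labels (k >= 2); encoding order follows this tuple.
    alleles : tuple of str
        The two allele letters of a genotype variable.
    risk_allele : str
        Which allele counts toward the genetic risk score.  In simulation the
        risk allele is drawn with frequency ``maf`` (i.e. it is the minor
        allele of the simulated population).
    maf : float
        Simulated minor-allele frequency, in ``(0, 0.5]``.
    """

    name: str
    var_type: str = CONTINUOUS
    domain: str = ""
    effect: float = 0.0
    missing_rate: float = 0.0
    levels: tuple = ()
    alleles: tuple = ()
    risk_allele: str = ""
    maf: float = 0.0

    def __post_init__(self):
        if self.var_type not in VAR_TYPES:
            raise ValueError(f"unknown var_type {self.var_type!r}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"{self.name}: missing_rate must be in [0, 1)")
        if self.var_type == CATEGORICAL:
            if len(self.levels) < 2:
                raise ValueError(f"{self.name}: categorical needs >= 2 levels")
        if self.var_type == GENOTYPE:
            if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
                raise ValueError(f"{self.name}: genotype needs two distinct alleles")
            if self.risk_allele not in self.alleles:
                raise ValueError(f"{self.name}: risk allele not among alleles")
            if not (0.0 < self.maf <= 0.5):
                raise ValueError(f"{self.name}: maf must be in (0, 0.5]")


@dataclass
class CohortTable:
    """Rectangle of typed values plus its data dictionary.

    ``data`` holds predictors and the outcome column; missing entries are
    ``NaN``.  ``variables`` declares the predictors only; the outcome is a
    complete continuous column named ``outcome_name``.
    """

    data: pd.DataFrame
    variables: list  # list[VariableSpec]
    outcome_name: str

    def __post_init__(self):
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate variable names: {dupes}")
        if self.outcome_name in names:
            raise ValueError("outcome must not appear among predictors")
        expected = names + [self.outcome_name]
        if sorted(self.data.columns) != sorted(expected):
            raise ValueError("table columns do not match the dictionary")
        if len(self.data) == 0 or not names:
            raise ValueError("empty cohort")
        if self.data[self.outcome_name].isna().any():
            raise ValueError("outcome column must be complete")

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def predictor_names(self) -> list:
        return [v.name for v in self.variables]

    @property
    def outcome(self) -> np.ndarray:
        return self.data[self.outcome_name].to_numpy(dtype=float)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def spec_for(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), list(self.variables), self.outcome_name)

    # -- numeric encoding --------------------------------------------------
    def encode_numeric(self, include_outcome: bool = False) -> pd.DataFrame:
        """Encode the table as floats for tree models.

        Continuous columns pass through; categorical levels become their
        index in the declared level order; genotype strings become the count
        of risk-allele letters (0/1/2).  ``NaN`` cells stay ``NaN``.
        """
        out = {}
        for v in self.variables:
            out[v.name] = encode_column(self.data[v.name], v)
        if include_outcome:
            out[self.outcome_name] = self.data[self.outcome_name].astype(float)
        return pd.DataFrame(out, index=self.data.index)

    def decode_column(self, name: str, codes: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`encode_numeric` for one column (exact codes)."""
        return decode_column(codes, self.spec_for(name))

    # -- persistence -------------------------------------------------------
    def to_csv(self, csv_path, dictionary_path=None) -> None:
        """Write values as CSV (empty cell = missing) and the dictionary as JSON."""
        cols = self.predictor_names + [self.outcome_name]
        self.data[cols].to_csv(csv_path, index=False, na_rep="")
        if dictionary_path is not None:
            payload = {
                "outcome": self.outcome_name,
                "variables": [asdict(v) for v in self.variables],
            }
            Path(dictionary_path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_csv(cls, csv_path, dictionary_path) -> "CohortTable":
        payload = json.loads(Path(dictionary_path).read_text())
        variables = [
            VariableSpec(**{**d, "levels": tuple(d["levels"]), "alleles": tuple(d["alleles"])})
            for d in payload["variables"]
        ]
        dtypes = {
            v.name: (float if v.var_type == CONTINUOUS else str) for v in variables
        }
        dtypes[payload["outcome"]] = float
        df = pd.read_csv(csv_path, dtype=dtypes, keep_default_na=True)
        # empty strings from the CSV round-trip mean missing for string columns
        for v in variables:
            if v.var_type != CONTINUOUS:
                col = df[v.name]
                df[v.name] = col.where(~col.isin(["", "nan"]) & col.notna(), np.nan)
        return cls(df, variables, payload["outcome"])


def encode_column(series: pd.Series, spec: VariableSpec) -> pd.Series:
    if spec.var_type == CONTINUOUS:
        return series.astype(float)
    if spec.var_type == CATEGORICAL:
        mapping = {lvl: float(i) for i, lvl in enumerate(spec.levels)}
        enc = series.map(mapping)
        bad = series.notna() & enc.isna()
        if bad.any():
            raise ValueError(f"{spec.name}: undeclared level {series[bad].iloc[0]!r}")
        return enc.astype(float)
    # genotype: count risk-allele letters after orientation-normalizing
    risk = spec.risk_allele
    allowed = set(spec.alleles)

    def count(g):
        if g is None or (isinstance(g, float) and np.isnan(g)):
            return np.nan
        g = str(g)
        if len(g) != 2 or not set(g) <= allowed:
            raise ValueError(f"{spec.name}: invalid genotype {g!r}")
        return float(g.count(risk))

    return series.map(count).astype(float)


def decode_column(codes: np.ndarray, spec: VariableSpec) -> np.ndarray:
    """Map integer codes back to the column's native representation."""
    codes = np.asarray(codes)
    if spec.var_type == CONTINUOUS:
        return codes.astype(float)
    if spec.var_type == CATEGORICAL:
        return np.array([spec.levels[int(round(c))] for c in codes], dtype=object)
    other = spec.alleles[0] if spec.alleles[1] == spec.risk_allele else spec.alleles[1]
    return np.array(
        [genotype_string(spec.risk_allele, other, int(round(c))) for c in codes],
        dtype=object,
    )


def genotype_string(risk: str, other: str, n_risk: int) -> str:
    """Two-letter genotype with ``n_risk`` copies of the risk allele, letters sorted."""
    if n_risk not in (0, 1, 2):
        raise ValueError("risk-allele count must be 0, 1 or 2")
    return "".join(sorted(risk * n_risk + other * (2 - n_risk)))
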