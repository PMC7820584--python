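"""Genotype-panel utilities: MAF, Hardy-Weinberg screening, genetic risk score.

The genetic risk score (GRS) is the unweighted sum over a SNP panel of each
subject's risk-allele counts, ``GRS = sum_i NRA_i`` with ``NRA_i`` in
{0, 1, 2}.  Panels are screened per SNP with the minor allele frequency
(MAF) and a 1-df chi-square goodness-of-fit test against Hardy-Weinberg
proportions (q^2, 2pq, p^2).

The module also bundles the published genotype distribution of the 11-SNP
childhood-obesity panel (BDNF-AS, ETV5, FTO, GNPDA2, KCTD15, LEPR, MC4R,
NEGR1, SEC16B, TCF7L2, TMEM18 variants) as genotype percentages at the
reported per-SNP sample sizes, so the MAF/HWE arithmetic can be exercised
against printed reference values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2


@dataclass(frozen=True)
class SNPDef:
    """Identity of one SNP: its two alleles and which one carries risk."""

    snp_id: str
    alleles: tuple
    risk_allele: str

    def __post_init__(self):
        if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
            raise ValueError(f"{self.snp_id}: need two distinct alleles")
        if self.risk_allele not in self.alleles:
            raise ValueError(f"{self.snp_id}: risk allele not among alleles")

    @property
    def other_allele(self) -> str:
        return self.alleles[0] if self.alleles[1] == self.risk_allele else self.alleles[1]

    def complement(self) -> "SNPDef":
        """Same SNP with the risk label on the opposite allele."""
        return SNPDef(self.snp_id, self.alleles, self.other_allele)


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts, oriented as (major hom, het, minor hom)."""

    n_hom_major: int
    n_het: int
    n_hom_minor: int

    def __post_init__(self):
        if min(self.n_hom_major, self.n_het, self.n_hom_minor) < 0:
            raise ValueError("negative genotype count")
        if self.total == 0:
            raise ValueError("all-zero genotype counts")

    @property
    def total(self) -> int:
        return self.n_hom_major + self.n_het + self.n_hom_minor


@dataclass(frozen=True)
class GRSValue:
    """One subject's genetic risk score over a panel."""

    value: int
    n_snps_used: int
    n_missing_snps: int

    def __post_init__(self):
        if not (0 <= self.value <= 2 * self.n_snps_used):
            raise ValueError("GRS outside [0, 2 * n_snps_used]")


def minor_allele_frequency(counts: GenotypeCounts) -> float:
    """MAF = (het + 2 * minor hom) / (2 * n); auto-reoriented to <= 0.5.

    If the supplied orientation gives a frequency above one half, the
    major/minor labels are swapped and the complement returned, so the
    result is invariant under mislabeled orientation.
    """
    freq = (counts.n_het + 2 * counts.n_hom_minor) / (2 * counts.total)
    return min(freq, 1.0 - freq)


def hwe_chi_square(counts: GenotypeCounts) -> tuple:
    """1-df chi-square of observed genotype counts vs Hardy-Weinberg.

    Expected counts are (p^2 n, 2pq n, q^2 n) with q the MAF estimated from
    the same counts (one estimated parameter -> 1 df).  No continuity
    correction.  Monomorphic input has no degree of freedom left; that is
    signalled with a ``ValueError`` rather than a fabricated p-value.
    """
    n = counts.total
    q = minor_allele_frequency(counts)
    if q == 0.0:
        raise ValueError("monomorphic SNP: HWE statistic undefined")
    p = 1.0 - q
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    # orient observed to match the (major, het, minor) expectation
    if counts.n_hom_minor <= counts.n_hom_major:
        observed = np.array([counts.n_hom_major, counts.n_het, counts.n_hom_minor])
    else:
        observed = np.array([counts.n_hom_minor, counts.n_het, counts.n_hom_major])
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))


def genetic_risk_score(genotypes: dict, panel: list) -> GRSValue:
    """Sum risk-allele counts over a panel; missing SNPs excluded and counted.

    ``genotypes`` maps snp_id -> two-letter genotype string (letter order
    irrelevant) or ``None``/``NaN`` for missing.
    """
    value = 0
    used = 0
    missing = 0
    for snp in panel:
        g = genotypes.get(snp.snp_id)
        if g is None or (isinstance(g, float) and np.isnan(g)):
            missing += 1
            continue
        g = "".join(sorted(str(g)))
        if len(g) != 2 or not set(g) <= set(snp.alleles):
            raise ValueError(f"{snp.snp_id}: invalid genotype {g!r}")
        value += g.count(snp.risk_allele)
        used += 1
    return GRSValue(value=value, n_snps_used=used, n_missing_snps=missing)


def grs_column(genotype_frame: pd.DataFrame, panel: list) -> pd.Series:
    """Per-subject GRS over a genotype DataFrame (columns = snp_ids).

    Subjects missing any panel SNP get ``NaN`` (left for the imputation
    stage to fill, rather than silently rescoring on a shorter panel).
    """
    scores = []
    for _, row in genotype_frame.iterrows():
        g = genetic_risk_score(row.to_dict(), panel)
        scores.append(float(g.value) if g.n_missing_snps == 0 else np.nan)
    return pd.Series(scores, index=genotype_frame.index, name="grs")


# ---------------------------------------------------------------------------
# Published reference panel: genotype percentages and printed MAFs
# ---------------------------------------------------------------------------

#: snp_id -> (genotype % for (major hom, het, minor hom), per-SNP n, printed MAF).
#: Sample sizes are the integers at which the printed percentages produce
#: whole genotype counts (call rates > 96% of a 221-subject cohort).
REFERENCE_PANEL = {
    "rs925946": ((55.91, 36.82, 7.27), 220, 0.2568),
    "rs7647305": ((66.97, 29.41, 3.62), 221, 0.1833),
    "rs7190492": ((41.82, 40.91, 17.27), 220, 0.3773),
    "rs10938397": ((30.77, 46.15, 23.08), 221, 0.4615),
    "rs368794": ((43.44, 44.80, 11.76), 221, 0.3416),
    "rs1137101": ((31.82, 50.45, 17.73), 220, 0.4295),
    "rs17782313": ((68.64, 28.64, 2.73), 220, 0.1705),
    "rs2568958": ((41.18, 43.89, 14.93), 221, 0.3688),
    "rs10913469": ((67.27, 27.73, 5.00), 220, 0.1886),
    "rs7903146": ((44.29, 43.38, 12.33), 219, 0.3402),
    "rs6548238": ((65.91, 28.64, 5.45), 220, 0.1977),
}


def reconstruct_counts(percentages: tuple, n: int) -> GenotypeCounts:
    """Genotype counts from printed percentages at sample size ``n``."""
    counts = [int(round(pct * n / 100.0)) for pct in percentages]
    return GenotypeCounts(*counts)


def reference_counts(snp_id: str) -> GenotypeCounts:
    pcts, n, _ = REFERENCE_PANEL[snp_id]
    return reconstruct_counts(pcts, n)


def panel_qc_report(counts_by_snp: dict) -> pd.DataFrame:
    """Per-SNP QC table: n, MAF, HWE chi-square and p-value."""
    rows = []
    for snp_id, counts in counts_by_snp.items():
        stat, pval = hwe_chi_square(counts)
        rows.append(
            {
                "snp_id": snp_id,
                "n": counts.total,
                "maf": minor_allele_frequency(counts),
                "chi_square": stat,
                "p_value": pval,
            }
        )
    return pd.DataFrame(rows)


def read_snp_definitions(path) -> list:
    """Read a SNP definition TSV: snp_id, allele1, allele2, risk_allele."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"snp_id", "allele1", "allele2", "risk_allele"}
    if not required <= set(df.columns):
        raise ValueError(f"SNP definition file needs columns {sorted(required)}")
    return [
        SNPDef(r.snp_id, (r.allele1, r.allele2), r.risk_allele)
        for r in df.itertuples()
    ]
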