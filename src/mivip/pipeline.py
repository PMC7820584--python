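"""End-to-end orchestration: cohort -> imputations -> RF + GBM -> consensus.

The pipeline reproduces the full importance-ranking procedure on either a
synthetic cohort spec or a CSV + data-dictionary pair:

1. optionally collapse the genotype panel into one additive genetic risk
   score (GRS) predictor (subjects with an incomplete panel get a missing
   GRS for the imputation stage to fill);
2. impute the table M times with chained forests;
3. per imputation, fit the OOB forest (permutation importances with SEs,
   OOB pseudo-R^2) and the CV-sized boosting model (relative influence);
4. pool the forest importances (Rubin-style), summarize ranks for both
   methods, min-max normalize each method's matrix and average them into
   the consensus score;
5. write the machine-readable bundle (CSVs + run metadata) and the four
   plots (importance bars for each method, rank-CI plot, consensus bars,
   calibration scatter).

Everything is reproducible from (config, master seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boosting import GBMConfig, fit_gbm_cv, relative_importance
from .cohort import CONTINUOUS, GENOTYPE, CohortTable, VariableSpec
from .consensus import consensus_scores, minmax_normalize, top_k
from .forest import RFConfig, calibration_line, fit_rf_oob, oob_pseudo_r2, permutation_importance_oob
from .genetics import SNPDef, grs_column
from .impute import multiply_impute
from .pooling import ImportanceMatrix, pool_importance, rank_summary
from .synthetic import CohortSpec, generate_cohort, inject_missingness


@dataclass
class PipelineConfig:
    """Closure of one pipeline run; exactly one input source must be set."""

    cohort_spec: CohortSpec = None
    cohort_csv: str = None
    dictionary_json: str = None
    missing_mechanism: str = "MCAR"
    M: int = 100
    rf: RFConfig = field(default_factory=RFConfig)
    gbm: GBMConfig = field(default_factory=GBMConfig)
    imputation_trees: int = 100
    imputation_max_iter: int = 10
    use_outcome_in_imputation: bool = False
    grs_only: bool = True
    corr_threshold: float = None
    calibration_direction: str = "predicted_on_observed"
    k_top: int = 30
    seed: int = 0
    output_dir: str = None
    make_plots: bool = True

    def __post_init__(self):
        from_spec = self.cohort_spec is not None
        from_files = self.cohort_csv is not None and self.dictionary_json is not None
        if from_spec == from_files:
            raise ValueError("provide either cohort_spec or cohort_csv + dictionary_json")
        if self.M < 2:
            raise ValueError("need at least 2 imputations")


@dataclass
class ReportBundle:
    rf_pooled: pd.DataFrame
    gbm_summary: pd.DataFrame
    consensus: pd.DataFrame
    rf_matrix: ImportanceMatrix
    gbm_matrix: ImportanceMatrix
    oob_r2: list
    best_n_trees: list
    calibration: tuple
    oob_mean_prediction: np.ndarray
    outcome: np.ndarray
    table: CohortTable
    metadata: dict
    paths: dict = field(default_factory=dict)


def collapse_genotypes_to_grs(table: CohortTable, grs_name: str = "grs") -> CohortTable:
    """Replace the raw SNP columns by one additive GRS predictor."""
    snp_specs = [v for v in table.variables if v.var_type == GENOTYPE]
    if not snp_specs:
        return table
    panel = [SNPDef(v.name, tuple(v.alleles), v.risk_allele) for v in snp_specs]
    geno = table.data[[v.name for v in snp_specs]]
    grs = grs_column(geno, panel)
    keep = [v for v in table.variables if v.var_type != GENOTYPE]
    df = table.data[[v.name for v in keep] + [table.outcome_name]].copy()
    df[grs_name] = grs
    keep.append(
        VariableSpec(
            grs_name, CONTINUOUS, "genetics",
            effect=float(sum(v.effect for v in snp_specs)),
        )
    )
    return CohortTable(df, keep, table.outcome_name)


def correlation_filter(table: CohortTable, threshold: float) -> tuple:
    """Drop the later of every |Pearson r| > threshold pair; returns (table, dropped)."""
    enc = table.encode_numeric()
    corr = enc.corr().abs()
    names = list(enc.columns)
    dropped = []
    kept = []
    for name in names:
        if any(corr.loc[name, k] > threshold for k in kept):
            dropped.append(name)
        else:
            kept.append(name)
    if not dropped:
        return table, []
    keep_specs = [v for v in table.variables if v.name in kept]
    df = table.data[kept + [table.outcome_name]].copy()
    return CohortTable(df, keep_specs, table.outcome_name), dropped


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    ss = np.random.SeedSequence(config.seed)
    s_missing, s_impute, s_rf, s_gbm = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )

    # 1. input table
    if config.cohort_spec is not None:
        table = generate_cohort(config.cohort_spec)
        table = inject_missingness(table, config.missing_mechanism, seed=s_missing)
    else:
        table = CohortTable.from_csv(config.cohort_csv, config.dictionary_json)

    if config.grs_only:
        table = collapse_genotypes_to_grs(table)
    dropped = []
    if config.corr_threshold is not None:
        table, dropped = correlation_filter(table, config.corr_threshold)

    # 2. multiple imputation
    imputations = multiply_impute(
        table, config.M, seed=s_impute,
        n_trees=config.imputation_trees, max_iter=config.imputation_max_iter,
        use_outcome=config.use_outcome_in_imputation,
    )

    # 3. per-imputation models
    names = table.predictor_names
    theta = np.zeros((config.M, len(names)))
    se = np.zeros_like(theta)
    ri = np.zeros_like(theta)
    oob_r2, best_n, oob_preds, per_imp = [], [], [], []
    rf_seeds = np.random.SeedSequence(s_rf).spawn(config.M)
    gbm_seeds = np.random.SeedSequence(s_gbm).spawn(config.M)
    for m, complete in enumerate(imputations.tables):
        rf_cfg = RFConfig(
            n_trees=config.rf.n_trees, n_permutations=config.rf.n_permutations,
            mtry=config.rf.mtry, min_samples_leaf=config.rf.min_samples_leaf,
            seed=int(rf_seeds[m].generate_state(1)[0] % (2**31)),
        )
        fit = fit_rf_oob(complete, rf_cfg)
        imp = permutation_importance_oob(fit)
        theta[m] = imp["theta_hat"].to_numpy()
        se[m] = imp["se"].to_numpy()
        oob_r2.append(oob_pseudo_r2(fit))
        oob_preds.append(fit.oob_predictions)

        gbm_cfg = GBMConfig(
            max_trees=config.gbm.max_trees, learning_rate=config.gbm.learning_rate,
            bag_fraction=config.gbm.bag_fraction,
            interaction_depth=config.gbm.interaction_depth,
            cv_folds=config.gbm.cv_folds,
            seed=int(gbm_seeds[m].generate_state(1)[0] % (2**31)),
        )
        gfit = fit_gbm_cv(complete, gbm_cfg)
        gi = relative_importance(gfit.ledger, gfit.best_n_trees, names)
        ri[m] = gi["relative_importance"].to_numpy()
        best_n.append(gfit.best_n_trees)
        per_imp.append({"rf": imp, "gbm": gi})

    rf_matrix = ImportanceMatrix(theta, names, "RF", se=se)
    gbm_matrix = ImportanceMatrix(ri, names, "GBM")

    # 4. pooling, ranks, consensus
    rf_pooled = pool_importance(rf_matrix).merge(
        rank_summary(rf_matrix), on="variable"
    )
    rf_pooled["method_tag"] = "RF"
    gbm_summary = (
        pd.DataFrame({"variable": names, "mean_relative_importance": ri.mean(axis=0)})
        .merge(rank_summary(gbm_matrix), on="variable")
    )
    gbm_summary["method_tag"] = "GBM"
    consensus = consensus_scores(minmax_normalize(rf_matrix), minmax_normalize(gbm_matrix))

    # 5. calibration of averaged OOB predictions
    mean_pred = np.nanmean(np.vstack(oob_preds), axis=0)
    ok = ~np.isnan(mean_pred)
    cal = calibration_line(mean_pred[ok], table.outcome[ok], config.calibration_direction)

    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "derived_seeds": {"missingness": s_missing, "imputation": s_impute,
                          "rf": s_rf, "gbm": s_gbm},
        "M": config.M,
        "n_subjects": table.n,
        "p_modeled": table.p,
        "grs_only": config.grs_only,
        "corr_threshold": config.corr_threshold,
        "dropped_correlated": dropped,
        "calibration_direction": config.calibration_direction,
        "calibration_intercept": cal[0],
        "calibration_slope": cal[1],
        "oob_pseudo_r2": [float(r) for r in oob_r2],
        "mean_oob_pseudo_r2": float(np.mean(oob_r2)),
        "best_n_trees": [int(b) for b in best_n],
        "imputation": imputations.manifest(),
        "rf_config": asdict(config.rf),
        "gbm_config": asdict(config.gbm),
    }

    bundle = ReportBundle(
        rf_pooled=rf_pooled, gbm_summary=gbm_summary, consensus=consensus,
        rf_matrix=rf_matrix, gbm_matrix=gbm_matrix,
        oob_r2=oob_r2, best_n_trees=best_n, calibration=cal,
        oob_mean_prediction=mean_pred, outcome=table.outcome,
        table=table, metadata=metadata,
    )
    if config.output_dir is not None:
        _write_bundle(bundle, per_imp, config)
    return bundle


def _write_bundle(bundle: ReportBundle, per_imp, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def write_csv(df, name):
        path = out / name
        df.to_csv(path, index=False)
        paths[name] = path

    write_csv(bundle.rf_pooled, "rf_pooled.csv")
    write_csv(bundle.gbm_summary, "gbm_importance.csv")
    write_csv(bundle.consensus, "consensus.csv")
    (out / "run_metadata.json").write_text(json.dumps(bundle.metadata, indent=1))
    paths["run_metadata.json"] = out / "run_metadata.json"

    sub = out / "per_imputation"
    sub.mkdir(exist_ok=True)
    for m, tabs in enumerate(per_imp):
        tabs["rf"].to_csv(sub / f"rf_importance_{m:03d}.csv", index=False)
        tabs["gbm"].to_csv(sub / f"gbm_importance_{m:03d}.csv", index=False)

    if config.make_plots:
        from . import plots

        k = min(config.k_top, bundle.table.p)
        paths["rf_importance_plot"] = plots.importance_bars(
            bundle.rf_pooled, "theta_bar", out / "rf_importance", k=k,
            title="RF permutation importance (pooled)",
            xlabel="mean OOB MSE increase",
        )
        paths["rank_ci_plot"] = plots.rank_ci_plot(
            bundle.rf_pooled, out / "rf_rank_ci", k=k,
            title="RF importance ranks (mean and 95% CI)",
        )
        paths["gbm_importance_plot"] = plots.importance_bars(
            bundle.gbm_summary, "mean_relative_importance", out / "gbm_importance",
            k=k, title="GBM scaled relative importance (mean over imputations)",
            xlabel="relative importance",
        )
        paths["consensus_plot"] = plots.importance_bars(
            bundle.consensus, "consensus_score", out / "consensus", k=k,
            title="Consensus importance", xlabel="normalized consensus score",
        )
        ok = ~np.isnan(bundle.oob_mean_prediction)
        paths["calibration_plot"] = plots.calibration_plot(
            bundle.oob_mean_prediction[ok], bundle.outcome[ok],
            bundle.calibration, out / "calibration",
            title="Average OOB prediction vs observed outcome",
        )
    bundle.paths = paths
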