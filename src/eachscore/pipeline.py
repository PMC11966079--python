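"""End-to-end pipeline: simulate → impute → split → fit → attribute →
change points → scorecard → apply → evaluate.

Every source of randomness is an explicit seed in :class:`RunConfig`; two
runs with the same config produce byte-identical scorecard JSON.  The
logistic comparator is fitted on the same training data so the nonlinearity
gain of the scorecard can be read off one report pair.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as eio
from .attribution import compute_attributions, dependence_profile
from .changepoint import bin_profile, detect_changepoints
from .evaluation import EvalReport, evaluate_scores
from .model_core import (
    DEFAULT_GRID,
    ModelConfig,
    fit_gbdt,
    fit_logistic_baseline,
    impute,
    split,
)
from .scorecard import (
    ScoreCard,
    apply_scorecard_frame,
    build_intervals,
    category_segments,
    fill_missing_intervals,
    normalize,
    score_intervals,
)
from .synthetic_cohort import Cohort, SchemaError, generate_cohort, perioperative_risk, perioperative_schema

logger = logging.getLogger("eachscore")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "build_scorecard"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs, seeds included."""

    # simulation (used when no cohort is supplied)
    n: int = 25_000
    prevalence: float = 0.004
    sim_seed: int = 1

    # model
    train_fraction: float = 0.70
    cv_folds: int = 3
    grid: dict | None = None
    class_weight: dict | str | None = None
    split_seed: int = 2
    model_seed: int = 3

    # change points
    n_bins: int = 50
    min_bin_count: int | None = None
    k_max: int = 5
    epsilon: float | None = None
    score_stat: str = "sum"

    # evaluation
    bootstrap_seed: int = 4
    n_boot: int = 1000

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    model: object
    baseline: object
    imputation_table: dict
    changepoints: dict  # feature -> ChangePointSet (continuous features only)
    scorecard: ScoreCard
    train: Cohort
    test: Cohort
    test_scores: pd.DataFrame  # per-feature scores + total per test patient
    report: EvalReport
    baseline_report: EvalReport
    config: RunConfig = field(default=None)


def build_scorecard(model, train: Cohort, attrs, *, n_bins=50, min_bin_count=None,
                    k_max=5, epsilon=None, stat="sum", provenance=None):
    """Steps 2-4 in one call: change points per continuous feature, interval
    construction, raw interval scores, global normalization, sparse-interval
    repair.  Returns (scorecard, changepoints by feature)."""
    segments_by_feature = {}
    changepoints = {}
    for spec in train.schema:
        if spec.kind == "categorical":
            segments_by_feature[spec.name] = category_segments(spec.categories)
            continue
        profile = dependence_profile(attrs, train, spec.name)
        try:
            binned = bin_profile(profile, n_bins=n_bins, min_bin_count=min_bin_count)
            cps = detect_changepoints(binned, k_max=k_max, epsilon=epsilon)
        except SchemaError:
            # degenerate or too-sparse feature: one segment covering the line
            segments_by_feature[spec.name] = build_intervals([])
            continue
        changepoints[spec.name] = cps
        segments_by_feature[spec.name] = build_intervals(cps)
        logger.info("%s: %d change point(s) at %s", spec.name, len(cps.points),
                    [round(p, 4) for p in cps.points])

    entries = score_intervals(attrs, train, segments_by_feature, stat=stat)
    card = normalize(entries, provenance=provenance)
    card = fill_missing_intervals(card)
    logger.info("normalization constants: raw_min=%.6g raw_max=%.6g", card.raw_min, card.raw_max)
    return card, changepoints


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> PipelineResult:
    """Run the whole flow on a supplied cohort or the default synthetic one."""
    if cohort is None:
        schema = perioperative_schema()
        risk = perioperative_risk(config.prevalence)
        cohort = generate_cohort(schema, risk, config.n, config.sim_seed)
    logger.info("cohort: n=%d prevalence=%.4f%%", cohort.n, 100 * cohort.prevalence)

    cohort, imputation_table = impute(cohort)

    model_config = ModelConfig(
        train_fraction=config.train_fraction,
        cv_folds=config.cv_folds,
        grid=dict(config.grid) if config.grid else dict(DEFAULT_GRID),
        seed=config.model_seed,
        class_weight=config.class_weight,
    )
    train, test = split(cohort, ModelConfig(
        train_fraction=config.train_fraction, cv_folds=config.cv_folds,
        grid=model_config.grid, seed=config.split_seed))
    logger.info("split: train=%d (%d cases) test=%d (%d cases)",
                train.n, int(train.outcome.sum()), test.n, int(test.outcome.sum()))

    model = fit_gbdt(train, model_config)
    logger.info("selected hyperparameters: %s", model.params)
    baseline = fit_logistic_baseline(train, seed=config.model_seed)

    attrs = compute_attributions(model, train)
    card, changepoints = build_scorecard(
        model, train, attrs,
        n_bins=config.n_bins, min_bin_count=config.min_bin_count,
        k_max=config.k_max, epsilon=config.epsilon, stat=config.score_stat,
        provenance={"config_hash": config.config_hash(),
                    "model_fingerprint": model.fingerprint,
                    "model_params": model.params},
    )

    test_scores = apply_scorecard_frame(card, test.features)
    report = evaluate_scores(test_scores["total"].to_numpy(), test.outcome,
                             n_boot=config.n_boot, seed=config.bootstrap_seed)
    baseline_report = evaluate_scores(baseline.margin(test.features), test.outcome,
                                      n_boot=config.n_boot, seed=config.bootstrap_seed)
    logger.info("test AUC: scorecard=%.4f logistic=%.4f", report.auc, baseline_report.auc)

    return PipelineResult(
        model=model, baseline=baseline, imputation_table=imputation_table,
        changepoints=changepoints, scorecard=card, train=train, test=test,
        test_scores=test_scores, report=report, baseline_report=baseline_report,
        config=config,
    )


def write_artifacts(result: PipelineResult, out_dir) -> None:
    """Persist the run: scorecard JSON + CSV, patient scores, eval reports,
    imputation table, chosen hyperparameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    eio.write_scorecard(result.scorecard, out / "scorecard.json")
    eio.write_scorecard_csv(result.scorecard, out / "scorecard.csv")
    result.test_scores.to_csv(out / "test_scores.csv", index=False)
    eio.write_eval_report(result.report, out / "eval_scorecard.json")
    eio.write_eval_report(result.baseline_report, out / "eval_logistic.json")
    (out / "model_meta.json").write_text(json.dumps({
        "params": result.model.params,
        "fingerprint": result.model.fingerprint,
        "imputation_table": result.imputation_table,
        "config": result.config.to_dict() if result.config else None,
    }, indent=1))
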