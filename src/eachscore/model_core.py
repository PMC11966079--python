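"""Preprocessing and model fitting: imputation, stratified split, grid-searched
gradient-boosted trees, and a linear (logistic) comparator.

The boosted model is the risk engine behind the scorecard; its raw output is
an additive log-odds margin, which is what makes exact Shapley decomposition
and interval scoring possible downstream.  Imputation constants are frozen
on the training data and re-applied verbatim to validation data — the
standard discipline that keeps external validation honest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .synthetic_cohort import Cohort, SchemaError, schema_fingerprint

__all__ = [
    "ModelConfig",
    "FittedModel",
    "impute",
    "apply_imputation",
    "split",
    "fit_gbdt",
    "fit_logistic_baseline",
    "DEFAULT_GRID",
]

# small by design: the search procedure matters more than an exhaustive grid
DEFAULT_GRID = {
    "max_depth": [3, 5],
    "learning_rate": [0.05, 0.1],
    "n_estimators": [100, 200],
}

# fixed LightGBM settings for bit-reproducible single-threaded fits
_LGBM_FIXED = dict(
    objective="binary",
    deterministic=True,
    force_row_wise=True,
    n_jobs=1,
    verbose=-1,
    min_child_samples=20,
)


@dataclass
class ModelConfig:
    train_fraction: float = 0.70
    cv_folds: int = 3
    grid: dict = field(default_factory=lambda: dict(DEFAULT_GRID))
    seed: int = 0
    objective_metric: str = "auc"
    class_weight: dict | str | None = None  # optional imbalance handling, off by default

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")
        if self.objective_metric != "auc":
            raise ValueError("only objective_metric='auc' is supported")


@dataclass
class FittedModel:
    """Predictor contract: ``margin(X)`` returns raw additive log-odds,
    ``probability(X)`` its logistic transform."""

    kind: str  # "gbdt" | "logistic"
    estimator: object
    schema: list
    fingerprint: str
    params: dict = field(default_factory=dict)
    cv_results: list = field(default_factory=list)  # (params, mean CV AUC) per candidate
    design_info: dict = field(default_factory=dict)  # logistic baseline encoding

    def _check(self, X: pd.DataFrame) -> pd.DataFrame:
        names = [s.name for s in self.schema]
        missing = set(names) - set(X.columns)
        if missing:
            raise SchemaError(f"input lacks features {sorted(missing)}")
        X = X[names]
        if X.isna().any().any():
            raise SchemaError("input contains missing values; impute first")
        return X

    def margin(self, X: pd.DataFrame) -> np.ndarray:
        X = self._check(X)
        if self.kind == "gbdt":
            return np.asarray(self.estimator.predict(X, raw_score=True), dtype=float)
        design = _logistic_design(X, self.schema, self.design_info)
        return np.asarray(self.estimator.decision_function(design), dtype=float)

    def probability(self, X: pd.DataFrame) -> np.ndarray:
        return expit(self.margin(X))


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute(cohort: Cohort):
    """Fill missing entries with the column mean (continuous) or mode
    (categorical) of the *observed* values.

    Returns the completed cohort and the per-feature imputation table so the
    identical constants can be re-applied to validation data.
    """
    table = {}
    for s in cohort.schema:
        col = cohort.features[s.name]
        observed = col.dropna()
        if len(observed) == 0:
            raise SchemaError(f"feature {s.name!r} has no observed values; cannot impute")
        if s.kind == "continuous":
            table[s.name] = float(observed.mean())
        else:
            # mode; ties broken by category order for determinism
            counts = observed.value_counts()
            top = counts.max()
            winners = [c for c in s.categories if counts.get(c, 0) == top]
            table[s.name] = winners[0]
    return apply_imputation(cohort, table), table


def apply_imputation(cohort: Cohort, table: dict) -> Cohort:
    """Fill missing entries using a frozen imputation table."""
    features = cohort.features.copy()
    for s in cohort.schema:
        if s.name not in table:
            raise SchemaError(f"imputation table lacks feature {s.name!r}")
        col = features[s.name]
        if col.isna().any():
            features[s.name] = col.fillna(table[s.name])
    return Cohort(features, cohort.outcome.copy(), list(cohort.schema), dict(cohort.provenance))


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split(cohort: Cohort, config: ModelConfig):
    """Stratified train/test partition.

    Train size is round(f * n) exactly; within each outcome class the train
    count differs from f * (class size) by at most one.  Stratification is
    essential at sub-percent prevalence, where a plain random split can
    leave the test set with no cases at all.
    """
    y = cohort.outcome
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise SchemaError("both outcome classes must be present to split")
    if counts.min() < 2:
        raise SchemaError("each outcome class needs >= 2 members to stratify")

    f = config.train_fraction
    n_train = round(f * cohort.n)
    rng = np.random.default_rng(config.seed)

    # floor per class, then hand out the remainder by largest fractional part
    base = {c: int(np.floor(f * m)) for c, m in zip(classes, counts)}
    frac = {c: f * m - base[c] for c, m in zip(classes, counts)}
    remainder = n_train - sum(base.values())
    for c in sorted(classes, key=lambda c: (-frac[c], c))[:remainder]:
        base[c] += 1

    train_idx = []
    for c, m in zip(classes, counts):
        members = np.flatnonzero(y == c)
        perm = rng.permutation(m)
        train_idx.append(members[perm[: base[c]]])
    train_mask = np.zeros(cohort.n, dtype=bool)
    train_mask[np.concatenate(train_idx)] = True

    def subset(mask):
        return Cohort(
            cohort.features.loc[mask].reset_index(drop=True),
            cohort.outcome[mask],
            list(cohort.schema),
            dict(cohort.provenance),
        )

    return subset(train_mask), subset(~train_mask)


# ---------------------------------------------------------------------------
# gradient-boosted model with grid-search CV
# ---------------------------------------------------------------------------

def _grid_candidates(grid: dict):
    keys = list(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def fit_gbdt(train: Cohort, config: ModelConfig) -> FittedModel:
    """Grid-search cross-validated LightGBM fit.

    Every grid candidate is scored by mean AUC over stratified folds; the
    maximizer (first in grid order on ties) is refit on the full training
    set.  Categorical features are consumed natively via pandas categorical
    dtype — no one-hot encoding by the caller.
    """
    y = train.outcome
    if len(np.unique(y)) < 2:
        raise SchemaError("training outcome is single-class; cannot fit a classifier")

    legal = set(LGBMClassifier().get_params())
    illegal = set(config.grid) - legal
    if illegal:
        raise ValueError(f"unknown hyperparameters in grid: {sorted(illegal)}")

    X = train.features
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(X, y))

    cv_results = []
    for params in _grid_candidates(config.grid):
        aucs = []
        for tr, va in folds:
            est = LGBMClassifier(random_state=config.seed, class_weight=config.class_weight,
                                 **{**_LGBM_FIXED, **params})
            est.fit(X.iloc[tr], y[tr])
            aucs.append(roc_auc_score(y[va], est.predict_proba(X.iloc[va])[:, 1]))
        cv_results.append((params, float(np.mean(aucs))))

    best_params, _ = max(cv_results, key=lambda pr: pr[1])
    best = LGBMClassifier(random_state=config.seed, class_weight=config.class_weight,
                          **{**_LGBM_FIXED, **best_params})
    best.fit(X, y)
    return FittedModel(
        kind="gbdt",
        estimator=best,
        schema=list(train.schema),
        fingerprint=schema_fingerprint(train.schema),
        params=dict(best_params),
        cv_results=cv_results,
    )


# ---------------------------------------------------------------------------
# linear comparator
# ---------------------------------------------------------------------------

def _logistic_design(X: pd.DataFrame, schema: list, info: dict) -> pd.DataFrame:
    """Main-effects design: continuous features z-scored with the training
    location/scale (conditioning only — the fit is unpenalized, so
    predictions are unaffected), categoricals as drop-first dummies with
    the schema's category set (so train and test encode identically)."""
    parts = {}
    for s in schema:
        col = X[s.name]
        if s.kind == "continuous":
            mu, sd = info["location"][s.name], info["scale"][s.name]
            parts[s.name] = (col.to_numpy(dtype=float) - mu) / sd
        else:
            for cat in s.categories[1:]:
                parts[f"{s.name}[{cat}]"] = (col == cat).to_numpy(dtype=float)
    design = pd.DataFrame(parts)
    return design[info["columns"]]


def fit_logistic_baseline(train: Cohort, seed: int = 0) -> FittedModel:
    """Unpenalized main-effects logistic regression — the linear comparator
    whose inability to bend is what the nonlinear scorecard is measured
    against."""
    y = train.outcome
    if len(np.unique(y)) < 2:
        raise SchemaError("training outcome is single-class; cannot fit a classifier")
    columns, location, scale = [], {}, {}
    for s in train.schema:
        if s.kind == "continuous":
            columns.append(s.name)
            col = train.features[s.name].to_numpy(dtype=float)
            location[s.name] = float(col.mean())
            sd = float(col.std())
            scale[s.name] = sd if sd > 0 else 1.0
        else:
            columns.extend(f"{s.name}[{cat}]" for cat in s.categories[1:])
    info = {"columns": columns, "location": location, "scale": scale}
    design = _logistic_design(train.features, train.schema, info)
    est = LogisticRegression(C=np.inf, max_iter=5000, random_state=seed)
    est.fit(design, y)
    return FittedModel(
        kind="logistic",
        estimator=est,
        schema=list(train.schema),
        fingerprint=schema_fingerprint(train.schema),
        params={"penalty": "none"},
        design_info=info,
    )
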