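"""Exact Shapley attributions of the boosted model and per-feature
dependence profiles.

Attributions live in margin (log-odds) space, where the tree ensemble is
exactly additive: for every sample, base value + sum of per-feature
attributions equals the model margin ("local accuracy").  That identity is
what lets interval scores downstream conserve the model's output.  The
attributions are computed by the polynomial-time tree-path algorithm built
into LightGBM, not a sampling approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import FittedModel
from .synthetic_cohort import Cohort, SchemaError, schema_fingerprint

__all__ = [
    "AttributionSet",
    "DependenceProfile",
    "compute_attributions",
    "rank_features",
    "dependence_profile",
]


@dataclass
class AttributionSet:
    """n x p Shapley attribution matrix (log-odds units) plus the scalar
    expected margin (base value), aligned to the source cohort."""

    values: pd.DataFrame
    base_value: float
    sample_index: np.ndarray

    @property
    def feature_names(self) -> list:
        return list(self.values.columns)

    def margins(self) -> np.ndarray:
        """Reconstructed model margins: base + row sums (local accuracy)."""
        return self.base_value + self.values.to_numpy().sum(axis=1)


@dataclass
class DependenceProfile:
    """(feature value, attribution) pairs for one feature, sorted by value
    ascending; ties keep sample order (stable)."""

    feature: str
    values: np.ndarray
    attributions: np.ndarray
    order: np.ndarray  # sample indices in sorted order
    kind: str
    degenerate: bool  # fewer than 2 distinct values

    def __len__(self) -> int:
        return len(self.values)


def compute_attributions(model: FittedModel, cohort: Cohort) -> AttributionSet:
    """Per-sample, per-feature Shapley decomposition of the model margin.

    Requires an imputed cohort whose schema matches the model's training
    fingerprint.  The returned base value is constant across samples.
    """
    if model.kind != "gbdt":
        raise SchemaError("attributions are defined for the tree-ensemble model")
    if schema_fingerprint(cohort.schema) != model.fingerprint:
        raise SchemaError("cohort schema does not match the model's training schema")
    X = cohort.features
    if X.isna().any().any():
        raise SchemaError("cohort contains missing values; impute before attribution")
    contrib = model.estimator.predict(X, pred_contrib=True)
    values = pd.DataFrame(contrib[:, :-1], columns=list(X.columns))
    base = float(contrib[0, -1])
    return AttributionSet(values=values, base_value=base, sample_index=np.arange(len(X)))


def rank_features(attrs: AttributionSet, top_k: int | None = None) -> list:
    """Features ordered by importance = mean |attribution|, descending.

    Ties keep schema (column) order.  Returns (name, importance) pairs;
    ``top_k`` optionally truncates the list (the default scorecard keeps
    every feature).
    """
    if len(attrs.values) == 0:
        raise SchemaError("empty attribution set")
    imp = attrs.values.abs().mean(axis=0)
    order = np.argsort(-imp.to_numpy(), kind="stable")
    ranked = [(attrs.feature_names[i], float(imp.iloc[i])) for i in order]
    return ranked[:top_k] if top_k is not None else ranked


def dependence_profile(attrs: AttributionSet, cohort: Cohort, feature: str) -> DependenceProfile:
    """Re-index one feature's attributions by its observed values — the
    scatter whose slope changes mark where the model's sensitivity shifts."""
    if feature not in attrs.values.columns:
        raise SchemaError(f"unknown feature {feature!r}")
    spec = next(s for s in cohort.schema if s.name == feature)
    col = cohort.features[feature]
    if spec.kind == "categorical":
        vals = col.cat.codes.to_numpy()
    else:
        vals = col.to_numpy(dtype=float)
    order = np.argsort(vals, kind="stable")  # stable: equal values keep sample order
    sorted_vals = col.to_numpy()[order] if spec.kind == "categorical" else vals[order]
    return DependenceProfile(
        feature=feature,
        values=sorted_vals,
        attributions=attrs.values[feature].to_numpy()[order],
        order=order,
        kind=spec.kind,
        degenerate=len(np.unique(vals)) < 2,
    )
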