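"""Shared fixtures: small schemas, a planted-signal cohort with a fitted
model and its attributions (session-scoped — fitting is the slow part)."""

import numpy as np
import pytest

from eachscore import (
    AttributionSet,
    FeatureSpec,
    ModelConfig,
    Multinomial,
    Normal,
    PiecewiseEffect,
    RiskSpec,
    compute_attributions,
    fit_gbdt,
    generate_cohort,
)

# the recovery / nonlinearity study family: one standard-normal feature with
# a non-monotone piecewise-constant log-odds effect (odds ratios ~4.5 / ~3.3)
TRUE_BREAKPOINTS = (-0.8, 0.6)
TRUE_LEVELS = (1.5, 0.0, 1.2)
TRUE_INTERCEPT = -1.5

FAST_GRID = {"max_depth": [3], "learning_rate": [0.05], "n_estimators": [200]}


def single_feature_schema():
    return [FeatureSpec("x", "continuous", "sd units", None, Normal(0.0, 1.0))]


def single_feature_risk():
    return RiskSpec(TRUE_INTERCEPT, (("x", PiecewiseEffect(TRUE_BREAKPOINTS, TRUE_LEVELS)),))


def make_single_feature_cohort(seed, n=20_000):
    return generate_cohort(single_feature_schema(), single_feature_risk(), n, seed)


def fast_config(seed=0, **kw):
    kw.setdefault("grid", dict(FAST_GRID))
    kw.setdefault("cv_folds", 2)
    return ModelConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def mixed_schema():
    """Three features: a planted piecewise signal, a pure-noise continuous
    feature, and a categorical signal."""
    return [
        FeatureSpec("signal", "continuous", "", None, Normal(0.0, 1.0)),
        FeatureSpec("noise", "continuous", "", None, Normal(0.0, 1.0)),
        FeatureSpec("group", "categorical", "", ("a", "b", "c"), Multinomial((0.5, 0.3, 0.2))),
    ]


@pytest.fixture(scope="session")
def mixed_risk():
    from eachscore import CategoricalEffect

    return RiskSpec(
        -1.8,
        (
            ("signal", PiecewiseEffect(TRUE_BREAKPOINTS, TRUE_LEVELS)),
            ("group", CategoricalEffect((("a", 0.0), ("b", 0.5), ("c", 1.0)))),
        ),
    )


@pytest.fixture(scope="session")
def mixed_cohort(mixed_schema, mixed_risk):
    return generate_cohort(mixed_schema, mixed_risk, 20_000, seed=11)


@pytest.fixture(scope="session")
def mixed_model(mixed_cohort):
    return fit_gbdt(mixed_cohort, fast_config(seed=11))


@pytest.fixture(scope="session")
def mixed_attrs(mixed_model, mixed_cohort) -> AttributionSet:
    return compute_attributions(mixed_model, mixed_cohort)
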