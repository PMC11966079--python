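"""Synthetic tabular cohorts with known piecewise-nonlinear log-odds structure.

Real development cohorts for perioperative risk models are rarely shareable,
so every downstream stage of the scorecard pipeline is exercised against
simulated cohorts whose ground truth — the per-feature log-odds contribution
— is known exactly.  A cohort is a feature table (continuous and categorical
columns), a rare binary outcome drawn from a logistic model, and the schema
describing each column.

The outcome model is

    P(y_i = 1 | x_i) = logistic(b0 + sum_j f_j(x_ij))

where each ``f_j`` is a piecewise-constant step function of a continuous
feature (breakpoints + levels), a per-category level table for a categorical
feature, or identically zero for null features.  Piecewise-constant effects
are the simplest ground truth whose breakpoints a slope-change detector
should later recover.

Missingness is injected separately, missing-completely-at-random on the
feature table only; the outcome is generated from the complete data and is
never masked.  The missing marker is NaN (pandas' native "not available"
token), never a numeric sentinel.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "Normal",
    "Uniform",
    "Multinomial",
    "FeatureSpec",
    "PiecewiseEffect",
    "CategoricalEffect",
    "RiskSpec",
    "Cohort",
    "SchemaError",
    "generate_cohort",
    "inject_missingness",
    "calibrate_intercept",
    "perioperative_schema",
    "perioperative_risk",
]


class SchemaError(ValueError):
    """A feature spec, risk spec, or cohort violates the declared schema."""


# ---------------------------------------------------------------------------
# feature distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Normal:
    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise SchemaError(f"normal distribution needs sigma > 0, got {self.sigma}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mu, self.sigma, size=n)


@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float

    def __post_init__(self):
        if not self.hi > self.lo:
            raise SchemaError(f"uniform distribution needs hi > lo, got [{self.lo}, {self.hi}]")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=n)


@dataclass(frozen=True)
class Multinomial:
    probs: tuple

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if len(p) < 2:
            raise SchemaError("multinomial distribution needs >= 2 categories")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise SchemaError(f"multinomial probabilities must be >= 0 and sum to 1, got {list(p)}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(len(self.probs), size=n, p=np.asarray(self.probs, dtype=float))


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """One column of the cohort: its kind, units, and sampling distribution."""

    name: str
    kind: str  # "continuous" | "categorical"
    units: str = ""
    categories: tuple = None
    distribution: object = None

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise SchemaError(f"{self.name}: kind must be continuous or categorical, got {self.kind!r}")
        if self.kind == "categorical":
            if self.categories is None or len(self.categories) < 2:
                raise SchemaError(f"{self.name}: categorical feature needs >= 2 categories")
            if self.distribution is not None:
                if not isinstance(self.distribution, Multinomial):
                    raise SchemaError(f"{self.name}: categorical feature needs a multinomial distribution")
                if len(self.distribution.probs) != len(self.categories):
                    raise SchemaError(
                        f"{self.name}: {len(self.distribution.probs)} probabilities for "
                        f"{len(self.categories)} categories"
                    )
        else:
            if self.categories is not None:
                raise SchemaError(f"{self.name}: continuous feature cannot declare categories")
            if isinstance(self.distribution, Multinomial):
                raise SchemaError(f"{self.name}: continuous feature cannot use a multinomial distribution")


def schema_fingerprint(schema: list) -> str:
    """Stable hash of feature names / kinds / categories; used to guard
    against scoring a cohort with a model trained on a different layout."""
    payload = [(s.name, s.kind, list(s.categories) if s.categories else None) for s in schema]
    return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# ground-truth risk model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PiecewiseEffect:
    """Step-function log-odds contribution of a continuous feature.

    ``levels[k]`` applies on the half-open segment [breakpoints[k-1],
    breakpoints[k]); the leftmost segment is unbounded below, the rightmost
    unbounded above, so len(levels) == len(breakpoints) + 1.
    """

    breakpoints: tuple
    levels: tuple

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        lv = np.asarray(self.levels, dtype=float)
        if len(lv) != len(bp) + 1:
            raise SchemaError("piecewise effect needs len(levels) == len(breakpoints) + 1")
        if len(bp) and not np.all(np.diff(bp) > 0):
            raise SchemaError("breakpoints must be strictly increasing")
        if not np.all(np.isfinite(lv)) or not np.all(np.isfinite(bp)):
            raise SchemaError("breakpoints and levels must be finite")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(np.asarray(self.breakpoints, dtype=float), x, side="right")
        return np.asarray(self.levels, dtype=float)[idx]


@dataclass(frozen=True)
class CategoricalEffect:
    """Per-category log-odds contribution; categories absent from the table
    contribute zero."""

    levels: tuple  # tuple of (category, level) pairs

    def __post_init__(self):
        for _, lv in self.levels:
            if not math.isfinite(lv):
                raise SchemaError("categorical effect levels must be finite")

    def __call__(self, x: pd.Series) -> np.ndarray:
        table = dict(self.levels)
        return np.asarray([table.get(v, 0.0) for v in x], dtype=float)


@dataclass(frozen=True)
class RiskSpec:
    """Ground-truth outcome model: baseline log-odds plus per-feature effects."""

    intercept: float
    effects: tuple = ()  # tuple of (feature name, effect) pairs

    def effect_for(self, name: str):
        for fname, eff in self.effects:
            if fname == name:
                return eff
        return None

    def validate_against(self, schema: list) -> None:
        names = {s.name: s for s in schema}
        for fname, eff in self.effects:
            if fname not in names:
                raise SchemaError(f"risk effect references unknown feature {fname!r}")
            spec = names[fname]
            if spec.kind == "continuous" and not isinstance(eff, PiecewiseEffect):
                raise SchemaError(f"{fname}: continuous feature needs a piecewise effect")
            if spec.kind == "categorical":
                if not isinstance(eff, CategoricalEffect):
                    raise SchemaError(f"{fname}: categorical feature needs a categorical effect")
                unknown = set(dict(eff.levels)) - set(spec.categories)
                if unknown:
                    raise SchemaError(f"{fname}: effect names unknown categories {sorted(unknown)}")


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Feature table + binary outcome + schema, with generation provenance."""

    features: pd.DataFrame
    outcome: np.ndarray
    schema: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.outcome = np.asarray(self.outcome)
        if len(self.features) != len(self.outcome):
            raise SchemaError("feature table and outcome length differ")
        if len(self.features) < 1:
            raise SchemaError("cohort must contain at least one row")
        if not np.isin(self.outcome, [0, 1]).all():
            raise SchemaError("outcome must be binary 0/1")
        names = [s.name for s in self.schema]
        if list(self.features.columns) != names:
            raise SchemaError("feature columns do not match schema order")
        for s in self.schema:
            col = self.features[s.name]
            if s.kind == "categorical":
                if not isinstance(col.dtype, pd.CategoricalDtype):
                    raise SchemaError(f"{s.name}: expected categorical dtype")
                if set(col.dtype.categories) - set(s.categories):
                    raise SchemaError(f"{s.name}: values outside declared categories")
            else:
                if not np.issubdtype(col.dtype, np.floating):
                    raise SchemaError(f"{s.name}: expected float dtype for continuous feature")

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def prevalence(self) -> float:
        return float(self.outcome.mean())

    def fingerprint(self) -> str:
        return schema_fingerprint(self.schema)

    def copy(self) -> "Cohort":
        return Cohort(self.features.copy(), self.outcome.copy(), list(self.schema), dict(self.provenance))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def linear_predictor(features: pd.DataFrame, risk: RiskSpec) -> np.ndarray:
    """b0 + sum_j f_j(x_j) for every row, in log-odds units."""
    eta = np.full(len(features), float(risk.intercept))
    for fname, eff in risk.effects:
        col = features[fname]
        if isinstance(eff, PiecewiseEffect):
            eta += eff(col.to_numpy(dtype=float))
        else:
            eta += eff(col)
    return eta


def generate_cohort(schema: list, risk: RiskSpec, n: int, seed: int) -> Cohort:
    """Draw ``n`` patients from the schema's distributions and a Bernoulli
    outcome from the risk model.  Identical arguments give an identical
    cohort, bit for bit."""
    if n < 1:
        raise SchemaError("n must be >= 1")
    risk.validate_against(schema)
    rng = np.random.default_rng(seed)
    cols = {}
    for s in schema:
        if s.distribution is None:
            raise SchemaError(f"{s.name}: no sampling distribution declared")
        draw = s.distribution.draw(rng, n)
        if s.kind == "categorical":
            cols[s.name] = pd.Categorical.from_codes(draw, categories=list(s.categories))
        else:
            cols[s.name] = draw.astype(float)
    features = pd.DataFrame(cols)
    p = expit(linear_predictor(features, risk))
    outcome = (rng.random(n) < p).astype(np.int64)
    return Cohort(features, outcome, list(schema), {"seed": seed, "n": n, "risk_intercept": risk.intercept})


def inject_missingness(cohort: Cohort, rates, seed: int) -> Cohort:
    """Mask feature entries missing-completely-at-random.

    ``rates`` is a single probability applied to every feature or a
    dict mapping feature name -> probability.  The outcome is never masked.
    """
    names = [s.name for s in cohort.schema]
    if np.isscalar(rates):
        rates = {name: float(rates) for name in names}
    for name, r in rates.items():
        if name not in names:
            raise SchemaError(f"missingness rate for unknown feature {name!r}")
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name}: missingness rate must be in [0, 1], got {r}")
    rng = np.random.default_rng(seed)
    features = cohort.features.copy()
    for name in names:  # schema order keeps the draw sequence reproducible
        r = rates.get(name, 0.0)
        if r == 0.0:
            continue
        mask = rng.random(len(features)) < r
        if mask.any():
            col = features[name]
            if isinstance(col.dtype, pd.CategoricalDtype):
                col = col.copy()
                col[mask] = np.nan
                features[name] = col
            else:
                features.loc[mask, name] = np.nan
    return Cohort(features, cohort.outcome.copy(), list(cohort.schema),
                  {**cohort.provenance, "missingness_seed": seed})


def calibrate_intercept(schema: list, effects: tuple, target_prevalence: float,
                        n_probe: int = 100_000, seed: int = 2016) -> float:
    """Solve for the baseline log-odds b0 such that the marginal outcome
    prevalence E[logistic(b0 + S)] over a probe sample of the feature
    distributions equals ``target_prevalence``.

    Monte-Carlo root finding: with n_probe = 1e5 the calibration error on a
    0.4% prevalence is well under the binomial noise of any cohort drawn
    afterwards.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    probe_risk = RiskSpec(intercept=0.0, effects=effects)
    probe_risk.validate_against(schema)
    rng = np.random.default_rng(seed)
    cols = {}
    for s in schema:
        draw = s.distribution.draw(rng, n_probe)
        if s.kind == "categorical":
            cols[s.name] = pd.Categorical.from_codes(draw, categories=list(s.categories))
        else:
            cols[s.name] = draw.astype(float)
    s_sum = linear_predictor(pd.DataFrame(cols), probe_risk)

    def gap(b0):
        return expit(b0 + s_sum).mean() - target_prevalence

    return float(brentq(gap, -40.0, 20.0, xtol=1e-10))


# ---------------------------------------------------------------------------
# default preset: a perioperative-stroke-like cohort
# ---------------------------------------------------------------------------
#
# 29 features mirroring a noncardiac-surgery registry: demographics and
# anthropometrics, comorbidity flags, surgical context, and preoperative
# laboratory values.  Marginals follow typical registry summaries; a handful
# of features carry piecewise-nonlinear effects (low albumin, anemia,
# age steps, dysglycemia, non-monotone potassium and BMI), the surgical
# context is categorical signal, and the rest are null features.

def perioperative_schema() -> list:
    yn = ("no", "yes")

    def binary(name, p_yes, units=""):
        return FeatureSpec(name, "categorical", units, yn, Multinomial((1 - p_yes, p_yes)))

    return [
        FeatureSpec("age", "continuous", "years", None, Normal(56.9, 15.2)),
        FeatureSpec("sex", "categorical", "", ("female", "male"), Multinomial((0.446, 0.554))),
        FeatureSpec("height", "continuous", "cm", None, Normal(162.0, 8.7)),
        FeatureSpec("weight", "continuous", "kg", None, Normal(63.5, 12.0)),
        FeatureSpec("bmi", "continuous", "kg/m2", None, Normal(24.1, 3.7)),
        FeatureSpec("asa", "categorical", "class", ("1", "2", "3", "4", "5"),
                    Multinomial((0.2953, 0.5832, 0.1143, 0.0067, 0.0005))),
        binary("emergency", 0.058),
        binary("hypertension", 0.312),
        binary("diabetes", 0.152),
        binary("cardiovascular_accident", 0.020),
        binary("asthma", 0.006),
        binary("copd", 0.006),
        binary("liver_disease", 0.039),
        binary("kidney_disease", 0.032),
        binary("tuberculosis", 0.010),
        FeatureSpec("surgery_type", "categorical", "", ("low_risk", "high_risk"),
                    Multinomial((0.458, 0.542))),
        FeatureSpec("hemoglobin", "continuous", "g/dL", None, Normal(12.9, 1.86)),
        FeatureSpec("platelet", "continuous", "1e3/uL", None, Normal(245.0, 79.5)),
        FeatureSpec("bun", "continuous", "mg/dL", None, Normal(15.8, 6.0)),
        FeatureSpec("creatinine", "continuous", "mg/dL", None, Normal(1.0, 0.35)),
        FeatureSpec("albumin", "continuous", "g/dL", None, Normal(4.05, 0.47)),
        FeatureSpec("sodium", "continuous", "mmol/L", None, Normal(140.2, 2.7)),
        FeatureSpec("potassium", "continuous", "mmol/L", None, Normal(4.24, 0.41)),
        FeatureSpec("glucose", "continuous", "mg/dL", None, Normal(114.9, 39.9)),
        FeatureSpec("prothrombin_time", "continuous", "%", None, Normal(103.6, 14.9)),
        FeatureSpec("ptt", "continuous", "sec", None, Normal(31.5, 5.6)),
        FeatureSpec("ast", "continuous", "IU/L", None, Normal(25.3, 15.0)),
        FeatureSpec("alt", "continuous", "IU/L", None, Normal(25.4, 15.0)),
        FeatureSpec("egfr", "continuous", "mL/min/1.73m2", None, Normal(83.8, 27.3)),
    ]


def perioperative_effects() -> tuple:
    return (
        ("albumin", PiecewiseEffect((3.5, 4.1), (1.6, 0.7, 0.0))),
        ("hemoglobin", PiecewiseEffect((11.0,), (1.2, 0.0))),
        ("age", PiecewiseEffect((49.0, 64.0), (0.0, 0.35, 0.7))),
        ("glucose", PiecewiseEffect((110.0, 160.0), (0.0, 0.4, 0.8))),
        ("potassium", PiecewiseEffect((3.5, 4.6), (0.8, 0.0, 0.6))),
        ("bmi", PiecewiseEffect((18.6, 20.7), (0.6, 0.9, 0.0))),
        ("asa", CategoricalEffect((("1", 0.0), ("2", 0.3), ("3", 0.8), ("4", 1.4), ("5", 2.0)))),
        ("emergency", CategoricalEffect((("no", 0.0), ("yes", 0.8)))),
        ("surgery_type", CategoricalEffect((("low_risk", 0.0), ("high_risk", 0.7)))),
        ("cardiovascular_accident", CategoricalEffect((("no", 0.0), ("yes", 0.6)))),
    )


def perioperative_risk(target_prevalence: float = 0.004) -> RiskSpec:
    """Default ground truth calibrated to a rare outcome (0.4% by default)."""
    schema = perioperative_schema()
    effects = perioperative_effects()
    b0 = calibrate_intercept(schema, effects, target_prevalence)
    return RiskSpec(intercept=b0, effects=effects)


def logit_intercept(prevalence: float) -> float:
    """Baseline log-odds giving this marginal prevalence when all effects are zero."""
    return float(logit(prevalence))
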