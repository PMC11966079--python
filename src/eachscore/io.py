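"""Readers and writers for the pipeline's artifacts.

Formats are deliberately plain: cohorts travel as CSV with a JSON schema
sidecar (kind, units, categories, optional sampling distribution); the
scorecard has a canonical lossless JSON form plus a human-readable CSV
score table ("2.4–3.5, 55.40"); evaluation reports are JSON.  Missing
cohort cells are empty CSV fields.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .scorecard import IntervalScore, ScoreCard, Segment
from .synthetic_cohort import (
    CategoricalEffect,
    Cohort,
    FeatureSpec,
    Multinomial,
    Normal,
    PiecewiseEffect,
    RiskSpec,
    SchemaError,
    Uniform,
)

__all__ = [
    "schema_to_json", "schema_from_json", "write_schema", "read_schema",
    "risk_to_json", "risk_from_json", "write_risk", "read_risk",
    "write_cohort", "read_cohort",
    "write_scorecard", "read_scorecard", "write_scorecard_csv",
    "write_eval_report",
]

SCORECARD_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# schema JSON
# ---------------------------------------------------------------------------

def _dist_to_json(d):
    if d is None:
        return None
    if isinstance(d, Normal):
        return {"type": "normal", "mu": d.mu, "sigma": d.sigma}
    if isinstance(d, Uniform):
        return {"type": "uniform", "lo": d.lo, "hi": d.hi}
    if isinstance(d, Multinomial):
        return {"type": "multinomial", "probs": list(d.probs)}
    raise SchemaError(f"unknown distribution {d!r}")


def _dist_from_json(obj):
    if obj is None:
        return None
    kind = obj.get("type")
    if kind == "normal":
        return Normal(obj["mu"], obj["sigma"])
    if kind == "uniform":
        return Uniform(obj["lo"], obj["hi"])
    if kind == "multinomial":
        return Multinomial(tuple(obj["probs"]))
    raise SchemaError(f"unknown distribution type {kind!r}")


def schema_to_json(schema: list) -> list:
    return [
        {
            "name": s.name,
            "kind": s.kind,
            "units": s.units,
            "categories": list(s.categories) if s.categories else None,
            "distribution": _dist_to_json(s.distribution),
        }
        for s in schema
    ]


def schema_from_json(items: list) -> list:
    return [
        FeatureSpec(
            name=o["name"],
            kind=o["kind"],
            units=o.get("units", ""),
            categories=tuple(o["categories"]) if o.get("categories") else None,
            distribution=_dist_from_json(o.get("distribution")),
        )
        for o in items
    ]


def write_schema(schema: list, path) -> None:
    Path(path).write_text(json.dumps(schema_to_json(schema), indent=1))


def read_schema(path) -> list:
    return schema_from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# risk JSON
# ---------------------------------------------------------------------------

def risk_to_json(risk: RiskSpec) -> dict:
    effects = []
    for name, eff in risk.effects:
        if isinstance(eff, PiecewiseEffect):
            effects.append({"feature": name, "type": "piecewise",
                            "breakpoints": list(eff.breakpoints), "levels": list(eff.levels)})
        else:
            effects.append({"feature": name, "type": "categorical",
                            "levels": {c: l for c, l in eff.levels}})
    return {"intercept": risk.intercept, "effects": effects}


def risk_from_json(obj: dict) -> RiskSpec:
    effects = []
    for e in obj.get("effects", []):
        if e["type"] == "piecewise":
            eff = PiecewiseEffect(tuple(e["breakpoints"]), tuple(e["levels"]))
        elif e["type"] == "categorical":
            eff = CategoricalEffect(tuple(e["levels"].items()))
        else:
            raise SchemaError(f"unknown effect type {e['type']!r}")
        effects.append((e["feature"], eff))
    return RiskSpec(intercept=float(obj["intercept"]), effects=tuple(effects))


def write_risk(risk: RiskSpec, path) -> None:
    Path(path).write_text(json.dumps(risk_to_json(risk), indent=1))


def read_risk(path) -> RiskSpec:
    return risk_from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

OUTCOME_COLUMN = "outcome"


def write_cohort(cohort: Cohort, csv_path, schema_path=None) -> None:
    df = cohort.features.copy()
    df[OUTCOME_COLUMN] = cohort.outcome
    df.to_csv(csv_path, index=False)
    if schema_path is not None:
        write_schema(cohort.schema, schema_path)


def read_cohort(csv_path, schema) -> Cohort:
    """Read a cohort CSV against a schema (list of FeatureSpec or a schema
    JSON path).  Validation is strict: unknown or absent columns, non-binary
    outcomes, and categories outside the schema are named in the error."""
    if not isinstance(schema, list):
        schema = read_schema(schema)
    names = [s.name for s in schema]
    df = pd.read_csv(csv_path, dtype={s.name: str for s in schema if s.kind == "categorical"})
    expected = set(names) | {OUTCOME_COLUMN}
    stray = set(df.columns) - expected
    if stray:
        raise SchemaError(f"unexpected column(s) in {csv_path}: {sorted(stray)}")
    absent = expected - set(df.columns)
    if absent:
        raise SchemaError(f"missing column(s) in {csv_path}: {sorted(absent)}")

    outcome = df[OUTCOME_COLUMN].to_numpy()
    if not np.isin(outcome, [0, 1]).all():
        bad = np.flatnonzero(~np.isin(outcome, [0, 1]))[0]
        raise SchemaError(f"non-binary outcome at row {bad} of {csv_path}")

    cols = {}
    for s in schema:
        col = df[s.name]
        if s.kind == "categorical":
            observed = set(col.dropna())
            unknown = observed - set(s.categories)
            if unknown:
                raise SchemaError(
                    f"column {s.name!r}: categories outside schema: {sorted(unknown)}"
                )
            cols[s.name] = pd.Categorical(col, categories=list(s.categories))
        else:
            cols[s.name] = col.to_numpy(dtype=float)
    return Cohort(pd.DataFrame(cols), outcome.astype(np.int64), list(schema))


# ---------------------------------------------------------------------------
# scorecard JSON / CSV
# ---------------------------------------------------------------------------

def _bound(x: float) -> object:
    # JSON has no infinities; keep them as strings
    if math.isinf(x):
        return "-inf" if x < 0 else "inf"
    return x


def _unbound(x) -> float:
    return float(x)


def write_scorecard(card: ScoreCard, path) -> None:
    obj = {
        "format_version": SCORECARD_FORMAT_VERSION,
        "normalization": {"raw_min": card.raw_min, "raw_max": card.raw_max},
        "provenance": card.provenance,
        "features": [
            {
                "name": feature,
                "segments": [
                    {
                        "category": e.segment.category,
                        "lo": None if e.segment.lo is None else _bound(e.segment.lo),
                        "hi": None if e.segment.hi is None else _bound(e.segment.hi),
                        "raw_score": e.raw_score,
                        "normalized_score": e.normalized_score,
                        "n_points": e.n_points,
                        "filled": e.filled,
                    }
                    for e in entries
                ],
            }
            for feature, entries in card.entries.items()
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def read_scorecard(path) -> ScoreCard:
    obj = json.loads(Path(path).read_text())
    if obj.get("format_version") != SCORECARD_FORMAT_VERSION:
        raise SchemaError(
            f"scorecard format version {obj.get('format_version')!r} is not supported"
        )
    norm = obj.get("normalization")
    if not norm or "raw_min" not in norm or "raw_max" not in norm:
        raise SchemaError("scorecard JSON lacks normalization constants")
    entries = {}
    for feat in obj["features"]:
        segs = []
        for s in feat["segments"]:
            if s["category"] is not None:
                segment = Segment(category=s["category"])
            else:
                segment = Segment(lo=_unbound(s["lo"]), hi=_unbound(s["hi"]))
            segs.append(IntervalScore(
                feature=feat["name"], segment=segment, raw_score=s["raw_score"],
                n_points=s["n_points"], normalized_score=s["normalized_score"],
                filled=s["filled"],
            ))
        entries[feat["name"]] = segs
    return ScoreCard(entries=entries, raw_min=float(norm["raw_min"]),
                     raw_max=float(norm["raw_max"]), provenance=obj.get("provenance", {}))


def write_scorecard_csv(card: ScoreCard, path) -> None:
    """Presentation table: one row per segment, scores rounded to 2 decimals."""
    rows = []
    for feature, entries in card.entries.items():
        for e in entries:
            rows.append({
                "feature": feature,
                "interval": e.segment.text(),
                "score": round(e.normalized_score, 2) if e.normalized_score is not None else "",
                "n_points": e.n_points,
                "filled": int(e.filled),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_eval_report(report, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))
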