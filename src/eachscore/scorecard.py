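"""Interval scoring, global normalization, sparse-interval repair, and
patient scoring.

Change points partition each continuous feature's axis into half-open
segments with unbounded extremes, so any future patient value falls in
exactly one segment; each category of a categorical feature is its own
segment.  A segment's raw score is the SUM of the training attributions of
the samples it contains — the model's total log-odds contribution routed
through that value range.  Raw scores are then min-max normalized on ONE
global scale across all features (the global minimum maps to 0, the maximum
to 100), which is what makes scores comparable between, say, albumin ranges
and surgery type.  Segments that captured no training samples are repaired
from their neighbors after normalization, and a patient's total risk score
is the plain sum of their per-feature scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .attribution import AttributionSet
from .changepoint import ChangePointSet
from .synthetic_cohort import Cohort, SchemaError

__all__ = [
    "Segment",
    "IntervalScore",
    "ScoreCard",
    "PatientScore",
    "build_intervals",
    "category_segments",
    "score_intervals",
    "normalize",
    "fill_missing_intervals",
    "apply_scorecard",
]


@dataclass(frozen=True)
class Segment:
    """Half-open value interval [lo, hi) of a continuous feature, or a
    single category label."""

    lo: float | None = None
    hi: float | None = None
    category: str | None = None

    def __post_init__(self):
        if self.category is None and not (self.lo is not None and self.hi is not None):
            raise SchemaError("segment needs either [lo, hi) bounds or a category")

    @property
    def is_categorical(self) -> bool:
        return self.category is not None

    def contains(self, value) -> bool:
        if self.is_categorical:
            return value == self.category
        return self.lo <= value < self.hi

    def text(self) -> str:
        if self.is_categorical:
            return str(self.category)
        if math.isinf(self.lo) and math.isinf(self.hi):
            return "any"
        if math.isinf(self.lo):
            return f"<{self.hi:g}"
        if math.isinf(self.hi):
            return f"≥{self.lo:g}"
        return f"{self.lo:g}–{self.hi:g}"


@dataclass
class IntervalScore:
    feature: str
    segment: Segment
    raw_score: float | None  # None while unscored (empty segment)
    n_points: int
    normalized_score: float | None = None
    filled: bool = False

    @property
    def scored(self) -> bool:
        return self.raw_score is not None


@dataclass
class ScoreCard:
    """Per-feature interval/category -> normalized score lookup plus the
    global normalization constants it was built with."""

    entries: dict  # feature -> list[IntervalScore], segment order
    raw_min: float
    raw_max: float
    provenance: dict = field(default_factory=dict)

    @property
    def features(self) -> list:
        return list(self.entries)

    def feature_entries(self, feature: str) -> list:
        return self.entries[feature]


@dataclass
class PatientScore:
    patient_id: object
    per_feature: dict  # feature -> assigned normalized score

    @property
    def total(self) -> float:
        return float(sum(self.per_feature.values()))


# ---------------------------------------------------------------------------
# segment construction
# ---------------------------------------------------------------------------

def build_intervals(cps: ChangePointSet | np.ndarray, observed_range=None) -> list:
    """k ascending change points -> k+1 half-open segments covering the whole
    line: (-inf, p1), [p1, p2), ..., [pk, +inf)."""
    points = cps.points if isinstance(cps, ChangePointSet) else np.asarray(cps, dtype=float)
    if len(points) and not np.all(np.diff(points) > 0):
        raise SchemaError("change points must be strictly ascending")
    if observed_range is not None and len(points):
        lo, hi = observed_range
        if points[0] <= lo or points[-1] >= hi:
            raise SchemaError("change points must lie strictly inside the observed range")
    cuts = [-math.inf, *points.tolist(), math.inf]
    return [Segment(lo=cuts[i], hi=cuts[i + 1]) for i in range(len(cuts) - 1)]


def category_segments(categories) -> list:
    """One segment per category — the categorical analogue of intervals."""
    return [Segment(category=str(c)) for c in categories]


# ---------------------------------------------------------------------------
# raw interval scores
# ---------------------------------------------------------------------------

def _check_partition(segments: list) -> None:
    if all(s.is_categorical for s in segments):
        if len({s.category for s in segments}) != len(segments):
            raise SchemaError("duplicate category segments")
        return
    if any(s.is_categorical for s in segments):
        raise SchemaError("cannot mix interval and category segments for one feature")
    if not math.isinf(segments[0].lo) or not math.isinf(segments[-1].hi):
        raise SchemaError("interval segments must be unbounded at the extremes")
    for a, b in zip(segments, segments[1:]):
        if a.hi != b.lo:
            raise SchemaError("interval segments must tile the line without gaps or overlap")
        if not a.lo < a.hi:
            raise SchemaError("segments must have lo < hi")


def score_intervals(attrs: AttributionSet, cohort: Cohort, segments_by_feature: dict,
                    stat: str = "sum") -> list:
    """Raw score per segment = sum of that feature's training attributions
    over the samples falling in the segment.

    Per feature the segment raw scores conserve the attribution column sum
    exactly (every sample lands in exactly one segment).  Segments with no
    samples stay unscored (raw None) for the repair pass.  ``stat="mean"``
    switches to the per-sample mean — an occupancy-independent variant kept
    for sensitivity analysis, not the default.
    """
    if stat not in ("sum", "mean"):
        raise ValueError("stat must be 'sum' or 'mean'")
    if len(attrs.values) != cohort.n:
        raise SchemaError("attribution set and cohort are not aligned")
    out = []
    for feature, segments in segments_by_feature.items():
        if feature not in attrs.values.columns:
            raise SchemaError(f"unknown feature {feature!r}")
        _check_partition(segments)
        col = cohort.features[feature]
        a = attrs.values[feature].to_numpy()
        for seg in segments:
            if seg.is_categorical:
                mask = (col == seg.category).to_numpy()
            else:
                v = col.to_numpy(dtype=float)
                mask = (v >= seg.lo) & (v < seg.hi)
            n_pts = int(mask.sum())
            if n_pts > 0:
                raw = float(a[mask].sum()) if stat == "sum" else float(a[mask].mean())
            else:
                raw = None
            out.append(IntervalScore(feature=feature, segment=seg, raw_score=raw, n_points=n_pts))
    return out


# ---------------------------------------------------------------------------
# normalization (Step 4)
# ---------------------------------------------------------------------------

def normalize(entries: list, provenance: dict | None = None) -> ScoreCard:
    """Min-max normalize all scored raw scores onto one global 0-100 scale.

    The constants come from scored (non-filled) segments only; if every raw
    score is identical the model is degenerate and every segment gets 50
    with a loud warning.
    """
    raws = [e.raw_score for e in entries if e.scored]
    if not raws:
        raise SchemaError("no scored segments to normalize")
    raw_min, raw_max = min(raws), max(raws)
    normalized = []
    if raw_min == raw_max:
        warnings.warn(
            "all raw interval scores are identical; the model is degenerate "
            "and every score is set to 50",
            stacklevel=2,
        )
        for e in entries:
            normalized.append(replace(e, normalized_score=50.0 if e.scored else None))
    else:
        span = raw_max - raw_min
        for e in entries:
            score = 100.0 * (e.raw_score - raw_min) / span if e.scored else None
            normalized.append(replace(e, normalized_score=score))

    grouped: dict = {}
    for e in normalized:
        grouped.setdefault(e.feature, []).append(e)
    return ScoreCard(entries=grouped, raw_min=float(raw_min), raw_max=float(raw_max),
                     provenance=dict(provenance or {}))


def fill_missing_intervals(card: ScoreCard) -> ScoreCard:
    """Repair segments that captured no training samples.

    An unscored interval whose immediate neighbors are all scored receives
    the mean of their normalized scores (a single scored neighbor at an
    edge passes its score through).  If any adjacent interval is itself
    unscored, the sparse region is too wide for local averaging and the
    feature-wide mean of scored segments is used instead.  Categories have
    no meaningful adjacency, so an unscored category always receives the
    feature-wide mean.  Filled scores are flagged and never feed the
    normalization constants.
    """
    new_entries = {}
    for feature, entries in card.entries.items():
        scored_vals = [e.normalized_score for e in entries if e.scored]
        if not scored_vals:
            raise SchemaError(f"feature {feature!r} has no scored segments")
        feature_mean = float(np.mean(scored_vals))
        repaired = []
        for i, e in enumerate(entries):
            if e.scored:
                repaired.append(e)
                continue
            if e.segment.is_categorical:
                fill = feature_mean
            else:
                neighbors = [entries[j] for j in (i - 1, i + 1) if 0 <= j < len(entries)]
                if all(nb.scored for nb in neighbors):
                    fill = float(np.mean([nb.normalized_score for nb in neighbors]))
                else:
                    fill = feature_mean  # sparse neighborhood: fall back to the whole feature
            repaired.append(replace(e, normalized_score=fill, filled=True))
        new_entries[feature] = repaired
    return ScoreCard(entries=new_entries, raw_min=card.raw_min, raw_max=card.raw_max,
                     provenance=dict(card.provenance))


# ---------------------------------------------------------------------------
# applying the scorecard
# ---------------------------------------------------------------------------

def apply_scorecard(card: ScoreCard, patient, patient_id=None) -> PatientScore:
    """Score one patient record (mapping feature -> value).

    Every scorecard feature must be present and non-missing (impute first).
    Continuous values map to the segment containing them — the unbounded
    edge segments clamp values outside the training range.  A category
    never seen in training gets the feature-wide mean score with a warning.
    The total is the exact sum of the per-feature scores.
    """
    if isinstance(patient, pd.Series):
        patient = patient.to_dict()
    per_feature = {}
    for feature, entries in card.entries.items():
        if feature not in patient:
            raise SchemaError(f"patient record lacks feature {feature!r}")
        value = patient[feature]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise SchemaError(f"patient value for {feature!r} is missing; impute first")
        match = next((e for e in entries if e.segment.contains(value)), None)
        if match is None:
            if entries[0].segment.is_categorical:
                warnings.warn(
                    f"{feature}: unseen category {value!r}; using the feature-wide mean score",
                    stacklevel=2,
                )
                per_feature[feature] = float(
                    np.mean([e.normalized_score for e in entries if not e.filled])
                )
                continue
            raise SchemaError(f"{feature}: no segment contains value {value!r}")
        per_feature[feature] = float(match.normalized_score)
    return PatientScore(patient_id=patient_id, per_feature=per_feature)


def apply_scorecard_frame(card: ScoreCard, patients: pd.DataFrame) -> pd.DataFrame:
    """Vector convenience: per-feature scores + total for each row."""
    rows = []
    for idx, row in patients.iterrows():
        ps = apply_scorecard(card, row, patient_id=idx)
        rows.append({**ps.per_feature, "total": ps.total})
    return pd.DataFrame(rows, index=patients.index)
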