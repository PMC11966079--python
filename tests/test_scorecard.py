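"""Interval construction, raw-score conservation, global normalization,
sparse-interval repair, and patient scoring."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from eachscore import (
    Cohort,
    FeatureSpec,
    Multinomial,
    Normal,
    SchemaError,
    Segment,
    apply_scorecard,
    build_intervals,
    category_segments,
    fill_missing_intervals,
    normalize,
    score_intervals,
)
from eachscore.attribution import AttributionSet
from eachscore.scorecard import IntervalScore, ScoreCard


def make_attrs_cohort(values, attributions, feature="x"):
    schema = [FeatureSpec(feature, "continuous", "", None, Normal(0, 1))]
    n = len(values)
    cohort = Cohort(pd.DataFrame({feature: np.asarray(values, dtype=float)}),
                    np.zeros(n, dtype=int) if n > 1 else np.array([0]),
                    schema)
    attrs = AttributionSet(values=pd.DataFrame({feature: attributions}),
                           base_value=0.0, sample_index=np.arange(n))
    return attrs, cohort


def card_from_scores(feature_scores: dict) -> ScoreCard:
    """Hand-built scorecard: one catch-all interval per feature holding a
    fixed normalized score (categorical features map category -> score)."""
    entries = {}
    for feature, score in feature_scores.items():
        if isinstance(score, dict):
            entries[feature] = [
                IntervalScore(feature, Segment(category=c), raw_score=0.0,
                              n_points=1, normalized_score=s)
                for c, s in score.items()
            ]
        else:
            entries[feature] = [
                IntervalScore(feature, Segment(lo=-math.inf, hi=math.inf), raw_score=0.0,
                              n_points=1, normalized_score=score)
            ]
    return ScoreCard(entries=entries, raw_min=0.0, raw_max=1.0)


class TestBuildIntervals:
    def test_no_points_gives_whole_line(self):
        segs = build_intervals(np.array([]))
        assert len(segs) == 1
        assert segs[0].lo == -math.inf and segs[0].hi == math.inf

    def test_two_points_give_three_segments(self):
        segs = build_intervals(np.array([1.0, 2.5]))
        assert [(s.lo, s.hi) for s in segs] == [(-math.inf, 1.0), (1.0, 2.5), (2.5, math.inf)]

    def test_five_points_give_six_disjoint_exhaustive_segments(self):
        pts = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        segs = build_intervals(pts)
        assert len(segs) == 6
        for a, b in zip(segs, segs[1:]):
            assert a.hi == b.lo  # exhaustive, non-overlapping
        for v in (-100.0, 2.5, 4.0, 100.0):  # every value maps to exactly one
            assert sum(s.contains(v) for s in segs) == 1

    def test_unsorted_points_rejected(self):
        with pytest.raises(SchemaError):
            build_intervals(np.array([2.0, 1.0]))


class TestScoreIntervals:
    def test_two_term_sum(self):
        attrs, cohort = make_attrs_cohort([0.5, 1.5], [0.1, -0.2])
        entries = score_intervals(attrs, cohort, {"x": build_intervals(np.array([]))})
        assert entries[0].raw_score == pytest.approx(-0.1)
        assert entries[0].n_points == 2

    def test_per_feature_conservation(self, mixed_attrs, mixed_cohort):
        """Sum of segment raw scores equals the attribution column sum to
        1e-9 for interval and categorical features alike."""
        segments = {
            "signal": build_intervals(np.array([-0.8, 0.0, 0.6])),
            "noise": build_intervals(np.array([-1.0, 1.0])),
            "group": category_segments(("a", "b", "c")),
        }
        entries = score_intervals(mixed_attrs, mixed_cohort, segments)
        for feature in segments:
            seg_sum = sum(e.raw_score for e in entries if e.feature == feature and e.scored)
            col_sum = float(mixed_attrs.values[feature].sum())
            assert seg_sum == pytest.approx(col_sum, abs=1e-9)
            n_sum = sum(e.n_points for e in entries if e.feature == feature)
            assert n_sum == mixed_cohort.n

    def test_empty_segment_flagged_unscored(self):
        attrs, cohort = make_attrs_cohort([1.0, 2.0], [0.3, 0.4])
        entries = score_intervals(attrs, cohort, {"x": build_intervals(np.array([5.0, 6.0]))})
        empty = entries[1]  # [5, 6) holds no samples
        assert not empty.scored and empty.raw_score is None and empty.n_points == 0

    def test_overlapping_segments_rejected(self):
        attrs, cohort = make_attrs_cohort([1.0], [0.1])
        bad = [Segment(lo=-math.inf, hi=2.0), Segment(lo=1.0, hi=math.inf)]
        with pytest.raises(SchemaError):
            score_intervals(attrs, cohort, {"x": bad})

    def test_mean_variant(self):
        attrs, cohort = make_attrs_cohort([0.5, 1.5], [0.1, -0.2])
        entries = score_intervals(attrs, cohort, {"x": build_intervals(np.array([]))},
                                  stat="mean")
        assert entries[0].raw_score == pytest.approx(-0.05)


class TestNormalize:
    def entries_from_raws(self, raws):
        segs = build_intervals(np.arange(1.0, len(raws), dtype=float))
        return [IntervalScore("x", s, raw_score=r, n_points=1) for s, r in zip(segs, raws)]

    def test_affine_map_to_0_100(self):
        card = normalize(self.entries_from_raws([-3.0, 1.0, 5.0]))
        got = [e.normalized_score for e in card.entries["x"]]
        assert got == pytest.approx([0.0, 50.0, 100.0])
        assert (card.raw_min, card.raw_max) == (-3.0, 5.0)

    def test_shift_invariance(self):
        a = normalize(self.entries_from_raws([-3.0, 1.0, 5.0]))
        b = normalize(self.entries_from_raws([7.0, 11.0, 15.0]))
        assert [e.normalized_score for e in a.entries["x"]] == pytest.approx(
            [e.normalized_score for e in b.entries["x"]]
        )

    def test_degenerate_all_equal_warns_and_sets_50(self):
        with pytest.warns(UserWarning, match="degenerate"):
            card = normalize(self.entries_from_raws([2.0, 2.0, 2.0]))
        assert all(e.normalized_score == 50.0 for e in card.entries["x"])

    def test_binary_feature_spanning_extremes_scores_0_and_100(self):
        """A two-category feature holding both the global min and max raw
        score gets categories scored exactly 0 and 100."""
        entries = [
            IntervalScore("surgery", Segment(category="low"), raw_score=-4.0, n_points=5),
            IntervalScore("surgery", Segment(category="high"), raw_score=9.0, n_points=5),
            IntervalScore("age", Segment(lo=-math.inf, hi=math.inf), raw_score=1.0, n_points=5),
        ]
        card = normalize(entries)
        scores = {e.segment.category: e.normalized_score for e in card.entries["surgery"]}
        assert scores == pytest.approx({"low": 0.0, "high": 100.0})


class TestFillMissingIntervals:
    def card_with(self, norm_scores):
        """Interval entries; None marks an unscored segment."""
        segs = build_intervals(np.arange(1.0, len(norm_scores), dtype=float))
        entries = {
            "x": [
                IntervalScore("x", s, raw_score=None if v is None else float(v),
                              n_points=0 if v is None else 1,
                              normalized_score=v)
                for s, v in zip(segs, norm_scores)
            ]
        }
        return ScoreCard(entries=entries, raw_min=0.0, raw_max=100.0)

    def test_interior_gap_gets_neighbor_mean(self):
        card = fill_missing_intervals(self.card_with([40.0, None, 60.0]))
        filled = card.entries["x"][1]
        assert filled.normalized_score == 50.0 and filled.filled

    def test_edge_gap_gets_single_neighbor(self):
        card = fill_missing_intervals(self.card_with([None, 40.0, 70.0]))
        assert card.entries["x"][0].normalized_score == 40.0

    def test_consecutive_gaps_get_feature_wide_mean(self):
        """Two adjacent empty segments: local averaging is unsupported, so
        both fall back to the mean over all scored segments (47.5)."""
        card = fill_missing_intervals(self.card_with([40.0, None, None, 55.0]))
        assert card.entries["x"][1].normalized_score == 47.5
        assert card.entries["x"][2].normalized_score == 47.5

    def test_feature_without_any_scored_segment_rejected(self):
        with pytest.raises(SchemaError):
            fill_missing_intervals(self.card_with([None, None]))

    def test_filled_scores_never_widen_normalization(self, mixed_attrs, mixed_cohort):
        """End-to-end: a segment emptied by construction gets a filled score
        while the stored raw min/max still match the scored segments only."""
        hi = float(mixed_cohort.features["signal"].max())
        segments = {"signal": build_intervals(np.array([hi - 1e-9, hi - 5e-10]))}
        entries = score_intervals(mixed_attrs, mixed_cohort, segments)
        card = fill_missing_intervals(normalize(entries))
        raws = [e.raw_score for e in card.entries["signal"] if e.scored]
        assert card.raw_min == min(raws) and card.raw_max == max(raws)
        assert any(e.filled for e in card.entries["signal"])


class TestApplyScorecard:
    def test_edge_clamp_below_training_minimum(self):
        card = card_from_scores({})
        card.entries["x"] = [
            IntervalScore("x", s, raw_score=0.0, n_points=1, normalized_score=v)
            for s, v in zip(build_intervals(np.array([0.0])), [10.0, 90.0])
        ]
        assert apply_scorecard(card, {"x": -1e9}).per_feature["x"] == 10.0

    def test_unseen_category_gets_feature_mean_with_warning(self):
        card = card_from_scores({"g": {"a": 20.0, "b": 60.0}})
        with pytest.warns(UserWarning, match="unseen"):
            ps = apply_scorecard(card, {"g": "zzz"})
        assert ps.per_feature["g"] == 40.0

    def test_missing_value_rejected(self):
        card = card_from_scores({"x": 10.0})
        with pytest.raises(SchemaError, match="impute"):
            apply_scorecard(card, {"x": float("nan")})

    def test_total_matches_brute_force_lookup(self, mixed_attrs, mixed_cohort):
        """Independent oracle: look up each patient value segment by segment
        and sum by hand; must equal PatientScore.total exactly."""
        segments = {
            "signal": build_intervals(np.array([-0.8, 0.6])),
            "noise": build_intervals(np.array([0.0])),
            "group": category_segments(("a", "b", "c")),
        }
        entries = score_intervals(mixed_attrs, mixed_cohort, segments)
        card = fill_missing_intervals(normalize(entries))
        for i in (0, 17, 4242):
            patient = mixed_cohort.features.iloc[i].to_dict()
            ps = apply_scorecard(card, patient)
            brute = 0.0
            for feature, value in patient.items():
                matches = [e.normalized_score for e in card.entries[feature]
                           if e.segment.contains(value)]
                assert len(matches) == 1
                brute += matches[0]
            assert ps.total == brute

    def test_monotone_effect_yields_nondecreasing_segment_scores(self):
        """Directional sanity: a known monotone-increasing log-odds effect
        produces non-decreasing normalized scores along the segments."""
        from eachscore import (
            PiecewiseEffect, RiskSpec, compute_attributions, fit_gbdt, generate_cohort,
        )
        from conftest import fast_config

        schema = [FeatureSpec("x", "continuous", "", None, Normal(0, 1))]
        risk = RiskSpec(-1.5, (("x", PiecewiseEffect((-0.5, 0.7), (0.0, 1.0, 2.0))),))
        cohort = generate_cohort(schema, risk, 20_000, seed=6)
        model = fit_gbdt(cohort, fast_config(seed=6))
        attrs = compute_attributions(model, cohort)
        entries = score_intervals(attrs, cohort,
                                  {"x": build_intervals(np.array([-0.5, 0.7]))},
                                  stat="mean")
        card = normalize(entries)
        scores = [e.normalized_score for e in card.entries["x"]]
        assert scores == sorted(scores)


class TestReferencePatientAggregation:
    """Reference worked example: two patients' known per-feature scores
    must aggregate through the scoring path to the known totals."""

    LOW = {"age": (42.77, 49.02), "sex": ("male", 48.52), "height": (160.4, 49.78),
           "weight": (61.8, 48.60), "bmi": (24.02, 48.85), "asa": ("1", 46.17),
           "emergency": ("no", 47.10), "hypertension": ("no", 49.30),
           "diabetes": ("no", 49.83), "cardiovascular_accident": ("no", 47.39),
           "asthma": ("no", 50.00), "copd": ("no", 49.59), "liver_disease": ("no", 49.81),
           "kidney_disease": ("no", 49.80), "tuberculosis": ("no", 49.80),
           "surgery_type": ("low_risk", 0.0), "hemoglobin": (13.0, 49.66),
           "platelet": (293.0, 49.80), "bun": (14.0, 49.27), "creatinine": (0.0, 50.40),
           "albumin": (4.0, 50.54), "sodium": (137.0, 50.41), "potassium": (4.0, 53.46),
           "glucose": (81.0, 47.39), "prothrombin_time": (11.9, 52.13),
           "ptt": (28.0, 46.54), "ast": (14.0, 47.30), "alt": (22.0, 49.64),
           "egfr": (120.0, 49.06)}
    HIGH = {"age": (71.07, 51.82), "sex": ("male", 48.52), "height": (156.3, 49.91),
            "weight": (55.8, 53.02), "bmi": (22.84, 48.85), "asa": ("4", 53.76),
            "emergency": ("yes", 52.95), "hypertension": ("no", 49.30),
            "diabetes": ("no", 49.83), "cardiovascular_accident": ("no", 47.39),
            "asthma": ("no", 50.00), "copd": ("no", 49.59), "liver_disease": ("yes", 50.17),
            "kidney_disease": ("no", 49.80), "tuberculosis": ("no", 49.80),
            "surgery_type": ("high_risk", 100.0), "hemoglobin": (12.0, 49.49),
            "platelet": (92.0, 50.66), "bun": (8.0, 49.27), "creatinine": (0.0, 50.40),
            "albumin": (3.0, 55.35), "sodium": (137.0, 50.41), "potassium": (3.0, 50.75),
            "glucose": (115.0, 54.08), "prothrombin_time": (11.6, 52.13),
            "ptt": (28.0, 46.54), "ast": (64.0, 52.37), "alt": (78.0, 50.30),
            "egfr": (90.0, 50.83)}

    @staticmethod
    def card_and_patient(column):
        scores, patient = {}, {}
        for feature, (value, score) in column.items():
            patient[feature] = value
            if isinstance(value, str):
                scores[feature] = {value: score}
            else:
                scores[feature] = score
        return card_from_scores(scores), patient

    @pytest.mark.parametrize("column,total", [(LOW, 1379.16), (HIGH, 1517.29)])
    def test_total_equals_printed_sum(self, column, total):
        card, patient = self.card_and_patient(column)
        ps = apply_scorecard(card, patient)
        assert len(ps.per_feature) == 29
        assert ps.total == pytest.approx(total, abs=0.005)
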