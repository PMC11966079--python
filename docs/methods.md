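# Methods

This note records the model behind `eachscore`, the choices made where the
method leaves room, and what the synthetic experiments do and do not
establish.

## The scoring model

The pipeline turns a fitted gradient-boosted tree classifier into an
additive interval scorecard. Let `m(x)` be the model's raw margin
(log-odds). Exact tree-path Shapley attribution decomposes every
prediction as

    m(x_i) = phi_0 + sum_j phi_ij

with a constant base value `phi_0` and one term per feature. All scoring
happens in margin space: additivity is exact there (it is not in
probability space), and the downstream interval sums inherit that
exactness. The implementation uses LightGBM's built-in tree-path
attribution (`pred_contrib`), which satisfies the identity to ~1e-14; the
test suite enforces 1e-6.

For each continuous feature the pairs `(x_ij, phi_ij)` form a dependence
profile. Where the model's sensitivity to a feature changes, the profile's
slope changes; the scorecard's intervals are cut at the steepest such
changes (at most five per feature, so at most six intervals). Each
category of a categorical feature is its own segment — slope is undefined
on unordered categories.

A segment's **raw score** is the sum of training attributions of the
samples inside it. Summing (rather than averaging) makes a segment's score
scale with how much of the training population it affects, which is the
behaviour the cumulative patient score needs; an occupancy-independent
mean variant is available via `score_intervals(..., stat="mean")` for
sensitivity analysis. Per feature, the scored segments partition the
training samples, so segment raw scores conserve the attribution column
sum exactly (tested to 1e-9).

Raw scores are min-max normalized **globally** — one `(S_min, S_max)` pair
across all features — onto 0–100. This is what makes scores comparable
across features: a binary feature whose two categories carry the extreme
raw scores ends up scored 0 and 100. If every raw score is identical the
model is degenerate; every segment is set to 50 and a warning is raised.

A patient's total is the exact sum of their per-feature segment scores.
Interval edges are half-open `[lo, hi)` with unbounded extremes, so any
future value — including values outside the training range — maps to
exactly one segment.

## Change-point detection

Raw profiles are far too noisy for slope estimation, so they are reduced
to quantile bins first:

- **Binning.** Boundaries at equal ranks of the sorted profile
  (`n_bins = 50` by default); a boundary landing inside a run of equal
  values advances to the next value change, so point masses occupy bins by
  themselves. Bins under `min_bin_count = max(20, n/1000)` merge into
  their right neighbour (the last bin merges left) until every slope
  estimate rests on enough samples. Bin centers are in-bin mean values,
  which keeps the detector translation-equivariant.
- **Candidate scoring.** Slopes are chords between consecutive bin
  centers; the candidate at interior bin `j` is scored by the absolute
  second difference `|s_j − s_{j−1}|`. Selected points must be at least
  one bin apart (a noisy kink cannot consume several of the five slots),
  ties break toward the smaller feature value, and the returned point is
  the bin's left-edge value.
- **Noise threshold.** Candidates must strictly exceed
  `epsilon = 3 × 1.4826 × MAD` of the slope changes — the conventional
  robust ~3-sigma outlier cut (with a 1e-9-of-slope-scale floor against
  floating-point dust). An exactly linear profile has zero slope change
  everywhere and yields **no** points; a noiseless kinked profile has zero
  noise scale and yields exactly its kinks. A fixed small multiple of the
  slope SD was considered and rejected: on fitted tree ensembles the
  binned profile carries step-structure wiggle whose slope-change noise
  floor sits far above a 0.1-SD cut, so that rule spends top-5 slots on
  wiggle; the MAD cut tracks the actual noise level and leaves the
  noiseless contrasts unchanged.

On noiseless piecewise-linear binned profiles the detector provably lands
on the same boundaries as exhaustive segmented least squares; the test
suite checks this equivalence up to three kinks and thirty bins, and
checks on fitted models (10 seeded cohorts, n = 20,000, known breakpoints)
that ≥80% of detected points fall within 0.25 feature-SD of a true
breakpoint (measured: ~90%, both true breakpoints found in every seed).

## Sparse segments and missing data

Two distinct mechanisms, deliberately kept separate:

- **Patient-level missingness** is imputed with the training means/modes
  before scoring. The imputation table is frozen on the training split and
  re-applied verbatim to validation or external data — validation data
  never contributes to the constants.
- **Segment-level sparsity** (an interval that captured no training
  samples, e.g. beyond a detected breakpoint in a thin tail) is repaired
  after normalization: if both immediate neighbours (or the single
  neighbour, at an edge) are scored, the segment receives their mean; if
  any neighbour is itself unscored, local averaging is unsupported and the
  segment falls back to the feature-wide mean of scored segments. Unscored
  categories always take the feature-wide mean (categories have no
  adjacency). Filled scores are flagged and excluded from the
  normalization constants — they are derived values and must not shift the
  observed range.

## The synthetic cohort family

The simulator draws features independently from declared distributions and
the outcome from `Bernoulli(logistic(b0 + sum_j f_j(x_ij)))`, where each
`f_j` is piecewise-constant (continuous), a per-category level table, or
zero. The default preset mirrors a noncardiac-surgery registry: 29
features (17 continuous, 12 categorical) with realistic marginals, step
effects on albumin (<3.5, <4.1 g/dL), hemoglobin (<11 g/dL), age (>49,
>64 y), glucose (>110, >160 mg/dL), non-monotone effects on potassium and
BMI, categorical hazards for ASA class, emergency surgery, high-risk
surgery type and prior cerebrovascular events, and null features for the
rest. The intercept is calibrated by Monte-Carlo root finding so the
marginal prevalence hits a target (0.4% by default, the rare-event regime
the method is aimed at). Missingness is injected
missing-completely-at-random on features only, with NaN as the marker.

What the simulator does **not** emulate: feature correlation (age/eGFR,
height/weight/BMI are independent here), skewed laboratory marginals,
informative missingness, or time-to-event structure. Passing tests
therefore demonstrate that the machinery recovers known piecewise
structure and conserves its bookkeeping — not that the scorecard will
match a boosted model's AUC on any particular clinical cohort.

The breakpoint-recovery and nonlinearity-gain experiments use a deliberately
simple member of the family: one standard-normal feature with breakpoints
(−0.8, +0.6) and levels (1.5, 0.0, 1.2) — odds ratios ≈ 4.5 and 3.3,
strong but clinically plausible — at intercept −1.5 (≈30% prevalence) and
n = 20,000. At 0.4% prevalence and this n there are ~80 cases, too few for
any profile-based detector to see structure; the moderate-prevalence family
isolates the detector's behaviour from case starvation. Problem sizes
throughout the suite (n = 4,000–25,000, 2-fold CV, single-candidate grids
where the grid search itself is not under test) were chosen to keep the
default run at desk scale.

## Numerical and design notes

- **Determinism.** Every random draw flows from an explicit seed
  (simulation, split, model, bootstrap); LightGBM runs single-threaded
  deterministic. Two runs with the same config produce byte-identical
  scorecard JSON, which is why provenance carries a config hash rather
  than a timestamp.
- **Splitting.** Stratified by outcome with exact `round(f·n)` train size
  and per-class counts within one of `f × class size`. At sub-percent
  prevalence an unstratified split can leave a test set with no cases.
- **Grid search.** Mean CV AUC over stratified folds, maximizer refit on
  the full training set, ties to the first candidate in grid order. The
  default grid is small (depth × learning rate × estimators, 8 points);
  the selection procedure, not grid coverage, is the contract.
- **Class imbalance.** No resampling or reweighting by default; an
  optional `class_weight` switch is exposed.
- **AUC.** Mann–Whitney with ties counted one half; 95% CI from 1,000
  stratified percentile-bootstrap resamples (cases and controls resampled
  separately — at 0.4% prevalence unstratified resampling produces
  one-class replicates). Thresholds: Youden's J maximized over midpoints
  of consecutive distinct scores plus the minimum score, ties to the lower
  threshold, `score ≥ threshold` classified positive.
- **Logistic baseline.** Unpenalized main-effects fit on z-scored
  continuous features and drop-first dummies; z-scoring is conditioning
  only and does not change the fit.

## Known limitations

- With very rare outcomes the sum-statistic interval scores are dominated
  by segment occupancy and the scorecard can trail the linear baseline at
  whole-cohort level even when it wins on non-monotone features; the
  worked example in the README shows exactly this. The nonlinearity gain
  is established where it is claimed: on held-out data for features whose
  true effect is non-monotone.
- At most five change points per feature is a readability constraint, not
  a statistical one; effects with more than five genuine kinks are
  truncated to the steepest five.
- The detector assumes enough distinct values to form three quantile bins;
  features that fail this are scored as a single interval (the pipeline
  does this automatically).
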