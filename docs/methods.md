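# Methods

## Task model

The package encodes a seven-block center-out reaching session
(16/48/24/24/160/40/40 trials; 352 total). Eight targets sit 45° apart on
a 7 cm ring; a 63-number aiming ring (−31…31 at 5.625°) is shown during
the reporting blocks (blocks 3–5). A −45° (clockwise) cursor rotation is
applied only in the 160-trial rotation block; the aiming report and
stimulation flags follow the block table (reports in blocks 3–5,
stimulation in blocks 4–5). Target order is pseudorandomized under the
constraint that every consecutive 8-trial epoch contains each target
exactly once; epoch permutations are drawn independently with no further
constraint, and the familiarization block is balanced the same way (the
protocol gives no reason to treat it differently, and one code path is
simpler). Three setups differ only in feedback mode and screen context:
endpoint/horizontal, online/vertical, online/horizontal.

Sign conventions, used everywhere: hand angles are counterclockwise
positive with the target at 0°; the aim-number map is
aim° = −n × 5.625, fixed so that reporting −8 equals +45° of
counterclockwise compensation — the only mapping consistent with a
clockwise −45° rotation being countered by aiming at −8. Target error is
reported as normalized rotation-block hand angle − 45 (0 = full
compensation, negative = clockwise undershoot). That formula is stated
here prominently because the summary tables it reproduces never write it
down; it is forced by the near-identity explicit + implicit ≈ 45 + target
error.

## Synthetic cohorts

Each simulated subject is a two-process learner, the minimal generative
structure consistent with the additive explicit/implicit decomposition the
analysis assumes. With explicit state x_e and implicit state x_i (both in
degrees, starting at 0):

- aim = x_e clipped to ±explicit_cap, snapped to the 5.625° grid; on
  reporting trials Gaussian report noise (SD sigma_report, in number
  units) is added before snapping, and the snapped integer is what the
  subject "says";
- hand = aim + x_i + N(0, sigma_motor);
- cursor = hand + rotation; target error e = cursor (common frame);
- with visual feedback: x_e ← x_e − eta_explicit · e (on reporting trials
  only), x_i ← A_implicit · x_i − B_implicit · (cursor − aim);
- without feedback: x_i ← A_implicit · x_i, strategy frozen.

The implicit error signal is the aim-to-cursor discrepancy, not target
error, matching the view of implicit adaptation as driven by sensory
prediction error relative to the intended direction. The strategy is
applied only while the aiming ring is on screen; in the no-feedback and
washout blocks the subject aims straight at the target, which makes the
aftereffect reflect the implicit state alone — the behavior real
aftereffect magnitudes (~12°, far below explicit + implicit) imply.

Trajectories are rendered at 100 Hz: a minimum-jerk radial profile from 0
to 8 cm, time-scaled so the 1 cm radius is crossed at RT and the 7 cm
radius at RT + MT, with direction hand angle plus one smooth angular bump
per reach (SD 0.2°, clipped at 2.5 SD) as curvature noise. Per-trial RT
and MT are Gaussian around per-subject means.

Cohort-level variability comes entirely from per-arm parameter
distributions (clipped normals). Defaults were calibrated once to the
study conditions: the endpoint/horizontal setup uses a fast strategy and
low implicit sensitivity (eta ≈ 0.15, A ≈ 0.98, B ≈ 0.010), giving pooled
group means of explicit ≈ 30°, implicit ≈ 13° over the rotation block; the
online/vertical setup slows the strategy and raises implicit sensitivity
(eta ≈ 0.05, B ≈ 0.022), shifting the balance toward implicit learning.
Arm effects are mean shifts only (dlPFC-like: +0.05 on eta; CB-like:
+0.006 on B). Heavy-tailed inter-individual variability is emulated by a
mixture: with probability 0.1 a subject's eta and B are drawn with 3×
inflated SD. Context and feedback influence behavior only through these
distributions, keeping the generator orthogonal to the analysis pipeline.

What the generator does **not** emulate: online feedback corrections
within a movement, use-dependent or savings effects, reporting latencies,
target-specific biases, temporal drift in motor noise. Passing tests
therefore certify the pipeline's arithmetic and its statistical
calibration under the assumed additive structure — not that real data
satisfy that structure.

## Kinematics

Hand angle is the chord between the points where the trajectory first
crosses radii 1 and 7 cm ("along the trajectory" is read as radial
distance, consistent with the 7 cm ring and standard practice). Crossings
are linearly interpolated between the straddling samples; the first
crossing is used if noise causes re-entry. RT = target onset to the 1 cm
crossing, MT = 1 cm to 7 cm; MT > 400 ms (strictly) flags the trial too
slow. Angles are wrapped to (−180, 180]. Trials that never reach 7 cm are
flagged invalid and excluded from means with a logged count, never
silently dropped; too-slow trials are kept by default (a filter is
exposed), since the reference analysis does not state its handling.

## Measures and screening

Epoch means average 8 consecutive trials, with invalid trials reducing the
count (an all-invalid epoch is missing). Baseline bias is the mean of the
final 8 valid trials of the last baseline block (fewer are used, with a
warning, if necessary). The subject's rotation-block mean uses trial means
over all valid trials (epoch means are available and identical when
nothing is missing); explicit/implicit summary means are restricted to
trials with both valid kinematics and a recorded report, which is what
makes explicit + implicit = normalized hand angle an exact identity on
that set. The outlier screen is a single pass per group over the three
rotation-block measures (target error, explicit, implicit) with inclusive
mean ± 3 SD bounds: a value exactly at a bound is kept, an all-identical
group excludes nobody, and groups smaller than 3 are skipped with a
warning. One pass (not iterated) matches the single exclusion count
reported per experiment in the reference tables.

## Statistics

All tests operate on (n, mean, sample-SD) sufficient statistics; raw-data
overloads reduce to the same quantities and agree to ~1e−10.

- One-way ANOVA: SSW = Σ(nᵢ−1)sᵢ², SSB = Σnᵢ(mᵢ−m̄)² with the weighted
  grand mean; η_p² = SSB/(SSB+SSW), f = √(η²/(1−η²)).
- Tukey–Kramer: q = |Δm| / √(MSW/2 · (1/nᵢ+1/nⱼ)); p from the
  studentized-range distribution (scipy), cross-checked in the tests
  against direct numerical integration of its density.
- t-tests: Student pooled-variance by default (it reproduces the printed
  t, d, g values; Welch is an option). d uses the pooled two-group SD
  (also inside Tukey output — that is what matches printed pairwise d);
  g = d · (1 − 3/(4N−9)), the form that reproduces the printed g.
- 2×3 factorial: Type-III (unweighted-marginal-means) sums of squares via
  Wald quadratic forms on sum-to-zero regression coefficients computed
  from cell ns/means; MS_error pools within-cell variances. A raw-data
  overload through statsmodels OLS/anova_lm (typ=3, Sum coding) agrees to
  1e−8. The 2-level context effect is reported with df = 1 (a source
  table prints "F(2,52)" for it, but the recomputed F matches at df 1/52,
  so the label is treated as typographical).
- JZS Bayes factors: Cauchy prior on standardized effect size implemented
  as a normal-with-inverse-gamma-mixed variance g; the t-test BF uses the
  effective-sample-size form (default scale √2/2), the one-way ANOVA BF
  the fixed-effects formulation (default scale 0.5) with standardized
  group effects on the sum-to-zero projection. Marginalizing location and
  scale analytically leaves a 1-D integral over g, evaluated by adaptive
  quadrature with the quadrature error reported alongside the value.
  From full summaries the ANOVA BF is exact; from (F, ns) alone the mean
  direction is unidentified for unbalanced groups, so the geometric mean
  over pairwise-difference patterns is returned (pattern-free for balanced
  designs; ≤2% spread at the imbalances handled here), with the spread
  folded into the error estimate.
- Power: exact noncentral-t with noncentrality d√(n/2) and df 2n−2;
  smallest integer n ≥ 2 with power ≥ target, by forward scan.
- p-values are reported unadjusted for the a-priori t-tests, and no
  multiple-testing correction is added beyond Tukey, matching the
  analysis the tables come from.

## Numerical choices and problem sizes

Quadrature uses scipy `quad` on (0, ∞) with limit 200; integration-error
estimates accompany every BF. Degenerate inputs: zero pooled variance
with unequal means yields an infinite-t sentinel (p = 0); zero-variance
groups give F = ∞ only when means differ. Monte-Carlo calibration tests
use sizes chosen for tight-but-fast checks on one CPU: 10,000 vectorized
null replicates for ANOVA type-I error, 200 full simulated pipelines for
the end-to-end null calibration, 30×1000 subjects for the outlier-rate
check, 100-subject cohorts for parameter recovery; assertions use 4
binomial SEs around the nominal value.

## Known limitations

Summary-based recomputation inherits the 2-decimal rounding of printed
inputs (recomputed statistics drift by up to ~0.02 from printed ones).
The generator's learner is intentionally minimal; it is not a fitted
model, and the package does not fit state-space models to data. Washout
dynamics are simulated but only summarized as epoch curves. The
three-group f = 0.7 sample-size figure quoted from earlier work is not
recomputed (its software rounding convention is unknown); only the
two-group noncentral-t calculation is.
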