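# Methods

## Problem setting

A wrist-worn biosensor records four physiological channels — blood volume
pulse (BVP, 64 Hz), electrodermal activity (EDA, 4 Hz), skin temperature
(TEMP, 4 Hz) and heart rate derived from the pulse (HR, 1 Hz) — while the
wearer marks distress episodes with a button press.  Presses are point
events; episode duration is unknown.  Detection is cast as binary
classification of 5-min windows: the window ending at a press is an
*event*, the 5 min after the press is an excluded *buffer* (the episode may
continue past the press, so neither label is safe there), and *nonevents*
are sampled from the remaining wear time.  Windows are treated as
independent observations, with participant identity available as a cluster
key.

## Synthetic cohort generator

The generator is the package's study population.  Its defaults mirror the
reference cohort's marginals (`e4wild.reference`): 8 participants, 4–48
recording days, 4–11 wear hours/day, and per-participant tag rates whose
rate × exposure products total ≈ 1,639 presses; `reference_cohort_spec()`
pins each participant to the exact marginal row.

Signal model, per session (one session per participant-day, starting
between 08:00 and 12:00 UTC):

* **HR** — AR(1) mean-reverting walk (a = 0.995, innovation sd 0.6 bpm,
  stationary sd ≈ 6 bpm) around a 72 bpm baseline plus the participant's
  random intercept; clipped to 45–140 bpm.
* **BVP** — amplitude-modulated two-harmonic pulse whose instantaneous
  frequency is the HR channel / 60, so HR is consistent with the
  oscillation it is nominally derived from.  The envelope (≈ 0.8 a.u.)
  drifts slowly; additive sensor noise sd 0.05.
* **EDA** — tonic level ≈ 1.5 µS plus the participant intercept, drifting
  as an AR(1) on a 4-s grid (interpolated, so the drift has no power in the
  phasic band); phasic activity is a Poisson train of skin conductance
  responses (baseline 2/min, biexponential kernel with rise 0.7 s / decay
  4 s, lognormal amplitudes around 0.3 µS).  The measurement-noise floor is
  sd 0.001 µS, deliberately below the 0.01 µS SCR prominence threshold so
  the detector counts injected responses, not noise.
* **TEMP** — ≈ 33 °C with slow drift.
* **Non-wear** — one contiguous block per session (default 5 % of the
  session) overwritten with off-wrist readings (EDA 0, TEMP ≈ 25.5 °C).

Each tag injects a signature over `[tag − onset_lead, tag − onset_lead +
duration)` (defaults 270 s lead, 300 s duration, so the change mostly
precedes the press, as distress precedes the decision to report it):
SCR rate and amplitude × `eda_phasic_gain` (default 2.5), BVP envelope
tilted by `bvp_slope_shift` (default 0.02 /s, zero-mean ramp), HR +
`hr_delta` (default 8 bpm).  No field estimates of these effect sizes
exist; the defaults are plausible acute-arousal magnitudes and are free
parameters, not claims about any real cohort.  `EffectSpec.null()` removes
the signature entirely; random draws follow a fixed consumption pattern, so
null and event-free runs are byte-identical under the same seed.

Cluster heterogeneity is an i.i.d. per-participant additive shift of the HR
baseline (sd 5 bpm) and tonic EDA (sd 0.4 µS) — the random intercept a
mixed-effect model can exploit, and the mechanism that makes
cross-participant generalization harder than within-participant
generalization.

What the generator does **not** model: realistic PPG morphology
(dicrotic notch, beat-to-beat variability structure), motion artifacts,
accelerometer/inter-beat-interval channels, circadian EDA/TEMP rhythms, or
any dependence of tagging behavior on physiology (tags are a Poisson
process independent of the signals).  Passing tests therefore demonstrate
pipeline correctness and statistical calibration, not clinical performance
on real recordings.

## Wear filtering

Non-wear is flagged where EDA < 0.03 µS **and** TEMP < 30 °C for ≥ 5 min —
a standard off-wrist heuristic; all three thresholds are arguments.  Sleep
is a recurring clock window (default 23:00–07:00 UTC) because no sleep
annotation exists; precedence sleep > non-wear > wear, and the three states
always partition the session span.  Tags inside masked time are dropped
and counted.  Intervals are half-open `[start, end)` in UNIX seconds;
channel sample *i* covers `[start + i/rate, start + (i+1)/rate)`.

## Windowing

Tags are processed in time order; a tag is kept only if its event window
lies wholly in wear time and clears the previous kept tag's buffer
(inter-tag gap ≥ 600 s).  The stricter-than-minimal drop rule keeps every
event window disjoint from every buffer, which the suite checks
exhaustively.  Nonevent starts are drawn uniformly on the whole-second grid
(1 s is the coarsest common grid of all four channels, keeping every slice
sample-aligned, including 1 Hz HR); each placed window is removed from
eligibility before the next draw.  The cohort nonevent budget is
`ratio × events` (default ratio 1.67, matching the realized
negatives-per-positive of the reference analysis) apportioned by eligible
time, with ≥ 3 per session.  Windows containing any gap or masked time are
rejected, not imputed.

## Features

66 features in fixed order (24 BVP / 9 HR / 5 TEMP / 28 EDA).  The exact
upstream catalog is not public; this catalog reproduces the published group
counts and contains the feature families reported as most important (BVP
slope, frequency content, variability).  Spectra: Welch, 64-s Hann
segments, 50 % overlap; band powers by trapezoidal integration of the PSD;
spectral entropy is Shannon entropy of the normalized PSD scaled to [0, 1].
EDA tonic = zero-phase 4th-order Butterworth low-pass at 0.05 Hz, phasic =
residual (sum reconstructs the input exactly); SCRs are phasic peaks with
prominence ≥ 0.01 µS, with onset at the prominence base, rise time
onset→peak, and half-recovery peak→half-amplitude crossing (excluded from
means when unobserved).  Degenerate (constant) slices define skewness,
kurtosis, spectral entropy and dominant frequency as 0 so vectors stay
finite.  Standardization is always fit on training rows only and applied
to all rows — fitting on pooled data would leak test statistics into
training.

## Models

All four families share `fit / predict_score / predict_label` with scores
in [0, 1] and a 0.5 default threshold.  Class imbalance is handled by
duplicating positive rows with replacement until counts match (inside
every fit, after standardization); duplication rather than synthetic
interpolation keeps the feature distribution untouched.

MERF is classification-via-regression: a random-forest regressor on 0/1
labels plus per-cluster intercepts, alternating (E) the closed-form
intercept posterior mean `b_i = σ_b² Σr_i / (σ² + n_i σ_b²)` with (M) a
forest refit on `y − b` and moment updates of `σ², σ_b²`; a generalized
log-likelihood trace is recorded and the best state kept (max 3–5
iterations by default — the trace flattens quickly at these sample sizes).
The forest seed is fixed across iterations, so pinning `σ_b² = 0` makes
the fit *exactly* a plain forest on the labels; predictions for unseen
clusters use the forest alone.  Hyper-grids default to ≤ 2 points per
family so nested selection stays cheap; they are plain dicts.

## Evaluation

Inner selection maximizes validation accuracy: an explicit validation arm
where the scenario defines one (temporal/personalized), a stratified inner
k-fold over the pool for the random scenario (k shrinks to the feasible
maximum for small tables), and rotated held-out participants (≤ 4
rotations) for the participant scenario.  The participant scenario's
summary weights each test participant by its share of test windows — the
natural reading of population-percentage weighting; other scenarios use
unweighted fold/repetition means with standard errors.  Fold averaging
(not pooled predictions) is the primary aggregation.  Temporal repetitions
share one hold-out split; variability across the 10 repetitions comes from
oversampling draws and model seeds.  Paired personal-vs-temporal t-tests
are two-sided, uncorrected (a multiplicity caveat applies; with ~5 metrics
× 8 participants, a few p < 0.05 are expected by chance).

Feature attributions are Saabas-style tree-path contributions: each
split's change in node prediction is credited to the split feature, giving
per-observation signed values (positive pushes toward the event class);
permutation importance is the fallback for non-tree models.

Learning curves fit `a − b·n^(−c)` by bounded nonlinear least squares
(`a ∈ [0,1]` for bounded metrics, `c ∈ [0,10]`, multi-start over 8
initializations); `b ≈ 0` or `c ≈ 0` is flagged degenerate (flat curve),
and extrapolation to a target above the fitted asymptote is flagged
unreachable.  The power analysis fixes one participant's temporal test
split and down-samples the training split to 10/25/50/75/90/100 % by
label-stratified sampling, the 100 % fraction once and the others 10
times by default.

## Problem sizes and numerical choices

The test suite and acceptance script run cohorts of 3–4 participants with
1–2 sessions of 1–1.5 h per day (≈ 40–120 windows), two-candidate grids,
forests of 40–50 trees, outer k = 5, inner k = 3 — sizes chosen so each
statistical check (null calibration, scenario ordering, recovery
simulations) completes in seconds while leaving Monte-Carlo noise small
relative to the asserted margins.  The full-scale reference cohort
(≈ 2,405 wear-hours) is exercised only where signals are not needed
(tag-count arithmetic); nothing prevents running the generator at that
scale.  Ties in Spearman correlations use average ranks (scipy); ROC AUC
is trapezoidal; precision is defined as 0 when no positive predictions are
made, F1 as 0 when precision + recall = 0.

## Known limitations

* The feature catalog is a reconstruction constrained by the published
  group counts, not the original list; it is data, swappable without code
  change.
* MERF's variance updates are moment-style (EM with the current posterior)
  on a 0/1 response; `σ_b²` is a heuristic on the probability scale, not a
  calibrated logistic variance component.
* The sleep mask is a fixed clock window; real adolescents' sleep varies.
* Temporal splits use observation-day quantiles (floor at 75 %, ceil at
  87.5 %), which guarantees non-empty validation/test arms only for
  participants with ≥ 8 observation days; shorter participants are skipped
  in the personalized scenario.
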