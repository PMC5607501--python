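# Methods

This note documents the models the package implements, the assumptions
behind them, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical choices that matter.

## T2 relaxometry under Rician noise

Magnitude MR images carry Rician noise: the observed magnitude is
`m = |(ν + g₁) + i·g₂|` with independent `g₁, g₂ ~ N(0, σ²)` around the
noiseless signal `ν`. At low SNR this biases magnitudes upward (`E[m] →
σ√(π/2)` as ν → 0), so ordinary least squares on `ln m` vs TE — the
classical T2 fit — overestimates T2 whenever the late echoes approach the
noise floor.

The estimator of record is therefore the maximum-likelihood fit of
`(S₀, T2)` under the full Rician log-likelihood, with `ν = S₀·e^(−TE/T2)`.
Implementation choices:

- `ln I₀(x)` is evaluated as `ln(ive(0, x)) + x` (exponentially scaled
  Bessel), stable for arbitrarily large arguments.
- Optimization is bounded quasi-Newton (L-BFGS-B) over `(ln S₀, T2)`,
  initialized from the log-linear fit; when the initializer fails or the
  optimizer does not converge, a coarse profile-likelihood grid scan
  restarts it. Tests verify the optimum against an exhaustive 0.5-ms-grid
  profile search.
- T2 is bounded to [1, 300] ms — the myocardial range plus headroom — and
  an optimum resting on a bound is reported with an explicit
  `clipped_low`/`clipped_high` status rather than silently accepted.
  Degenerate inputs (all-zero signal, no decay) fail with status codes,
  never with fabricated values.
- The noise scale is treated as known per slice, estimated once from a
  signal-free background region via the Rayleigh relation
  `σ = RMS(background)/√2`. Per-pixel σ estimation is deliberately out of
  scope; a homogeneous coil-noise floor per slice is assumed.
- All echoes are used by default, including the first. Dropping the first
  echo (a common practice with gradient-spin-echo readouts, where it
  behaves differently) is a caller decision: pass a reduced
  `MultiEchoStack`.

Measured on the package's own Monte-Carlo conditions (six echoes
16–96 ms, S₀ = 1000, T2 = 60 ms, σ = 20): the MLE's mean bias is about
+0.1 ms against +0.3 ms for the log-linear fit; at a first-echo SNR of ~7
the gap widens to roughly +3.7 vs +8.9 ms. The bias *ordering* is robust
across noise levels; the absolute MLE bias grows at very low SNR because
only six echoes inform each pixel.

## AHA segmentation and the inhomogeneity statistics

Three short-axis slices (basal, mid, apical) are parcellated by pixel
angle about the slice centroid, anchored at the anterior RV-insertion
ray: six 60° sectors on basal and mid (segments 1–6, 7–12), four 90°
sectors apically (13–16). No apex segment is defined — a three-slice
protocol does not cover the true apex. Angles are measured clockwise in
image-display coordinates (rows grow downward), the orientation
clinicians see. A pixel exactly on a sector boundary joins the
counter-clockwise-following segment; the branch cut at the insertion ray
is handled by modular arithmetic. The partition is exact: segment pixel
counts sum to the mask size, and the pixel-count-weighted mean of
segmental means reproduces the global masked mean to machine precision.

Per segment, the mean T2 and the sample standard deviation (n−1) of the
pixel T2 values ("pixel-SD") are recorded; segments under `min_pixels`
(default 10) are flagged and excluded downstream, with the count of used
segments reported. Subject level:

- `maxT2` — the largest segmental mean;
- `madSD` — the mean absolute deviation of the segmental pixel-SDs about
  their arithmetic mean. The mean-centred form matches the phrase "mean
  absolute deviation"; a median-centred variant is available via
  `summarize(..., center="median")`.

Focal inflammation raises one or two segments' T2 and inflates the spread
of pixel-SDs, so both statistics move while the myocardium-wide mean
barely does — that is the premise of the approach.

Group comparison uses a Shapiro–Wilk gate (α = 0.05, per parameter, per
group): Welch's unequal-variance t-test when both groups look Gaussian,
otherwise the Wilcoxon rank-sum test. Groups under n = 3 skip testing.
No multiple-testing correction is applied.

## Feature-tracking strain

An end-diastolic contour is propagated frame to frame by normalized
cross-correlation block matching: 15×15 template, 25×25 search window
(±5 px/frame), parabolic sub-pixel peak refinement. Refinement is skipped
when the integer-lag match is already exact (score ≈ 1), where it would
only amplify neighbour asymmetry. Matches with peak correlation below 0.5
are replaced by the mean displacement of the nearest confident neighbours
along the contour and flagged. Because frame-wise matching accumulates
drift over a cycle, the residual displacement after tracking once around
(including the wrap back to frame 0) is removed by linear redistribution
across frames.

Strain is Lagrangian and perimeter-based: `ε(t) = 100·(L(t) − L(0))/L(0)`
with L the polyline length (closed for short-axis, open for four-chamber
contours). Strain rate is the time derivative of the strain fraction
(central differences, one-sided at the endpoints), in 1/s. Global
circumferential strain is the arithmetic mean of the three per-slice
*peak* values (peak-then-average); averaging the curves first and then
taking the peak is available behind `average_curves_first=True`. Peaks
are signed extrema — most negative for contraction — and the reported
peak strain rate is the global signed extremum of the SR curve, not the
systolic-only extremum. The right ventricle is handled identically to the
left given its contour.

## Lake Louise criteria

T2-ratio = myocardial / skeletal-muscle signal on T2-weighted black-blood
images, pathological at ≥ 1.9 (boundary inclusive). EGEr is the standard
relative-enhancement ratio `[(myo_post − myo_pre)/myo_pre] /
[(sm_post − sm_pre)/sm_pre]`, pathological at ≥ 4; zero or negative
muscle enhancement renders it undefined (flagged, never coerced to a
number). Diagnosis is positive at ≥ 2 of 3 criteria. The edema criterion
defaults to ratio-OR-visual (both assessments are performed in practice);
`edema_mode="ratio_only"` restricts it to the ratio.

## Diagnostic modelling

- **Logistic models** are fit by IRLS (statsmodels `Logit`); AIC is
  recomputed from the log-likelihood as `2k − 2lnL` with the intercept
  counted. Perfect or quasi-perfect separation is detected (statsmodels'
  separation warning, or any |slope| > 20) and flagged; a
  ridge-stabilized fallback keeps coefficients finite, and fully
  degenerate designs fall back to the intercept-only baseline with
  `converged=False`. Collinear predictors fit with a condition-number
  warning rather than an error, since near-collinearity of related
  parameters is an expected finding, not a failure.
- **ROC/AUC** uses the rank (Mann–Whitney) formula with midranks, which
  equals the pairwise count with half-credit for ties exactly; ROC points
  are emitted at every distinct threshold. Tests pin it against an O(n²)
  pair-count oracle and scikit-learn.
- **Cut-off discovery** is a depth-one classification tree: exhaustive
  scan of midpoints between consecutive distinct sorted values,
  maximizing Gini impurity decrease (entropy behind
  `criterion="information"`), both leaves ≥ `min_leaf` (default 7, a
  small-cohort-appropriate floor), ties broken toward the smaller
  threshold. The abnormal direction is the patient-majority side, so
  higher-abnormal (madSD, maxT2) and less-negative-abnormal (strain)
  rules fall out automatically.
- **Combined rules** are k-of-k: a subject is test-positive only when
  every criterion is met. This matches the sensitivity definition used
  with published cut-off combinations; its natural complement (controls
  count as true negatives unless all criteria are met) defines
  specificity. Since each added criterion can only shrink the positive
  set, sensitivity is non-increasing and specificity non-decreasing in
  the number of criteria — asserted as a test. Two AUCs are reported:
  the logistic model over the same predictors (continuous) and the
  binary rule output itself, since a rule-based AUC is otherwise
  ambiguous.
- Report percentages are rounded to integers for display; all
  comparisons and tests use the exact fractions. Undefined ratios (zero
  denominators) are reported as not-applicable, never as 0.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical* structure the analyses rest
on, not MR physics:

- **Decay pixels** — exact mono-exponential signals plus complex-Gaussian
  magnitude (Rician) noise, the standard construction. No k-space,
  B₀/B₁, motion, or stimulated-echo effects.
- **Heart phantoms** — a three-slice annulus with focal sector lesions
  (subepicardial by default, the typical myocarditis pattern), uniform
  base T2, per-pixel lesion jitter, and pure-noise background usable for
  σ estimation. The ground-truth T2 field is amplitude-independent by
  construction.
- **Cine phantoms** — the end-diastolic contour scaled about its centroid
  so the perimeter follows the prescribed strain curve exactly, then
  rigidly translated; frames render Gaussian speckle markers attached to
  the material points. Real speckle decorrelates and real walls shear;
  passing the recovery tests shows the tracker's mechanics are sound, not
  that it matches clinical feature-tracking software.
- **Cohorts** — independent Gaussian draws per parameter from the
  published group means/SDs (17 controls / 67 patients, LGE prevalence
  0.52 / 0.00 by default). madSD, which cannot be negative, is drawn from
  a zero-truncated normal whose *underlying* mean is solved (Newton on
  `μ + σ·φ(μ/σ)/Φ(μ/σ)`) so the post-truncation mean equals the published
  group mean. Inter-parameter correlations are not published and are not
  modelled; cohort-level metrics (AUCs, tree cut-offs) from these draws
  are therefore seed-dependent surrogates and are asserted only for
  internal consistency, never against the published cohort's values.

Every generator is bit-reproducible under a fixed seed.

## Problem sizes

The shipped test and acceptance runs use: 10⁴ pixels for Monte-Carlo MLE
recovery (50 pixels for the grid-oracle check), 96–128 px phantom grids,
20 cine phantoms of 20 frames / 48 contour points at 128² resolution, and
cohorts of 17 + 67 (10⁴–10⁵ per group for generator-calibration checks).
These sizes make every documented recovery property measurable while
keeping a full run in minutes on one core.

## Known limitations

- The per-pixel Rician MLE retains a finite-sample bias at very low SNR
  (six echoes per pixel); only the comparison against the log-linear fit,
  not absolute unbiasedness, holds there.
- The tracker assumes in-plane motion of a persistent speckle pattern;
  through-plane motion and decorrelation are not modelled, and radial
  strain and torsion are out of scope.
- Segmentation takes masks and RV-insertion landmarks as given; no
  automatic myocardium delineation.
- LGE and visual edema enter as binary flags; image-based reading of
  either is out of scope, as are T1/ECV mapping.
- Tree cut-offs from 84-subject cohorts have wide sampling variability;
  the package reports them per cohort and makes no stability claim
  without resampling (cross-validation is deliberately not implemented).
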