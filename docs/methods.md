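# Methods

## Problem and scope

`swaylab` analyses quiet-stance postural sway recorded as a
center-of-pressure (COP) trajectory on a force platform, with the goal of
discriminating people with Parkinson's disease (PD) from healthy older
adults (HOA). Each subject contributes one eyes-open (EO) and one
eyes-closed (EC) trial of anteroposterior (AP) and mediolateral (ML) COP
coordinates in mm, sampled at 10 Hz for 15 s (150 samples per axis). The
package covers the full pipeline: signal conditioning, extraction of 34
stabilometric parameters, univariate group statistics with dual
multiple-comparison control, and a repeated-split ensemble classification
harness — exercised end-to-end on a synthetic cohort generator, since no
clinical recordings ship with the package.

## Signal conditioning

Each axis is filtered with a 4th-order Butterworth bandpass, cutoffs
0.005–4.9 Hz, then linearly detrended. At 10 Hz the upper cutoff sits at
0.98 of Nyquist, so the filter is designed in second-order sections for
numerical stability. Application is zero-phase (forward–backward, with
odd-symmetric edge padding of length 3·order), which preserves the
temporal alignment of the AP/ML pair; "4th order" refers to the designed
order before the bidirectional pass, which squares the magnitude
response. A causal single-pass mode is retained as a configuration
switch for sensitivity analyses. After filtering and detrending the
signal mean is numerically zero, so the standard deviation (about the
mean, N−1) and RMS (about zero, N) of the same axis agree to within
sampling-factor √((N−1)/N).

## The 34 stabilometric parameters

Seventeen parameters per condition, EC names carrying an `_EC` suffix,
in canonical order: TOD, Std-AP, Std-ML, RMS-AP, RMS-ML, DA-AP, DA-ML,
V-AP, V-ML, Area, V-T, LF-AP, MF-AP, HF-AP, LF-ML, MF-ML, HF-ML.

- **TOD** (mm): Σᵢ √((apᵢ−āp)² + (mlᵢ−m̄l)²) — total sway path relative
  to the mean COP position.
- **Std / RMS** (mm): per-axis dispersion, as above.
- **DA** (mm): per-axis peak-to-peak amplitude, max − min.
- **V-AP, V-ML** (mm/s): (Σ|Δx|)·fs/(N−1) — the mean absolute step per
  displacement interval times the sampling rate.
- **V-T** (mm/s): same with 2-D step magnitudes √(Δap²+Δml²).
- **Area** (mm²): 95% confidence-ellipse area π·χ²₂(0.95)·√det(Σ), Σ the
  sample covariance (N−1) of the AP/ML pair. The χ² multiplier
  (5.991…) is the large-sample convention; no small-sample F correction
  is applied, and the multiplier is configurable. A singular covariance
  (collinear trajectory) yields area 0.
- **LF/MF/HF** (mm²/Hz): sums of one-sided boxcar-periodogram density
  ordinates over 0.01–0.1 Hz, >0.1–0.5 Hz and >0.5–1.0 Hz. The
  periodogram is Parseval-normalised (Σ P·Δf equals the mean square of
  the detrended signal). No windowing or segment averaging: a 150-sample
  record leaves no room for Welch averaging. Band edges at exactly 0.1
  and 0.5 Hz would belong to the lower band per the ">" convention, but
  with Δf = 1/15 Hz no bin falls on an edge, so the rule is inert for
  the reference geometry. A configuration flag switches the band values
  to integrated power (×Δf, units mm²); density sums are the default
  because the printed units of reference tables are mm²/Hz. Note the LF
  lower edge (0.01 Hz) lies below the 1/15 Hz resolution of a 15-s
  record, so LF effectively contains the 0.067 and 0.1 Hz bins only.

Velocity denominators use N−1 (the number of displacement intervals),
not N. The whole pipeline (filter → detrend → features) is applied
uniformly; features are translation-invariant and scale-equivariant
(mm features scale with k, areas and band powers with k²), which the
property tests verify.

## Univariate statistics

Each of the 34 parameters is compared between groups with the
Mann–Whitney U test (midranks; exact enumeration p when the pooled
sample is ≤12 without ties, otherwise the normal approximation with tie
and continuity corrections — the threshold is a desk-scale exactness
choice). Shapiro–Wilk (per group) and Levene (mean-centred) screening
p-values are recorded but deliberately gate nothing: the comparison test
is fixed, and re-deriving a normality-dependent branch would be
guesswork. Descriptives are median and IQR with linear-interpolation
(type-7) quantiles. Raw p-values are adjusted two ways, reported
separately: Bonferroni with family size fixed at m = 34, and
Benjamini–Hochberg step-up q-values. Significance is declared at
adjusted p < 0.05. BH q never exceeds the Bonferroni p, so the
Bonferroni-significant set is a subset of the FDR-significant set.

## Classification harness

PD is the positive class throughout; sensitivity = PD recall,
specificity = HOA recall.

- **Splits.** 15 stratified 70/30 train–test splits with seeds 0..14;
  seed 0 is the representative run. Per-class test counts are rounded
  half-up, so 37 HOA + 26 PD yields an 11 + 8 = 19-sample test set.
- **Leak-free preprocessing.** Mean imputation of missing feature cells
  and standardisation to zero mean / unit SD are fitted on the training
  partition of each split (and of each inner CV fold) only. A feature
  with zero training SD is centred, not divided, and flagged.
- **Tuning.** Each base learner (random forest, gradient boosting,
  RBF/linear/poly SVM) is tuned by exhaustive grid search with 3-fold
  stratified CV maximising ROC AUC; ties break in favour of the earlier
  combination in grid enumeration order (first listed key outermost).
  The full grids are the reference search space; a reduced grid
  (`GridSpec.small()`) with the same learners is used for the test suite
  and the acceptance script, which report the problem sizes they used.
- **Ensemble.** Soft voting: the unweighted mean of the three members'
  PD probabilities, threshold 0.5, ties predicting PD (fixed for
  determinism).
- **Metrics.** Confusion counts, accuracy, per-class precision/recall/
  F1, and AUC by the rank (pairwise) method with midranks for score
  ties; single-class truth leaves AUC undefined (NaN, flagged).
- **Bootstrap.** Each metric's 15 per-split values are resampled 1000
  times with replacement; the summary is the observed mean with the
  2.5/97.5 percentile interval of resample means. The bootstrap operates
  on the per-split results, not on pooled test predictions.
- **SMOTE.** Class imbalance (1.42:1) can be addressed by synthetic
  minority oversampling inside each training partition and CV fold (k =
  5 neighbours, the technique's canonical default; never applied to test
  data). SMOTE is implemented in-package: each synthetic sample is a
  uniform convex combination of a minority point and one of its k
  minority-class nearest neighbours. The SMOTE and plain pipelines are
  compared on the same splits with two-sided paired Wilcoxon signed-rank
  tests per (model, metric), BH-corrected across the family; all-zero
  difference vectors are reported as NA. The plain pipeline is the
  default.
- **Importances.** Mean-decrease-impurity feature importances are
  extracted from the tuned tree models (RF, GB) fitted on the
  representative split's training data. Rank concordance between two
  importance vectors uses Spearman's ρ with midranks; the p-value is an
  exact permutation value for n ≤ 8 and the t approximation otherwise
  (the package only calls this at n = 34). Note that with strongly
  correlated features, impurity importance splits credit across a
  correlated block — particularly for random forests, whose per-split
  feature subsampling (`max_features='sqrt'`) spreads attribution; GB
  considers all features at each split and concentrates credit on the
  strongest representative.

## Synthetic cohort generator

Each axis of each trial is a stationary damped stochastic oscillator,
x'' = −2ζω x' − ω² x + σξ(t), discretised exactly: the state transition
is the matrix exponential over one sample interval and the discrete
noise covariance follows from the stationary Lyapunov solution, so there
is no step-size bias and the trajectory is strictly proportional to the
drive σ. Trials start from the stationary distribution.

Defaults (37 HOA + 26 PD, 10 Hz, 15 s) place the healthy baseline at
published healthy quiet-stance magnitudes (AP std ≈ 1.4 mm and AP
velocity ≈ 4.7 mm/s eyes open). Group structure is multiplicative on
the baseline: PD eyes-open AP drive ×0.45 (hypokinetic sway, velocity
ratio ≈ 0.45), PD eyes-closed drive ×3.1 (AP) and ×1.6 (ML) with
damping ×0.8 (destabilised, AP-dominant; eyes-closed sway-path ratio
≈ 2.9). Between-subject heterogeneity is a unit-mean lognormal
multiplier on each axis drive (CV 0.35), chosen to give realistic
within-group overlap while keeping the groups separable. A tremor
sinusoid is available but off by default, matching cohorts of medicated
patients screened for confounding involuntary movement. `SimConfig.null`
removes all group effects for calibration runs. `blank_features` blanks
feature cells independently (default rate 0.02) to exercise mean
imputation.

**What the generator does and does not emulate.** It reproduces the
direction and rough magnitude of the two headline group contrasts, the
AP dominance of effects, group sizes, recording geometry, and missing
cells. It does not emulate real sway's nonstationarity, intermittent
postural corrections, bounded support, or feature-specific effect
patterns: because group effects scale a whole axis's drive, *every*
magnitude feature of that axis/condition shifts together, so univariate
analyses on synthetic cohorts flag many more significant parameters than
a clinical cohort would, and classification is easier than on real data.
Passing recovery tests therefore demonstrates the harness's correctness
and leak-freedom, not clinical-grade performance.

A further consequence of the fixed-cohort design: a single 63-subject
null cohort's repeated-split AUC has wide chance-level spread, because
the same subjects recur in all 15 splits and an accidental correlation
between subject heterogeneity and labels persists across splits. The
chance-level band [0.3, 0.7] is therefore asserted on the mean over
three independent null cohorts.

## Numerical choices and degenerate inputs

- Sampling rate is inferred from the time column (1/median Δt, rounded
  to 3 decimals) and trials with interval dispersion beyond 1% of the
  median are rejected; trials shorter than 3 samples are rejected at
  ingest (imputation operates on the feature table, never on raw gaps).
- CSV conventions: comma separator, `.` decimal, UTF-8, missing cells
  spelled `NA`; floats are written at full precision and read with
  round-trip parsing, so feature tables round-trip bit-for-bit.
- Condition labels (EO/EC) are carried by the cohort manifest, not
  parsed from filenames.
- Mann–Whitney exact/asymptotic threshold: pooled n ≤ 12, no ties.
- Degenerate covariance → ellipse area 0; single-class truth → AUC NaN;
  all-zero Wilcoxon differences → NA, excluded from the BH family.
- Problem sizes used by the test suite and acceptance script: the
  reduced tuning grids, 15 splits, 1000 bootstrap resamples, 100 null
  replicates for family-wise type-I calibration, and 10⁵ Monte-Carlo
  points for ellipse coverage.

## Known limitations

- The generator is a deliberately minimal stationary linear process; see
  above for what that implies about external validity.
- Impurity importances are attribution-unstable across correlated
  features; rank-concordance numbers should be read with that in mind.
- The exact Spearman permutation p is only used at n ≤ 8; at the
  package's operating point (n = 34 features) the t approximation is
  standard.
- Single trials per condition (the reference protocol) mean no
  within-subject reliability estimate is possible.
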