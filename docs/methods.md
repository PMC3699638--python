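# Methods

## Signal model and metrics

A BOLD voxel time course S(t), sampled every TR seconds, is treated as a
mean level plus fluctuations from physiology (cardiac pulsation,
respiration, vasomotion/metabolic drift) and from thermal/electronic noise.
Two summary statistics are computed per voxel and reported as a percentage
of the voxel's temporal mean.

### σ_physio: thermal-corrected fluctuation amplitude

Total temporal variance decomposes under the square-summation law,
σ²_EPI = σ²_physio + σ²_therm, because thermal noise is independent of the
physiological signal. σ²_therm is estimated as the mean temporal variance
over an out-of-brain corner ROI; corners are used because the N/2 EPI ghost
folds brain signal into the background along the phase-encode mid-edges.
Then σ_physio = √max(σ²_EPI − σ²_therm, 0).

Numerical choices:

- **Variance denominator** is n−1 everywhere (voxel and ROI), so the two
  variances are commensurable.
- **Clamping.** Sampling error can push σ²_EPI below σ²_therm in voxels with
  little physiology; the difference is clamped at zero and the number of
  clamped voxels is reported (`clipped_count`). On a thermal-only phantom
  about half the voxels clamp, and the tissue-mean σ_physio settles at a
  small positive clamp floor ≈ 0.1 × the thermal percentage — "zero" can
  only be approached, not reached, by a nonnegative estimator.
- **No detrending.** Variance is taken over the full analyzed time course;
  slow drift therefore contributes to σ_physio by design, and the phantom
  generator injects drift so tests reflect this.
- Voxels with nonpositive temporal mean (background, signal dropout) are
  marked undefined (NaN), never zero, and counted.

### Cardiac pulsatility: spectral amplitude at the heart rate

Each voxel's one-sided amplitude spectrum is computed by FFT with the
scaling |DFT|·2/n at interior bins and |DFT|/n at DC and Nyquist, so a pure
sinusoid of amplitude A on an exact bin reads A. The cardiac frequency f_c
is the mean (optionally median, robust to oximeter dropouts) heart rate
over the scan divided by 60. Amplitudes in bins whose center lies within
±0.02 Hz of f_c (closed interval) are integrated as Σ A(f_k)·Δf and divided
by the full window width 0.04 Hz; the result is normalized to the voxel
mean. The ±0.02 Hz half-width accommodates the finite width of the cardiac
peak under natural heart-rate variability; it is configurable
(`half_window_hz`).

Consequences of this convention worth keeping in mind:

- With Δf = 1/(n·TR) = 0.008 Hz (500 volumes at TR 0.25 s) the window holds
  5 bins, so a constant-rate sinusoid concentrated in one bin yields a map
  value of A·Δf/0.04 = A/5, not A. Absolute map values are therefore
  convention-dependent; group *contrasts* are not.
- A magnitude spectrum has a positive noise floor: each noise-only bin
  contributes a Rayleigh-mean amplitude σ_therm√(π/n). Tests that assert
  amplitude recovery at low SNR account for this analytically rather than
  pretending the estimator is unbiased.
- The metric requires f_c + 0.02 Hz < 1/(2·TR). At TR 0.25 s (Nyquist 2 Hz)
  a resting heart rate passes easily; at TR 2 s (sampling rate 0.5 Hz) the
  check fails by construction and the pipeline refuses the metric ("wb"
  mode computes σ_physio only).

### Preprocessing

- **Volume trimming:** the first 10 volumes of a cs acquisition are
  discarded (approach to steady state); 0 for wb data. Configurable.
- **Mask erosion:** tissue masks are eroded by convolving the {0,1}
  indicator with an isotropic 3 mm FWHM Gaussian (per-axis conversion to
  voxel units, zero padding outside the grid — conservative) and keeping
  voxels whose smoothed value is ≥ `erode_keep_threshold`. The threshold is
  a free choice; the default 0.9 strips boundary voxels with substantial
  non-tissue neighborhood while preserving mask cores, and the output is
  always a subset of the input. Erosion is monotone in the input mask.
- **Thermal ROI:** default 8×8 in-plane across all slices; policy
  `min-signal` picks the corner with the lowest mean signal (ghost
  avoidance), with `fixed` and `all-corners` alternatives. On homogeneous
  noise the four-corner and one-corner estimates agree to within sampling
  error; the ROI never intersects a tissue mask (asserted on every run).

## Cohort statistics

All p values are two-tailed; α = 0.05. The battery over the per-subject
summary table comprises: one-way ANOVA of NAWM σ_physio and NAWM
pulsatility across YC/EC/SVD; post-hoc pooled-variance unpaired t-tests for
the three group pairs, Bonferroni-corrected as a family of m = 3; ANCOVA
with thermal variance alone and with thermal variance + WM volume + WM PVE;
a paired NAWM-vs-WMH t-test within the SVD group with Cohen's d; an
intra-subject voxelwise GM-vs-NAWM unpaired t-test classifying each subject
as NAWM<GM / NAWM=GM / NAWM>GM at α = 0.05, tabulated per group; Levene
(absolute deviations from group means) and Shapiro-Wilk diagnostics;
Pearson correlations of lesion volume with the NAWM metrics; an EC-vs-SVD
comparison of cumulative head motion (the sum of per-volume RMS
displacements supplied as input); and a linear regression of NAWM σ_physio
on age with optional extra covariates.

Choices where the design was genuinely open:

- **ANCOVA** is a full-vs-reduced model comparison (group dummies +
  covariates vs covariates only), i.e. a Type-III-style group test with
  df = (k−1, N−k−p). With zero covariates it reduces exactly to one-way
  ANOVA. Design matrices are dummy-coded directly; no formula layer.
- **Cohen's d** defaults to the classic pooled-SD form even for the paired
  lesion contrast (the paired-differences variant is computed and labelled
  alongside), since the pooled form is the common reporting convention when
  the variant is unstated.
- **Post-hoc t-tests** use pooled variance (Student), consistent with
  integer degrees of freedom n₁+n₂−2; Welch is available by flag.
- **Missing values** (e.g. WMH columns in control groups) are dropped
  listwise per test; tests that lose their prerequisites are skipped with a
  recorded reason, never silently.
- The **intra-subject GM-vs-NAWM classification** uses an unpaired t-test
  across voxel values — the natural within-subject analogue when voxels are
  the sampling unit.

Calibration of the wrappers (type-I error ≈ 5% at α = 0.05 for the t-tests,
Levene, Shapiro-Wilk and Pearson; F = t² with two groups; affine invariance
of t, F, r, d) is enforced by seeded Monte-Carlo tests.

## Synthetic phantom generator

Per voxel the generator renders

S(t) = S0·[1 + cardiac + respiration + broadband + drift] + thermal,

with a cardiac sinusoid (amplitude in % of S0, optional harmonics, random
phase per voxel), a respiratory sinusoid (~0.3 Hz), broadband physiological
noise (white Gaussian low-pass filtered at 0.15 Hz — low-frequency weighted
as in resting-state data and separable from the cardiac window — and
standardized so each voxel's sample SD is exact), a centered linear drift,
and additive white thermal noise. Whole-brain (TR 2 s) series are produced
by rendering the same continuous-time model at the cs sampling interval and
decimating 8×, so cardiac power aliases exactly as slow sampling would
alias it, rather than being omitted.

Geometry is a concentric phantom: GM annulus around a WM disk on a 64×64×4
grid (510 volumes, TR 0.25 s by default), corners left signal-free for the
thermal ROI, with a contiguous WMH blob grown inside WM for SVD subjects
and per-subject radius jitter standing in for anatomy/atrophy variation.
Cohort designs draw per-subject tissue parameters around group means with
homoscedastic between-subject SDs; a shared per-subject factor keeps GM and
NAWM levels correlated within a subject, and lesion parameters are tied to
the subject's NAWM level so paired contrasts behave like repeated measures.
Cardiac harmonics default to zero in cohort designs because the second
harmonic of a ~1 Hz heart rate sits at the 2 Hz cs Nyquist edge, violating
the generator's own no-aliasing precondition; sub-Nyquist harmonic use is
supported in the voxel model.

The default graded design emulates the study conditions: cohorts of
11/10/7 (YC/EC/SVD), heart rates ~N(60, 5) bpm held constant within a
subject, NAWM broadband levels 0.6/1.0/1.3% (the reported WM σ_physio
scale), cardiac amplitudes 0.40/0.70/1.00% with GM above WM, lesion burden
~25% of WM in SVD with lesion metrics reduced relative to NAWM (ratios
0.5 cardiac / 0.7 broadband), thermal SNR ~100, drift 0.2%/min. A null
design (all groups EC-like, no lesions) supports type-I calibration.

Ground truth is written in the units the pipeline reports: the expected
pulsatility map value is obtained by running the spectral integration on
the noiseless cardiac component at the *analyzed* series length, averaged
over sinusoid phases (off-bin leakage magnitude is phase-dependent). The
truth value excludes the thermal amplitude floor, so noisy measurements sit
slightly above it by the analytically known floor.

What the phantoms do **not** emulate: real anatomy and registration error,
EPI ghosting/distortion beyond an empty-corner background, motion, inflow
effects, heart-rate drift within a scan, and spatially correlated
physiological noise. Passing tests therefore demonstrate correctness of the
estimators and statistics under the stated signal model, not robustness to
those real-data complications.

## Problem sizes in tests and the acceptance script

Recovery and cohort-level checks run on scaled-down grids (24×24×2 with the
full 510-volume cs course) so the entire battery — including 20 graded-design
power runs and 100 null-design calibration runs — completes in a few minutes
on one CPU; the phantom keeps every property the pipeline touches (tissue
contiguity, free corners, lesion-in-WM, full-length spectra). The spectral
closed forms are exercised at the native 500-point length where the
0.008 Hz bin spacing puts a 60 bpm heart rate exactly on bin 125.

## Known limitations

- Absolute pulsatility values depend on the stated FFT normalization and
  window discretization; compare values only within this convention.
- The cardiac-frequency estimate is a trace mean, not a spectral peak
  search; gross oximeter artifacts should be cleaned upstream (the reader
  drops samples outside 30–200 bpm).
- σ_physio inherits drift and any slow artifact; it is deliberately less
  specific than the cardiac-band metric.
- The paired lesion contrast assumes WMH masks are supplied; no lesion
  segmentation is performed.
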