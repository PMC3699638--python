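# pulsebold

Physiological-noise and cardiac-pulsatility mapping for resting-state BOLD
fMRI, aimed at characterizing white matter in aging and cerebral small
vessel disease (SVD), where lesions (white matter hyperintensities, WMH)
and the surrounding normal-appearing white matter (NAWM) differ in their
hemodynamic signal fluctuations.

## What it computes

Given a 4D BOLD series, tissue masks in BOLD space, and a pulse-oximetry
heart-rate trace, the package produces two voxelwise metrics, each expressed
as a percentage of the voxel's temporal mean:

**σ_physio** — the physiological component of the temporal fluctuation,
obtained from the square-summation law

```
σ²_EPI = σ²_physio + σ²_therm
```

where σ²_EPI is a voxel's total temporal variance and σ²_therm is the
thermal (scanner) variance estimated from an out-of-brain corner ROI, so
σ_physio = √max(σ²_EPI − σ²_therm, 0). This works at any repetition time.

**Cardiac pulsatility** — the average one-sided spectral amplitude within
±0.02 Hz of the cardiac frequency f_c (taken from pulse oximetry):

```
P = ( Σ_{|f_k − f_c| ≤ 0.02 Hz} A(f_k) · Δf ) / 0.04 Hz ,   Δf = 1/(n·TR)
```

normalized to the voxel mean. This requires cardiac-unaliased ("cs")
sampling: at TR = 0.25 s the Nyquist frequency is 2 Hz, comfortably above a
resting heart rate of ~1 Hz; at a conventional TR of 2 s (sampling rate
0.5 Hz) the cardiac band is aliased and the metric is refused ("wb" mode,
σ_physio only).

Per-subject tissue summaries (GM, WM, NAWM = WM∖WMH, WMH) feed a cohort
statistics battery: one-way ANOVA across young controls (YC), elderly
controls (EC) and SVD groups; ANCOVA with thermal noise, WM volume and WM
partial-volume estimate as nuisance covariates; Bonferroni-corrected
post-hoc t-tests; paired NAWM-vs-WMH tests with Cohen's d; voxelwise
intra-subject GM-vs-NAWM contrasts; Levene/Shapiro-Wilk diagnostics; head
motion comparisons; and a linear age regression.

A synthetic phantom generator (`pulsebold.simulate`) renders whole cohorts
with controllable tissue-specific cardiac amplitude, broadband physiological
noise, thermal noise, drift, lesion geometry and TR-dependent aliasing, so
the full pipeline is testable without scanner data.

## Worked example

```python
from pulsebold import PhysioNoiseModel, RunConfig
from pulsebold.simulate import CohortDesign, simulate_cohort

design = CohortDesign(grid_shape=(32, 32, 2), seed=42)   # phantom cohort
subj = next(iter(simulate_cohort(design)))               # first YC subject

cfg = RunConfig(mode="cs", thermal_extent=(6, 6))
res = PhysioNoiseModel(subj.bold, subj.masks, pulse=subj.pulse,
                       record=subj.record, config=cfg).fit()
print(res.summary())
```

prints

```
Physiological-noise model fit
==================================
mode: cs   TR: 0.25 s   volumes analyzed: 500
thermal ROI: corner x1y0, 72 voxels, variance 112
clamped voxels (sigma2_epi < sigma2_therm): 0
cardiac frequency: 1.035 Hz (±0.02 Hz window)

tissue    sigma_physio %   pulsatility %   voxels
GM                1.4253          0.3594      432
WM                0.7243          0.1769      464
NAWM              0.7243          0.1769      464
```

Reading: the first 10 of 510 volumes were discarded; thermal variance 112
(scanner units²) came from a 72-voxel corner ROI chosen by the min-signal
(ghost-avoiding) rule; this subject's heart rate was 62 bpm (1.035 Hz). Grey
matter fluctuates more than white matter on both metrics, as expected — the
generator injected 1.24% broadband / 0.99% cardiac amplitude in GM versus
0.65% / 0.43% in WM, and the fitted tissue means recover that ordering.
`res.summary_row()` yields the one-line-per-subject record that the cohort
layer consumes:

```python
import pandas as pd
from pulsebold import run_cohort
rows = []
for subj in simulate_cohort(design):
    fit = PhysioNoiseModel(subj.bold, subj.masks, pulse=subj.pulse,
                           record=subj.record, config=cfg).fit()
    rows.append(fit.summary_row())
print(run_cohort(pd.DataFrame(rows)).summary())
```

which reports, among others, `anova_sigma_physio_nawm: stat(2,25) = ...` —
the F test across the 11/10/7-subject cohorts with its (2, 25) degrees of
freedom — the Bonferroni-flagged post-hoc trio, and the paired NAWM-vs-WMH
lesion contrast with Cohen's d.

The same pipeline is scriptable from the shell:

```
pulsebold simulate --out cohort/ --seed 1
pulsebold map --bold cohort/YC01/bold.nii.gz \
    --masks GM=cohort/YC01/mask_gm.nii.gz,WM=cohort/YC01/mask_wm.nii.gz \
    --pulse cohort/YC01/pulse.csv --mode cs --out maps/YC01
pulsebold stats --summary summary.tsv --out report.tsv
pulsebold demo --out demo/ --seed 7        # simulate → map → stats, ~2 s
```

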