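"""Synthetic BOLD phantom generation.

The generator renders cohorts with the statistical structure the analysis
assumes — tissue-dependent cardiac pulsatility, broadband physiological
noise, thermal noise, slow drift, lesion geometry, and TR-dependent cardiac
aliasing — so every pipeline stage and every cohort-level claim can be
tested without real data.

Signal model per voxel::

    S(t) = S0 * [1 + cardiac(t) + respiratory(t) + broadband(t) + drift(t)]
           + thermal white noise

Cardiac and respiratory terms are sinusoids (fractions of S0); broadband
physiological noise is Gaussian noise low-pass filtered at 0.15 Hz and
standardized so each voxel's sample SD equals the requested percentage
exactly; drift is a centered linear ramp.  Whole-brain (wb) series are
rendered from the same continuous-time model by generating at the cs
sampling interval and decimating, so cardiac power is aliased rather than
absent.

Geometry is a concentric phantom, not anatomy: a grey-matter annulus around
a white-matter disk, with the image corners left as signal-free background
for the thermal-noise ROI, and (for SVD subjects) a contiguous lesion blob
inside WM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .io import (BoldSeries, PulseTrace, SubjectRecord, TissueMasks,
                 ValidationError)

logger = logging.getLogger("pulsebold")

#: Broadband physiological noise is low-pass filtered at this cutoff (Hz);
#: low-frequency weighting keeps it separable from the cardiac window.
BROADBAND_CUTOFF_HZ = 0.15

#: cs acquisition defaults: 64x64 matrix, 4 slices, 510 volumes at TR 0.25 s.
CS_SHAPE = (64, 64, 4)
CS_N_VOLUMES = 510
CS_TR = 0.25

#: wb acquisition defaults: TR 2 s, 128 volumes (cardiac-aliased).
WB_TR = 2.0
WB_N_VOLUMES = 128


@dataclass
class VoxelSignalModel:
    """Continuous-time signal model for one voxel (or one tissue class)."""

    baseline: float = 1000.0            # S0, scanner units
    cardiac_amp_pct: float = 0.0        # sinusoid amplitude, % of S0
    cardiac_harmonics: tuple = ()       # amplitude fractions at 2 f_c, 3 f_c, ...
    resp_amp_pct: float = 0.0
    resp_freq_hz: float = 0.3
    physio_broadband_pct: float = 0.0   # SD of low-passed Gaussian process, % of S0
    drift_pct_per_min: float = 0.0
    thermal_sd: float = 0.0             # additive white noise SD, signal units

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValidationError("baseline S0 must be positive")
        for name in ("cardiac_amp_pct", "resp_amp_pct",
                     "physio_broadband_pct", "thermal_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")

    def physio_sd_pct(self, n: int, tr_seconds: float) -> float:
        """Analytic SD (% of S0) of all non-thermal components combined.

        Sinusoids contribute A^2/2; broadband contributes its SD squared;
        a centered linear drift over the n sampled times contributes the
        sample variance of the ramp.
        """
        var = self.cardiac_amp_pct ** 2 / 2.0
        for frac in self.cardiac_harmonics:
            var += (frac * self.cardiac_amp_pct) ** 2 / 2.0
        var += self.resp_amp_pct ** 2 / 2.0
        var += self.physio_broadband_pct ** 2
        if self.drift_pct_per_min != 0.0 and n > 1:
            t_min = np.arange(n) * tr_seconds / 60.0
            var += self.drift_pct_per_min ** 2 * t_min.var(ddof=1)
        return float(np.sqrt(var))


def _lowpass_noise(rng: np.random.Generator, shape: tuple, n: int,
                   tr_seconds: float, cutoff_hz: float) -> np.ndarray:
    """Unit-SD Gaussian noise low-pass filtered along the last axis."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    spec[..., freqs > cutoff_hz] = 0.0
    filt = np.fft.irfft(spec, n=n, axis=-1)
    sd = filt.std(axis=-1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (filt - filt.mean(axis=-1, keepdims=True)) / sd


def simulate_voxel(model: VoxelSignalModel, f_c_hz: float, n: int,
                   tr_seconds: float, rng_seed, phase: float = 0.0) -> np.ndarray:
    """Render one voxel's time course; deterministic for a fixed seed."""
    if n < 16:
        raise ValidationError("need at least 16 time points")
    nyquist = 1.0 / (2.0 * tr_seconds)
    freqs = [f_c_hz] + [(i + 2) * f_c_hz for i in range(len(model.cardiac_harmonics))]
    if model.resp_amp_pct > 0:
        freqs.append(model.resp_freq_hz)
    if any(f >= nyquist for f in freqs if f > 0) and (
            model.cardiac_amp_pct > 0 or model.resp_amp_pct > 0):
        raise ValidationError(
            f"signal frequency at or above Nyquist {nyquist:g} Hz at TR "
            f"{tr_seconds} s"
        )
    rng = np.random.default_rng(rng_seed)
    t = np.arange(n) * tr_seconds
    frac = np.zeros(n)
    if model.cardiac_amp_pct > 0:
        frac += model.cardiac_amp_pct / 100.0 * np.sin(2 * np.pi * f_c_hz * t + phase)
        for i, h in enumerate(model.cardiac_harmonics):
            frac += (h * model.cardiac_amp_pct / 100.0
                     * np.sin(2 * np.pi * (i + 2) * f_c_hz * t + phase))
    if model.resp_amp_pct > 0:
        frac += model.resp_amp_pct / 100.0 * np.sin(
            2 * np.pi * model.resp_freq_hz * t + rng.uniform(0, 2 * np.pi))
    if model.physio_broadband_pct > 0:
        frac += model.physio_broadband_pct / 100.0 * _lowpass_noise(
            rng, (), n, tr_seconds, BROADBAND_CUTOFF_HZ)
    if model.drift_pct_per_min != 0.0:
        t_min = t / 60.0
        frac += model.drift_pct_per_min / 100.0 * (t_min - t_min.mean())
    course = model.baseline * (1.0 + frac)
    if model.thermal_sd > 0:
        course = course + rng.normal(0.0, model.thermal_sd, size=n)
    return course


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

def build_phantom_masks(shape: tuple, lesion_fraction: float = 0.0,
                        rng: Optional[np.random.Generator] = None,
                        include_csf: bool = False,
                        radius_scale: float = 1.0) -> TissueMasks:
    """Concentric GM annulus / WM disk phantom with corner background.

    ``radius_scale`` shrinks/grows the whole phantom (between-subject
    anatomy variation, e.g. WM atrophy).  The lesion (WMH) is a contiguous
    blob grown from an off-center seed inside WM until it covers
    ``lesion_fraction`` of WM voxels.
    """
    nx, ny, nz = shape
    r_gm = 0.42 * min(nx, ny) * radius_scale
    r_wm = 0.70 * r_gm
    r_csf = 0.18 * r_gm if include_csf else 0.0
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    gm2d = (r2 <= r_gm ** 2) & (r2 > r_wm ** 2)
    wm2d = (r2 <= r_wm ** 2) & (r2 > r_csf ** 2)
    csf2d = r2 <= r_csf ** 2

    def stack(m2d):
        return np.repeat(m2d[:, :, None], nz, axis=2)

    labels = {"GM": stack(gm2d), "WM": stack(wm2d)}
    if include_csf:
        labels["CSF"] = stack(csf2d)

    if lesion_fraction > 0:
        if not lesion_fraction < 1:
            raise ValidationError("lesion_fraction must lie in [0, 1)")
        wm = labels["WM"]
        n_lesion = int(round(lesion_fraction * wm.sum()))
        if n_lesion < 1:
            raise ValidationError("lesion_fraction too small for this grid")
        coords = np.argwhere(wm)
        # Seed off-center so the lesion is a contiguous blob inside WM.
        if rng is None:
            rng = np.random.default_rng(0)
        seed = np.array([cx + 0.4 * r_wm, cy, (nz - 1) / 2.0])
        jitter = rng.uniform(-1.0, 1.0, size=3)
        d = np.linalg.norm(coords - (seed + jitter), axis=1)
        chosen = coords[np.argsort(d, kind="stable")[:n_lesion]]
        wmh = np.zeros(shape, dtype=bool)
        wmh[tuple(chosen.T)] = True
        labels["WMH"] = wmh
    return TissueMasks(labels)


# ---------------------------------------------------------------------------
# Cohort design
# ---------------------------------------------------------------------------

@dataclass
class GroupDesign:
    """Per-group generator parameters: tissue means and between-subject SDs
    of cardiac amplitude and broadband physiological noise (all % of S0).

    Between-subject SDs are absolute (percentage points), identical across
    groups by default, so the cohorts are homoscedastic; within a subject
    the GM and NAWM draws share a common physiological factor, so the
    GM > NAWM ordering is preserved subject by subject.
    """

    n_subjects: int
    age_mean: float
    age_sd: float
    gm_cardiac_pct: float
    nawm_cardiac_pct: float
    gm_broadband_pct: float
    nawm_broadband_pct: float
    cardiac_sd: float = 0.08        # between-subject SD, percentage points
    broadband_sd: float = 0.12
    subject_factor_weight: float = 0.8   # shared fraction of the subject draw
    lesion_fraction: float = 0.0
    lesion_fraction_sd: float = 0.05
    wmh_cardiac_ratio: float = 0.5   # WMH amplitude relative to NAWM
    wmh_broadband_ratio: float = 0.7


@dataclass
class CohortDesign:
    """Full cohort specification; defaults emulate the study conditions:
    cohorts of 11/10/7 with NAWM metrics graded YC < EC < SVD and lesion
    metrics reduced relative to NAWM within SVD."""

    groups: dict = field(default_factory=lambda: default_group_designs())
    hr_mean_bpm: float = 60.0
    hr_sd_bpm: float = 5.0
    baseline: float = 1000.0
    thermal_snr: float = 100.0          # S0 / thermal SD
    drift_pct_per_min: float = 0.2
    resp_amp_pct: float = 0.1
    grid_shape: tuple = CS_SHAPE
    n_volumes: int = CS_N_VOLUMES
    tr_seconds: float = CS_TR
    voxel_dims_mm: tuple = (3.0, 3.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, g in self.groups.items():
            if g.n_subjects < 1:
                raise ValidationError(f"group {name} needs at least 1 subject")

    @property
    def n_subjects(self) -> int:
        return sum(g.n_subjects for g in self.groups.values())


def default_group_designs() -> dict:
    """Graded study-like design (NAWM ordering YC < EC < SVD; WMH < NAWM).

    Broadband (sigma_physio-dominating) NAWM levels follow the reported WM
    sigma_physio scale (~0.6 / 1.0 / 1.3 % across the three cohorts); GM sits
    above WM; cardiac amplitudes are graded similarly with GM > WM.
    """
    return {
        "YC": GroupDesign(n_subjects=11, age_mean=25.4, age_sd=3.2,
                          gm_cardiac_pct=0.9, nawm_cardiac_pct=0.40,
                          gm_broadband_pct=1.2, nawm_broadband_pct=0.60),
        "EC": GroupDesign(n_subjects=10, age_mean=65.8, age_sd=3.1,
                          gm_cardiac_pct=1.2, nawm_cardiac_pct=0.70,
                          gm_broadband_pct=1.6, nawm_broadband_pct=1.00),
        "SVD": GroupDesign(n_subjects=7, age_mean=70.0, age_sd=8.6,
                           gm_cardiac_pct=1.3, nawm_cardiac_pct=1.00,
                           gm_broadband_pct=1.7, nawm_broadband_pct=1.30,
                           lesion_fraction=0.25),
    }


def null_group_designs(n_subjects=(11, 10, 7)) -> dict:
    """All groups identical (EC-like); no lesions.  For type-I calibration."""
    base = default_group_designs()["EC"]
    return {
        name: replace(base, n_subjects=n, age_mean=base.age_mean,
                      lesion_fraction=0.0)
        for name, n in zip(("YC", "EC", "SVD"), n_subjects)
    }


@dataclass
class SubjectData:
    """Everything the pipeline needs for one phantom subject, plus truth."""

    bold: BoldSeries
    masks: TissueMasks
    pulse: PulseTrace
    record: SubjectRecord
    truth: dict


def _expected_pulsatility_pct(amp_pct: float, f_c_hz: float, n: int,
                              tr_seconds: float,
                              half_window_hz: float = 0.02,
                              n_phases: int = 16) -> float:
    """Expected map value for a pure sinusoid of the given amplitude.

    Evaluates the pipeline's own spectral integration on the noiseless
    cardiac component, so the truth table is stored in map units (a one-bin
    peak of amplitude A yields A*df / (2*half_window), not A).  For an
    off-bin cardiac frequency the leaked magnitude depends on the sinusoid
    phase, so the value is averaged over phases, matching the phase-random
    voxels of a rendered tissue block.
    """
    from .metrics import _one_sided_scale

    t = np.arange(n) * tr_seconds
    phases = np.arange(n_phases) * (2 * np.pi / n_phases)
    courses = amp_pct * np.sin(2 * np.pi * f_c_hz * t[None, :]
                               + phases[:, None])
    amp = np.abs(np.fft.rfft(courses, axis=1)) * _one_sided_scale(n)
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    df = freqs[1] - freqs[0]
    window = np.abs(freqs - f_c_hz) <= half_window_hz
    per_phase = amp[:, window].sum(axis=1) * df / (2.0 * half_window_hz)
    return float(per_phase.mean())


def _tissue_block(rng, n_voxels: int, model: VoxelSignalModel, f_c_hz: float,
                  n: int, tr_seconds: float) -> np.ndarray:
    """Render all voxels of one tissue class; per-voxel phases and noise."""
    t = np.arange(n) * tr_seconds
    frac = np.zeros((n_voxels, n))
    if model.cardiac_amp_pct > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_voxels)
        frac += (model.cardiac_amp_pct / 100.0
                 * np.sin(2 * np.pi * f_c_hz * t[None, :] + phases[:, None]))
    if model.resp_amp_pct > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_voxels)
        frac += (model.resp_amp_pct / 100.0
                 * np.sin(2 * np.pi * model.resp_freq_hz * t[None, :]
                          + phases[:, None]))
    if model.physio_broadband_pct > 0:
        frac += model.physio_broadband_pct / 100.0 * _lowpass_noise(
            rng, (n_voxels,), n, tr_seconds, BROADBAND_CUTOFF_HZ)
    if model.drift_pct_per_min != 0.0:
        t_min = t / 60.0
        frac += model.drift_pct_per_min / 100.0 * (t_min - t_min.mean())[None, :]
    block = model.baseline * (1.0 + frac)
    if model.thermal_sd > 0:
        block = block + rng.normal(0.0, model.thermal_sd, size=(n_voxels, n))
    return block


def simulate_subject(subject_id: str, group: str, tissue_models: dict,
                     hr_bpm: float, mode: str = "cs",
                     grid_shape: tuple = CS_SHAPE,
                     n_volumes: int = CS_N_VOLUMES,
                     tr_seconds: float = CS_TR,
                     lesion_fraction: float = 0.0,
                     voxel_dims_mm=(3.0, 3.0, 5.0),
                     age_years: float = 50.0, sex: str = "M",
                     radius_scale: float = 1.0, rng_seed=0,
                     analysis_volumes: Optional[int] = None) -> SubjectData:
    """Render one phantom subject.

    ``tissue_models`` maps class names (GM, WM, WMH, CSF) to
    :class:`VoxelSignalModel`; the WMH model applies inside the lesion and
    the WM model to the remaining (normal-appearing) WM.  In wb mode the
    series is generated at the cs sampling interval and decimated to TR
    ``tr_seconds`` so cardiac power aliases exactly as under slow sampling
    of the same continuous-time signal.
    """
    rng = np.random.default_rng(rng_seed)
    masks = build_phantom_masks(grid_shape, lesion_fraction=lesion_fraction,
                                rng=rng, include_csf="CSF" in tissue_models,
                                radius_scale=radius_scale)
    if lesion_fraction > 0 and "WMH" not in tissue_models:
        raise ValidationError("lesion requested but no WMH tissue model given")

    if mode == "cs":
        fine_tr, decim = tr_seconds, 1
    elif mode == "wb":
        decim = max(int(round(tr_seconds / CS_TR)), 1)
        fine_tr = tr_seconds / decim
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    n_fine = n_volumes * decim

    f_c = hr_bpm / 60.0
    nyq_fine = 1.0 / (2.0 * fine_tr)
    if f_c >= nyq_fine:
        raise ValidationError(
            f"cardiac frequency {f_c:g} Hz at or above generator Nyquist "
            f"{nyq_fine:g} Hz"
        )

    thermal_sd = next(iter(tissue_models.values())).thermal_sd
    data = rng.normal(0.0, thermal_sd if thermal_sd > 0 else 1e-12,
                      size=grid_shape + (n_volumes,))

    render_order = [c for c in ("GM", "WM", "CSF", "WMH") if c in tissue_models]
    for cls in render_order:
        if cls == "WMH":
            region = masks.get("WMH")
        elif cls == "WM":
            region = masks.nawm()
        else:
            region = masks.get(cls)
        if region is None or not region.any():
            continue
        block = _tissue_block(rng, int(region.sum()), tissue_models[cls], f_c,
                              n_fine, fine_tr)
        data[region] = block[:, ::decim] if decim > 1 else block

    bold = BoldSeries(data=data, tr_seconds=tr_seconds,
                      voxel_dims_mm=voxel_dims_mm)

    duration = n_volumes * tr_seconds
    times = np.arange(0.0, duration, 1.0)
    bpm = np.full(times.size, hr_bpm)
    pulse = PulseTrace(times_seconds=times, bpm=bpm)

    wm_total = int(masks["WM"].sum()) if "WM" in masks else 0
    disp = np.abs(rng.normal(0.05, 0.015, size=n_volumes))
    record = SubjectRecord(
        subject_id=subject_id, group=group, age_years=age_years, sex=sex,
        wm_volume=wm_total, wm_pve=float(rng.uniform(0.85, 0.95)),
        displacement_mm=disp,
    )

    # Expected map values are evaluated at the length the analysis will see
    # (binning, hence leakage, depends on it); defaults to the rendered
    # length, i.e. no volumes discarded downstream.
    n_analysis = analysis_volumes if analysis_volumes is not None else n_volumes
    truth = {"subject_id": subject_id, "group": group, "hr_bpm": hr_bpm,
             "f_c_hz": f_c, "thermal_sd": thermal_sd}
    for cls, model in tissue_models.items():
        key = "NAWM" if cls == "WM" else cls
        truth[f"{key}_cardiac_amp_pct"] = model.cardiac_amp_pct
        truth[f"{key}_broadband_pct"] = model.physio_broadband_pct
        truth[f"{key}_sigma_physio_pct"] = model.physio_sd_pct(n_fine, fine_tr)
        truth[f"{key}_pulsatility_pct"] = _expected_pulsatility_pct(
            model.cardiac_amp_pct, f_c, n_analysis, tr_seconds
        ) if mode == "cs" else np.nan
    return SubjectData(bold=bold, masks=masks, pulse=pulse, record=record,
                       truth=truth)


def simulate_cohort(design: CohortDesign, mode: str = "cs") -> Iterator[SubjectData]:
    """Yield phantom subjects one at a time (memory-friendly), reproducibly.

    Per-subject tissue parameters are drawn around the group means; within an
    SVD-like subject the lesion parameters are tied to that subject's NAWM
    level (ratio with small jitter), so paired NAWM-vs-WMH differences are
    consistent across subjects.
    """
    root = np.random.SeedSequence(design.seed)
    subject_seeds = root.spawn(design.n_subjects)
    idx = 0
    for gname, g in design.groups.items():
        for i in range(g.n_subjects):
            ss = subject_seeds[idx]
            idx += 1
            rng = np.random.default_rng(ss)
            hr = float(np.clip(rng.normal(design.hr_mean_bpm, design.hr_sd_bpm),
                               40.0, 110.0))
            age = float(np.clip(rng.normal(g.age_mean, g.age_sd), 18.0, 95.0))
            sex = "M" if rng.uniform() < 0.5 else "F"
            thermal_sd = design.baseline / float(
                np.clip(rng.normal(design.thermal_snr, 0.05 * design.thermal_snr),
                        5.0, None))

            # One shared physiological factor per subject keeps GM and NAWM
            # correlated; the rest is tissue-specific.
            w = g.subject_factor_weight
            w_ind = np.sqrt(max(1.0 - w * w, 0.0))
            z_card, z_bb = rng.standard_normal(2)

            def draw(mean, sd, z_shared):
                z = w * z_shared + w_ind * rng.standard_normal()
                return float(max(mean + sd * z, 0.02))

            nawm_card = draw(g.nawm_cardiac_pct, g.cardiac_sd, z_card)
            gm_card = draw(g.gm_cardiac_pct, g.cardiac_sd, z_card)
            nawm_bb = draw(g.nawm_broadband_pct, g.broadband_sd, z_bb)
            gm_bb = draw(g.gm_broadband_pct, g.broadband_sd, z_bb)

            common = dict(baseline=design.baseline, thermal_sd=thermal_sd,
                          drift_pct_per_min=design.drift_pct_per_min,
                          resp_amp_pct=design.resp_amp_pct)
            tissue_models = {
                "GM": VoxelSignalModel(cardiac_amp_pct=gm_card,
                                       physio_broadband_pct=gm_bb, **common),
                "WM": VoxelSignalModel(cardiac_amp_pct=nawm_card,
                                       physio_broadband_pct=nawm_bb, **common),
            }
            lesion_fraction = 0.0
            if g.lesion_fraction > 0:
                card_ratio = float(np.clip(
                    g.wmh_cardiac_ratio * (1 + 0.1 * rng.standard_normal()),
                    0.05, 0.95))
                bb_ratio = float(np.clip(
                    g.wmh_broadband_ratio * (1 + 0.1 * rng.standard_normal()),
                    0.05, 0.95))
                tissue_models["WMH"] = VoxelSignalModel(
                    cardiac_amp_pct=nawm_card * card_ratio,
                    physio_broadband_pct=nawm_bb * bb_ratio, **common)
                # Lesion burden varies between subjects and co-varies mildly
                # with the subject's broadband (sigma_physio-like) level.
                rel_bb = (nawm_bb - g.nawm_broadband_pct) / max(
                    g.nawm_broadband_pct, 1e-9)
                lesion_fraction = float(np.clip(
                    g.lesion_fraction * (1.0 + 0.5 * rel_bb)
                    + g.lesion_fraction_sd * rng.standard_normal(),
                    0.05, 0.6))

            yield simulate_subject(
                subject_id=f"{gname}{i + 1:02d}", group=gname,
                tissue_models=tissue_models, hr_bpm=hr, mode=mode,
                grid_shape=design.grid_shape, n_volumes=design.n_volumes,
                tr_seconds=design.tr_seconds,
                lesion_fraction=lesion_fraction,
                voxel_dims_mm=design.voxel_dims_mm,
                age_years=age, sex=sex,
                radius_scale=float(rng.uniform(0.88, 1.0)),
                rng_seed=ss.spawn(1)[0],
                # The standard cs analysis discards the first 10 volumes.
                analysis_volumes=(design.n_volumes - 10 if mode == "cs"
                                  else design.n_volumes),
            )


def truth_table(subjects) -> pd.DataFrame:
    """Collect per-subject injected ground truth into one table."""
    return pd.DataFrame([s.truth for s in subjects])


def write_cohort(design: CohortDesign, out_dir, mode: str = "cs") -> pd.DataFrame:
    """Render a cohort to disk (NIfTI + CSV/TSV artifacts); returns truth."""
    import os

    from . import io as pio

    os.makedirs(out_dir, exist_ok=True)
    truths, covariates = [], []
    for subj in simulate_cohort(design, mode=mode):
        sdir = os.path.join(out_dir, subj.record.subject_id)
        os.makedirs(sdir, exist_ok=True)
        pio.write_bold(subj.bold, os.path.join(sdir, "bold.nii.gz"))
        for cls, m in subj.masks.labels.items():
            pio.write_mask(m, os.path.join(sdir, f"mask_{cls.lower()}.nii.gz"),
                           voxel_dims_mm=design.voxel_dims_mm)
        pio.write_pulse_trace(subj.pulse, os.path.join(sdir, "pulse.csv"))
        np.savetxt(os.path.join(sdir, "displacement_mm.txt"),
                   subj.record.displacement_mm)
        truths.append(subj.truth)
        covariates.append({
            "subject_id": subj.record.subject_id, "group": subj.record.group,
            "age_years": subj.record.age_years, "sex": subj.record.sex,
            "wm_volume": subj.record.wm_volume, "wm_pve": subj.record.wm_pve,
        })
    truth = pd.DataFrame(truths)
    truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    pd.DataFrame(covariates).to_csv(os.path.join(out_dir, "covariates.tsv"),
                                    sep="\t", index=False)
    return truth
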