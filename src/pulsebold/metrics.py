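"""Voxelwise physiological-noise statistics.

Two metrics are computed per voxel, each expressed as a percentage of the
voxel's temporal mean:

* **sigma_physio** — the standard deviation of the time series attributable
  to physiology, obtained by subtracting the thermal-noise variance from the
  total temporal variance under the square-summation law
  ``sigma2_epi = sigma2_physio + sigma2_therm``.

* **cardiac pulsatility** — the average one-sided spectral amplitude within
  a ±0.02 Hz window around the cardiac frequency (derived from pulse
  oximetry), i.e. the percentage signal change at the heart rate.  Requires
  cardiac-unaliased sampling (TR short enough that f_c is below Nyquist).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import BoldSeries, PulseTrace, TissueMasks, ValidationError
from .preprocess import ThermalRoi

logger = logging.getLogger("pulsebold")

#: Half width of the cardiac integration window, Hz.
DEFAULT_HALF_WINDOW_HZ = 0.02


@dataclass
class VoxelMetricMap:
    """A per-voxel metric in percent of the voxel mean; NaN where undefined."""

    values: np.ndarray
    metric_name: str
    tr_seconds: float
    voxel_dims_mm: tuple = (3.0, 3.0, 5.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError("metric map must be 3D")
        defined = self.values[np.isfinite(self.values)]
        if defined.size and (defined < 0).any():
            raise ValidationError("metric values must be nonnegative where defined")

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum of a single time course.

    Scaled so a pure sinusoid of amplitude A on an exact frequency bin reads
    amplitude A at that bin: |DFT|·2/n at interior bins, |DFT|/n at 0 and
    Nyquist.
    """

    freqs_hz: np.ndarray
    amplitude: np.ndarray

    @property
    def df_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])


@dataclass
class NoiseDecomposition:
    """Per-voxel variance decomposition under the square-summation law."""

    sigma2_epi: np.ndarray        # total temporal variance, masked voxels
    sigma2_therm: float           # scalar thermal variance
    sigma_physio_pct: VoxelMetricMap
    clipped_count: int            # voxels where sigma2_epi < sigma2_therm
    undefined_count: int = 0      # voxels with nonpositive temporal mean


@dataclass
class CardiacFrequency:
    """Cardiac frequency from pulse oximetry, with its integration window."""

    f_c_hz: float
    half_window_hz: float = DEFAULT_HALF_WINDOW_HZ
    source: str = "trace_mean"

    def __post_init__(self) -> None:
        if self.f_c_hz <= 0:
            raise ValidationError("cardiac frequency must be positive")


# ---------------------------------------------------------------------------


def _one_sided_scale(n: int) -> np.ndarray:
    """Scale factors mapping |rfft| to one-sided amplitudes."""
    n_bins = n // 2 + 1
    scale = np.full(n_bins, 2.0 / n)
    scale[0] = 1.0 / n
    if n % 2 == 0:
        scale[-1] = 1.0 / n
    return scale


def amplitude_spectrum(course: np.ndarray, tr_seconds: float) -> AmplitudeSpectrum:
    """One-sided amplitude spectrum of a 1D time course."""
    course = np.asarray(course, dtype=np.float64)
    if course.ndim != 1 or course.size < 4:
        raise ValidationError("need a 1D course with at least 4 points")
    n = course.size
    amp = np.abs(np.fft.rfft(course)) * _one_sided_scale(n)
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    return AmplitudeSpectrum(freqs_hz=freqs, amplitude=amp)


def thermal_variance(series: BoldSeries, roi: ThermalRoi) -> float:
    """Mean over ROI voxels of each voxel's temporal variance (ddof=1)."""
    if series.n_volumes < 2:
        raise ValidationError("need at least 2 volumes for a variance")
    if roi.mask.shape != series.spatial_shape:
        raise ValidationError(
            f"ROI shape {roi.mask.shape} does not match series {series.spatial_shape}"
        )
    courses = series.data[roi.mask]          # (n_voxels, t)
    return float(courses.var(axis=1, ddof=1).mean())


def sigma_physio_map(series: BoldSeries, sigma2_therm: float,
                     mask: np.ndarray) -> NoiseDecomposition:
    """Thermal-corrected physiological-noise map, percent of voxel mean.

    Per masked voxel: ``sigma_physio = sqrt(max(sigma2_epi - sigma2_therm, 0))``
    with the clamp count reported; voxels with nonpositive temporal mean are
    marked undefined (NaN).  Variances use denominator n-1, commensurable
    with :func:`thermal_variance`.
    """
    if sigma2_therm < 0:
        raise ValidationError("thermal variance must be nonnegative")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.spatial_shape:
        raise ValidationError("mask shape does not match series")
    if not mask.any():
        raise ValidationError("evaluation mask is empty")
    if series.n_volumes < 2:
        raise ValidationError("need at least 2 volumes")

    courses = series.data[mask]              # (n_voxels, t)
    sigma2_epi = courses.var(axis=1, ddof=1)
    means = courses.mean(axis=1)

    diff = sigma2_epi - sigma2_therm
    clipped = int((diff < 0).sum())
    sigma_physio = np.sqrt(np.clip(diff, 0.0, None))

    pct = np.full(series.spatial_shape, np.nan)
    ok = means > 0
    vals = np.full(courses.shape[0], np.nan)
    vals[ok] = 100.0 * sigma_physio[ok] / means[ok]
    pct[mask] = vals
    undefined = int((~ok).sum())
    if undefined == courses.shape[0]:
        raise ValidationError("all masked voxels have nonpositive mean signal")
    if clipped:
        logger.info("sigma_physio: clamped %d voxel(s) with sigma2_epi < sigma2_therm",
                    clipped)
    metric = VoxelMetricMap(
        values=pct, metric_name="sigma_physio", tr_seconds=series.tr_seconds,
        voxel_dims_mm=series.voxel_dims_mm,
    )
    return NoiseDecomposition(
        sigma2_epi=sigma2_epi, sigma2_therm=float(sigma2_therm),
        sigma_physio_pct=metric, clipped_count=clipped, undefined_count=undefined,
    )


def cardiac_frequency(trace: PulseTrace, tr_seconds: float, mode: str = "cs",
                      scan_window: Optional[tuple] = None,
                      half_window_hz: float = DEFAULT_HALF_WINDOW_HZ,
                      source: str = "trace_mean") -> CardiacFrequency:
    """Cardiac frequency (Hz) from a heart-rate trace.

    Uses the mean (or median) bpm over the scan window divided by 60.  In
    cs mode the full integration window must sit below Nyquist,
    ``f_c + half_window < 1/(2 TR)``; violation is a hard error advising
    wb-mode, where pulsatility is not computed at all.
    """
    bpm = trace.bpm
    if scan_window is not None:
        t0, t1 = scan_window
        inside = (trace.times_seconds >= t0) & (trace.times_seconds <= t1)
        if inside.any():
            bpm = bpm[inside]
        else:
            logger.warning(
                "no pulse samples inside scan window [%g, %g] s; using whole trace",
                t0, t1,
            )
    if source == "trace_mean":
        f_c = float(np.mean(bpm)) / 60.0
    elif source == "trace_median":
        f_c = float(np.median(bpm)) / 60.0
    else:
        raise ValidationError(f"unknown cardiac-frequency source {source!r}")

    if mode == "cs":
        nyquist = 1.0 / (2.0 * tr_seconds)
        if f_c + half_window_hz >= nyquist:
            raise ValidationError(
                f"cardiac frequency {f_c:.3f} Hz + window {half_window_hz} Hz "
                f"reaches Nyquist {nyquist:.3f} Hz at TR {tr_seconds} s; the "
                "cardiac band is aliased — use wb mode (sigma_physio only)"
            )
    return CardiacFrequency(f_c_hz=f_c, half_window_hz=half_window_hz, source=source)


def cardiac_pulsatility_map(series: BoldSeries, fc: CardiacFrequency,
                            mask: np.ndarray) -> VoxelMetricMap:
    """Percent signal change at the cardiac frequency, per masked voxel.

    The one-sided amplitude spectrum is integrated over bins whose center
    frequency lies within ``half_window_hz`` of f_c (closed interval), the
    integral is divided by the full window width (0.04 Hz by default) to give
    an average amplitude, and that is normalized to the voxel temporal mean.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.spatial_shape:
        raise ValidationError("mask shape does not match series")
    if not mask.any():
        raise ValidationError("evaluation mask is empty")
    n = series.n_volumes
    if n < 4:
        raise ValidationError("need at least 4 volumes for a spectrum")
    nyquist = series.nyquist_hz
    if fc.f_c_hz + fc.half_window_hz >= nyquist:
        raise ValidationError(
            f"cardiac window [{fc.f_c_hz - fc.half_window_hz:.3f}, "
            f"{fc.f_c_hz + fc.half_window_hz:.3f}] Hz reaches Nyquist "
            f"{nyquist:.3f} Hz — cardiac pulsatility requires cs sampling"
        )

    freqs = np.fft.rfftfreq(n, d=series.tr_seconds)
    df = freqs[1] - freqs[0]
    window = np.abs(freqs - fc.f_c_hz) <= fc.half_window_hz
    if not window.any():
        raise ValidationError("no frequency bins inside the cardiac window")
    logger.debug(
        "cardiac window: %d bin(s) at %s Hz (df=%.4g)",
        int(window.sum()), np.array2string(freqs[window], precision=4), df,
    )

    courses = series.data[mask]                       # (n_voxels, t)
    spec = np.abs(np.fft.rfft(courses, axis=1)) * _one_sided_scale(n)
    avg_amp = spec[:, window].sum(axis=1) * df / (2.0 * fc.half_window_hz)
    means = courses.mean(axis=1)

    pct = np.full(series.spatial_shape, np.nan)
    vals = np.full(courses.shape[0], np.nan)
    ok = means > 0
    vals[ok] = 100.0 * avg_amp[ok] / means[ok]
    pct[mask] = vals
    return VoxelMetricMap(
        values=pct, metric_name="cardiac_pulsatility",
        tr_seconds=series.tr_seconds, voxel_dims_mm=series.voxel_dims_mm,
    )


def tissue_summary(metric_map: VoxelMetricMap, masks: TissueMasks) -> dict:
    """Mean map value per tissue class (GM, WM, NAWM, WMH, CSF).

    Returns ``{class: {"mean": float-or-nan, "n_voxels": int}}``; empty
    classes are reported with NaN means, never zero.  NAWM is WM minus WMH.
    """
    if masks.spatial_shape != metric_map.values.shape:
        raise ValidationError("mask shape does not match metric map")
    out = {}
    classes = dict(masks.labels)
    nawm = masks.nawm()
    if nawm is not None:
        classes["NAWM"] = nawm
    any_voxels = False
    for name, m in classes.items():
        vals = metric_map.values[m]
        vals = vals[np.isfinite(vals)]
        out[name] = {
            "mean": float(vals.mean()) if vals.size else float("nan"),
            "n_voxels": int(vals.size),
        }
        any_voxels = any_voxels or vals.size > 0
    if not any_voxels:
        raise ValidationError("every tissue class is empty on this map")
    return out


def cumulative_motion(displacement_mm) -> float:
    """Total head displacement: the per-volume RMS displacements summed."""
    disp = np.asarray(displacement_mm, dtype=np.float64)
    if disp.size == 0:
        raise ValidationError("displacement sequence is empty")
    if (disp < 0).any():
        raise ValidationError("displacements must be nonnegative")
    return float(disp.sum())
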