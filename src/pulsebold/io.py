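"""Reading, writing and validation of on-disk artifacts.

All spatial data are exchanged as NIfTI volumes already resampled into the
BOLD (EPI) grid; no registration is performed here.  Tabular data (pulse
traces, covariates, per-subject summaries) are delimited text.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("pulsebold")

#: Tissue class names understood by the pipeline.
TISSUE_CLASSES = ("GM", "WM", "WMH", "CSF")

#: Physiologic plausibility band for resting adult heart rate, beats/min.
BPM_MIN, BPM_MAX = 30.0, 200.0

GROUPS = ("YC", "EC", "SVD")


class ValidationError(ValueError):
    """An input failed a structural or physiological consistency check."""


@dataclass
class BoldSeries:
    """A 4D BOLD time series on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal in arbitrary scanner units.
    tr_seconds : float
        Repetition time (sampling interval) in seconds; must be positive.
    voxel_dims_mm : tuple of float
        Spatial voxel extents in mm.
    """

    data: np.ndarray
    tr_seconds: float
    voxel_dims_mm: tuple = (3.0, 3.0, 5.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValidationError(
                f"expected 4D (x, y, z, t) data, got {self.data.ndim}D"
            )
        if not np.isfinite(self.data).all():
            raise ValidationError("BOLD data contain non-finite values")
        if not self.tr_seconds > 0:
            raise ValidationError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        if len(self.voxel_dims_mm) != 3 or any(d <= 0 for d in self.voxel_dims_mm):
            raise ValidationError(f"bad voxel_dims_mm {self.voxel_dims_mm}")
        self.voxel_dims_mm = tuple(float(d) for d in self.voxel_dims_mm)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def nyquist_hz(self) -> float:
        """Highest unaliased frequency, 1 / (2 * TR)."""
        return 1.0 / (2.0 * self.tr_seconds)

    @property
    def sampling_hz(self) -> float:
        return 1.0 / self.tr_seconds

    @property
    def duration_seconds(self) -> float:
        return self.n_volumes * self.tr_seconds


@dataclass
class TissueMasks:
    """Per-class boolean voxel masks on the BOLD spatial grid.

    NAWM (normal-appearing white matter) is derived, not stored:
    WM voxels minus WMH voxels.
    """

    labels: dict

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("no tissue masks supplied")
        unknown = set(self.labels) - set(TISSUE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown tissue classes {sorted(unknown)}")
        if "GM" not in self.labels and "WM" not in self.labels:
            raise ValidationError("at least one of GM, WM must be present")
        shapes = {k: np.asarray(v).shape for k, v in self.labels.items()}
        if len(set(shapes.values())) > 1:
            raise ValidationError(f"mask shapes disagree: {shapes}")
        self.labels = {k: np.asarray(v, dtype=bool) for k, v in self.labels.items()}

    @property
    def spatial_shape(self) -> tuple:
        return next(iter(self.labels.values())).shape

    def __contains__(self, name: str) -> bool:
        return name in self.labels

    def __getitem__(self, name: str) -> np.ndarray:
        return self.labels[name]

    def get(self, name: str):
        return self.labels.get(name)

    def nawm(self) -> Optional[np.ndarray]:
        """WM with any WMH voxels carved out; None when WM is absent."""
        wm = self.labels.get("WM")
        if wm is None:
            return None
        wmh = self.labels.get("WMH")
        return wm if wmh is None else wm & ~wmh

    def union(self) -> np.ndarray:
        out = np.zeros(self.spatial_shape, dtype=bool)
        for m in self.labels.values():
            out |= m
        return out

    def check_shape(self, series: BoldSeries) -> None:
        if self.spatial_shape != series.spatial_shape:
            raise ValidationError(
                f"mask shape {self.spatial_shape} does not match "
                f"series spatial shape {series.spatial_shape}"
            )


@dataclass
class PulseTrace:
    """Pulse-oximetry heart-rate samples over the scan."""

    times_seconds: np.ndarray
    bpm: np.ndarray

    def __post_init__(self) -> None:
        self.times_seconds = np.asarray(self.times_seconds, dtype=np.float64)
        self.bpm = np.asarray(self.bpm, dtype=np.float64)
        if self.times_seconds.shape != self.bpm.shape or self.times_seconds.ndim != 1:
            raise ValidationError("times and bpm must be equal-length 1D arrays")
        if self.times_seconds.size == 0:
            raise ValidationError("pulse trace has no valid samples")
        if np.any(np.diff(self.times_seconds) < 0):
            raise ValidationError("pulse-trace times must be nondecreasing")
        if np.any(self.bpm < BPM_MIN) or np.any(self.bpm > BPM_MAX):
            raise ValidationError(
                f"bpm outside plausibility band [{BPM_MIN}, {BPM_MAX}]"
            )

    def __len__(self) -> int:
        return self.times_seconds.size


@dataclass
class SubjectRecord:
    """Per-subject covariates consumed by the statistics layer."""

    subject_id: str
    group: str
    age_years: float
    sex: str
    wm_volume: float = np.nan
    wm_pve: float = np.nan
    displacement_mm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.age_years < 0:
            raise ValidationError("age_years must be nonnegative")
        if np.isfinite(self.wm_pve) and not 0.0 <= self.wm_pve <= 1.0:
            raise ValidationError(f"wm_pve must lie in [0, 1], got {self.wm_pve}")
        if self.displacement_mm is not None:
            self.displacement_mm = np.asarray(self.displacement_mm, dtype=np.float64)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(voxel_dims_mm: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(voxel_dims_mm) + [1.0])
    return aff


def read_bold(path, tr_override: Optional[float] = None,
              voxel_dims_mm: Optional[Sequence[float]] = None) -> BoldSeries:
    """Load a 4D NIfTI volume as a :class:`BoldSeries`.

    The repetition time is taken from the header (4th zoom) unless
    ``tr_override`` is given; a header/override mismatch beyond 1% is logged.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"BOLD file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValidationError(f"expected 4D volume in {path}, got {data.ndim}D")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr_override is not None:
        if header_tr > 0 and abs(header_tr - tr_override) > 0.01 * tr_override:
            logger.warning(
                "TR override %.4g s differs from header TR %.4g s in %s",
                tr_override, header_tr, path,
            )
        tr = float(tr_override)
    elif header_tr > 0:
        tr = header_tr
    else:
        raise ValidationError(
            f"no positive repetition time in header of {path} and no override given"
        )
    dims = tuple(voxel_dims_mm) if voxel_dims_mm is not None else tuple(
        float(z) for z in zooms[:3]
    )
    return BoldSeries(data=data, tr_seconds=tr, voxel_dims_mm=dims)


def write_bold(series: BoldSeries, path) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series.voxel_dims_mm))
    img.header.set_zooms(tuple(series.voxel_dims_mm) + (series.tr_seconds,))
    nib.save(img, str(path))


def read_masks(paths: Mapping[str, object],
               reference: Optional[BoldSeries] = None) -> TissueMasks:
    """Load tissue masks (class name -> NIfTI path) and validate shapes."""
    labels = {}
    for name, p in paths.items():
        if not os.path.exists(str(p)):
            raise FileNotFoundError(f"mask file for {name} not found: {p}")
        arr = np.asanyarray(nib.load(str(p)).dataobj)
        if arr.ndim != 3:
            raise ValidationError(f"mask {name} in {p} is {arr.ndim}D, expected 3D")
        labels[name] = arr > 0.5
    masks = TissueMasks(labels)
    if reference is not None:
        masks.check_shape(reference)
    return masks


def write_mask(mask: np.ndarray, path, voxel_dims_mm=(3.0, 3.0, 5.0)) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_dims_mm))
    nib.save(img, str(path))


def write_metric_map(metric_map, path) -> None:
    """Write a :class:`~pulsebold.metrics.VoxelMetricMap` as NIfTI.

    Undefined voxels are stored as NaN so the round trip is lossless.
    """
    img = nib.Nifti1Image(
        metric_map.values.astype(np.float64), _affine(metric_map.voxel_dims_mm)
    )
    nib.save(img, str(path))


def read_metric_map(path, metric_name: str, tr_seconds: float):
    from .metrics import VoxelMetricMap

    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj).astype(np.float64)
    dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelMetricMap(
        values=values, metric_name=metric_name, tr_seconds=tr_seconds,
        voxel_dims_mm=dims,
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_pulse_trace(path) -> PulseTrace:
    """Read a two-column (time_seconds, bpm) delimited text file.

    Rows with heart rate outside the [30, 200] bpm plausibility band are
    dropped (count logged); an empty result is a hard error.
    """
    if not os.path.exists(str(path)):
        raise FileNotFoundError(f"pulse trace not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None,
                     skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValidationError(f"pulse trace {path} needs two columns (time, bpm)")
    # Header optional: a header row becomes NaN on coercion and is dropped.
    times = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    bpm = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    ok = times.notna() & bpm.notna()
    times, bpm = times[ok].to_numpy(), bpm[ok].to_numpy()
    plausible = (bpm >= BPM_MIN) & (bpm <= BPM_MAX)
    n_dropped = int((~plausible).sum())
    if n_dropped:
        logger.warning(
            "dropped %d pulse sample(s) outside [%g, %g] bpm in %s",
            n_dropped, BPM_MIN, BPM_MAX, path,
        )
    times, bpm = times[plausible], bpm[plausible]
    if times.size == 0:
        raise ValidationError(f"pulse trace {path} has no valid samples")
    order = np.argsort(times, kind="stable")
    return PulseTrace(times_seconds=times[order], bpm=bpm[order])


def write_pulse_trace(trace: PulseTrace, path) -> None:
    pd.DataFrame(
        {"time_seconds": trace.times_seconds, "bpm": trace.bpm}
    ).to_csv(path, index=False)


#: Column order of the per-subject summary table (the contract between the
#: map layer and the statistics layer).
SUMMARY_COLUMNS = [
    "subject_id", "group", "age_years", "sex", "mode",
    "sigma_physio_gm", "sigma_physio_nawm", "sigma_physio_wmh",
    "pulsatility_gm", "pulsatility_nawm", "pulsatility_wmh",
    "thermal_variance", "wm_volume", "wm_pve", "wmh_volume",
    "cumulative_motion_mm", "cardiac_freq_hz", "clipped_voxels",
    "sigma_contrast_class", "pulsatility_contrast_class",
]


def write_summary_table(rows, path) -> None:
    """Write per-subject summaries (list of dicts or DataFrame) as TSV."""
    df = pd.DataFrame(rows)
    cols = [c for c in SUMMARY_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False)


def read_summary_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValidationError(
            f"summary table {path} must contain subject_id and group columns"
        )
    return df


def read_covariates(path) -> pd.DataFrame:
    """Read a per-subject covariate table (CSV or TSV, sniffed)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject_id", "group", "age_years", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"covariate table missing columns {sorted(missing)}")
    return df
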