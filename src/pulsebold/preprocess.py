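"""Series and mask preparation: volume trimming, partial-volume erosion of
tissue masks, and placement of the out-of-brain thermal-noise ROI."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BoldSeries, TissueMasks, ValidationError

logger = logging.getLogger("pulsebold")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ThermalRoi:
    """Out-of-brain corner region used to estimate thermal noise variance.

    Corner placement avoids the N/2 EPI ghost, which folds brain signal into
    the background along the phase-encode axis mid-edges.
    """

    corner: str                 # e.g. "x0y0", "x1y0", or "all"
    extent_voxels: tuple        # in-plane (nx, ny); ROI spans all slices
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValidationError("thermal ROI is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def trim_volumes(series: BoldSeries, n_discard: int) -> BoldSeries:
    """Drop the first ``n_discard`` time points (approach to steady state)."""
    if n_discard < 0:
        raise ValidationError("n_discard must be nonnegative")
    if n_discard >= series.n_volumes:
        raise ValidationError(
            f"cannot discard {n_discard} of {series.n_volumes} volumes"
        )
    if n_discard == 0:
        return series
    return BoldSeries(
        data=series.data[..., n_discard:],
        tr_seconds=series.tr_seconds,
        voxel_dims_mm=series.voxel_dims_mm,
    )


def erode_mask(mask: np.ndarray, fwhm_mm: float, voxel_dims_mm,
               keep_threshold: float = 0.9) -> np.ndarray:
    """Erode a binary mask by Gaussian smoothing + thresholding.

    The {0,1} indicator is convolved with an isotropic Gaussian of the given
    FWHM (converted per-axis into voxel units); voxels whose smoothed value
    reaches ``keep_threshold`` are kept.  Outside-grid space is treated as
    non-tissue (zero padding), which is conservative for erosion.  The output
    is always a subset of the input.
    """
    if fwhm_mm <= 0:
        raise ValidationError("fwhm_mm must be positive")
    if not 0.0 < keep_threshold <= 1.0:
        raise ValidationError("keep_threshold must lie in (0, 1]")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        logger.warning("erode_mask: input mask is empty")
        return mask.copy()
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / d for d in voxel_dims_mm]
    smoothed = ndimage.gaussian_filter(
        mask.astype(np.float64), sigma=sigma_vox, mode="constant", cval=0.0
    )
    return mask & (smoothed >= keep_threshold)


_CORNERS = ("x0y0", "x1y0", "x0y1", "x1y1")


def _corner_block(shape, corner: str, extent) -> np.ndarray:
    nx, ny = extent
    block = np.zeros(shape, dtype=bool)
    xs = slice(0, nx) if corner[1] == "0" else slice(shape[0] - nx, shape[0])
    ys = slice(0, ny) if corner[3] == "0" else slice(shape[1] - ny, shape[1])
    block[xs, ys, :] = True
    return block


def thermal_roi(series: BoldSeries, masks: TissueMasks | None,
                extent_voxels=(8, 8), corner_policy: str = "min-signal",
                fixed_corner: str = "x0y0") -> ThermalRoi:
    """Delimit the corner ROI for thermal-noise estimation.

    Policies: ``fixed`` uses ``fixed_corner``; ``min-signal`` picks the corner
    with the lowest mean signal (ghost avoidance); ``all-corners`` unions the
    four corners.  Voxels inside any tissue mask are always excluded.
    """
    shape = series.spatial_shape
    nx, ny = extent_voxels
    if nx > shape[0] or ny > shape[1]:
        raise ValidationError(
            f"thermal ROI extent {extent_voxels} exceeds grid {shape[:2]}"
        )
    tissue = (
        masks.union() if masks is not None
        else np.zeros(shape, dtype=bool)
    )

    def roi_for(corner: str) -> np.ndarray:
        return _corner_block(shape, corner, (nx, ny)) & ~tissue

    if corner_policy == "fixed":
        if fixed_corner not in _CORNERS:
            raise ValidationError(f"unknown corner {fixed_corner!r}")
        chosen, roi = fixed_corner, roi_for(fixed_corner)
    elif corner_policy == "all-corners":
        roi = np.zeros(shape, dtype=bool)
        for c in _CORNERS:
            roi |= roi_for(c)
        chosen = "all"
    elif corner_policy == "min-signal":
        best, best_mean = None, np.inf
        for c in _CORNERS:
            r = roi_for(c)
            if not r.any():
                continue
            m = float(series.data[r].mean())
            if m < best_mean:
                best, best_mean = c, m
        if best is None:
            raise ValidationError("all candidate thermal ROIs are empty")
        chosen, roi = best, roi_for(best)
    else:
        raise ValidationError(f"unknown corner policy {corner_policy!r}")

    if not roi.any():
        raise ValidationError(
            f"thermal ROI at corner {chosen!r} is empty after tissue exclusion"
        )
    return ThermalRoi(corner=chosen, extent_voxels=(nx, ny), mask=roi)
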