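"""Model/Results objects tying the pipeline together.

:class:`PhysioNoiseModel` fits the per-subject voxelwise model — the
square-summation variance decomposition and (in cs mode) the cardiac
spectral-integration metric — and returns a :class:`PhysioNoiseResults`
carrying the maps, tissue summaries and diagnostics.

:class:`CohortModel` fits the cohort-level statistical battery over a
per-subject summary table and returns a :class:`CohortResults` with one
:class:`~pulsebold.stats.TestResult` per test plus skip reasons.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import asdict, dataclass
from typing import Optional

import pandas as pd

from . import io as pio
from . import metrics, preprocess, stats
from .io import (BoldSeries, PulseTrace, SubjectRecord, TissueMasks,
                 ValidationError)

logger = logging.getLogger("pulsebold")


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    ``discard_volumes=None`` resolves by mode: 10 for cs (approach to steady
    state at short TR), 0 for wb.
    """

    mode: str = "cs"
    discard_volumes: Optional[int] = None
    erode_fwhm_mm: float = 3.0
    erode_keep_threshold: float = 0.9
    thermal_corner_policy: str = "min-signal"
    thermal_extent: tuple = (8, 8)
    thermal_fixed_corner: str = "x0y0"
    half_window_hz: float = 0.02
    cardiac_source: str = "trace_mean"
    tr_override: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("cs", "wb"):
            raise ValidationError(f"mode must be 'cs' or 'wb', got {self.mode!r}")
        self.thermal_extent = tuple(self.thermal_extent)

    @property
    def n_discard(self) -> int:
        if self.discard_volumes is not None:
            return self.discard_volumes
        return 10 if self.mode == "cs" else 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class PhysioNoiseModel:
    """Per-subject physiological-noise model over a 4D BOLD series.

    Parameters
    ----------
    bold : BoldSeries
    masks : TissueMasks
        Binary tissue masks already in BOLD space.
    pulse : PulseTrace, optional
        Required for the cardiac pulsatility metric (cs mode).
    record : SubjectRecord, optional
        Covariates propagated into the summary row.
    config : RunConfig
    """

    def __init__(self, bold: BoldSeries, masks: TissueMasks,
                 pulse: Optional[PulseTrace] = None,
                 record: Optional[SubjectRecord] = None,
                 config: Optional[RunConfig] = None):
        config = config or RunConfig()
        masks.check_shape(bold)
        if config.mode == "cs" and pulse is None:
            raise ValidationError(
                "cs mode computes cardiac pulsatility and needs a pulse trace"
            )
        self.bold = bold
        self.masks = masks
        self.pulse = pulse
        self.record = record
        self.config = config

    @classmethod
    def from_files(cls, bold_path, mask_paths: dict, pulse_path=None,
                   record: Optional[SubjectRecord] = None,
                   config: Optional[RunConfig] = None) -> "PhysioNoiseModel":
        config = config or RunConfig()
        bold = pio.read_bold(bold_path, tr_override=config.tr_override)
        masks = pio.read_masks(mask_paths, reference=bold)
        pulse = pio.read_pulse_trace(pulse_path) if pulse_path else None
        return cls(bold, masks, pulse=pulse, record=record, config=config)

    def fit(self) -> "PhysioNoiseResults":
        cfg = self.config
        series = preprocess.trim_volumes(self.bold, cfg.n_discard)
        logger.info("discarded %d initial volume(s); %d remain",
                    cfg.n_discard, series.n_volumes)

        roi = preprocess.thermal_roi(
            series, self.masks, extent_voxels=cfg.thermal_extent,
            corner_policy=cfg.thermal_corner_policy,
            fixed_corner=cfg.thermal_fixed_corner,
        )
        assert not (roi.mask & self.masks.union()).any(), \
            "thermal ROI intersects tissue"
        sigma2_therm = metrics.thermal_variance(series, roi)
        logger.info("thermal ROI: corner %s, %d voxels, variance %.4g",
                    roi.corner, roi.n_voxels, sigma2_therm)

        eroded = TissueMasks({
            name: preprocess.erode_mask(
                m, cfg.erode_fwhm_mm, series.voxel_dims_mm,
                keep_threshold=cfg.erode_keep_threshold)
            for name, m in self.masks.labels.items()
        })
        eval_mask = eroded.union()
        if not eval_mask.any():
            raise ValidationError("all tissue masks empty after erosion")

        decomp = metrics.sigma_physio_map(series, sigma2_therm, eval_mask)

        fc = None
        puls_map = None
        if cfg.mode == "cs":
            fc = metrics.cardiac_frequency(
                self.pulse, series.tr_seconds, mode="cs",
                scan_window=(0.0, self.bold.duration_seconds),
                half_window_hz=cfg.half_window_hz, source=cfg.cardiac_source,
            )
            puls_map = metrics.cardiac_pulsatility_map(series, fc, eval_mask)

        sigma_summary = metrics.tissue_summary(decomp.sigma_physio_pct, eroded)
        puls_summary = (metrics.tissue_summary(puls_map, eroded)
                        if puls_map is not None else None)

        sigma_contrast = stats.intra_subject_tissue_contrast(
            decomp.sigma_physio_pct, eroded)
        puls_contrast = (stats.intra_subject_tissue_contrast(puls_map, eroded)
                         if puls_map is not None else None)

        return PhysioNoiseResults(
            model=self, series=series, thermal_roi=roi,
            decomposition=decomp, cardiac_freq=fc,
            pulsatility_map=puls_map, eroded_masks=eroded,
            sigma_summary=sigma_summary, pulsatility_summary=puls_summary,
            sigma_contrast=sigma_contrast, pulsatility_contrast=puls_contrast,
        )


@dataclass
class PhysioNoiseResults:
    """Fitted per-subject maps, summaries and diagnostics."""

    model: PhysioNoiseModel
    series: BoldSeries
    thermal_roi: preprocess.ThermalRoi
    decomposition: metrics.NoiseDecomposition
    cardiac_freq: Optional[metrics.CardiacFrequency]
    pulsatility_map: Optional[metrics.VoxelMetricMap]
    eroded_masks: TissueMasks
    sigma_summary: dict
    pulsatility_summary: Optional[dict]
    sigma_contrast: Optional[stats.TestResult]
    pulsatility_contrast: Optional[stats.TestResult]

    @property
    def sigma_physio_map(self) -> metrics.VoxelMetricMap:
        return self.decomposition.sigma_physio_pct

    def _tissue_mean(self, summary: Optional[dict], cls: str) -> float:
        if summary is None or cls not in summary:
            return float("nan")
        return summary[cls]["mean"]

    def summary_row(self) -> dict:
        """One row of the per-subject summary table (the stats contract)."""
        rec = self.model.record
        motion = float("nan")
        if rec is not None and rec.displacement_mm is not None:
            motion = metrics.cumulative_motion(rec.displacement_mm)
        wmh_mask = self.model.masks.get("WMH")
        row = {
            "subject_id": rec.subject_id if rec else "unknown",
            "group": rec.group if rec else "",
            "age_years": rec.age_years if rec else float("nan"),
            "sex": rec.sex if rec else "",
            "mode": self.model.config.mode,
            "sigma_physio_gm": self._tissue_mean(self.sigma_summary, "GM"),
            "sigma_physio_nawm": self._tissue_mean(self.sigma_summary, "NAWM"),
            "sigma_physio_wmh": self._tissue_mean(self.sigma_summary, "WMH"),
            "pulsatility_gm": self._tissue_mean(self.pulsatility_summary, "GM"),
            "pulsatility_nawm": self._tissue_mean(self.pulsatility_summary, "NAWM"),
            "pulsatility_wmh": self._tissue_mean(self.pulsatility_summary, "WMH"),
            "thermal_variance": self.decomposition.sigma2_therm,
            "wm_volume": rec.wm_volume if rec else float("nan"),
            "wm_pve": rec.wm_pve if rec else float("nan"),
            "wmh_volume": int(wmh_mask.sum()) if wmh_mask is not None else 0,
            "cumulative_motion_mm": motion,
            "cardiac_freq_hz": (self.cardiac_freq.f_c_hz
                                if self.cardiac_freq else float("nan")),
            "clipped_voxels": self.decomposition.clipped_count,
            "sigma_contrast_class": (
                self.sigma_contrast.extra.get("classification", "")
                if self.sigma_contrast else ""),
            "pulsatility_contrast_class": (
                self.pulsatility_contrast.extra.get("classification", "")
                if self.pulsatility_contrast else ""),
        }
        return row

    def summary(self) -> str:
        """Human-readable per-subject report."""
        lines = ["Physiological-noise model fit",
                 "=" * 34,
                 f"mode: {self.model.config.mode}   "
                 f"TR: {self.series.tr_seconds:g} s   "
                 f"volumes analyzed: {self.series.n_volumes}",
                 f"thermal ROI: corner {self.thermal_roi.corner}, "
                 f"{self.thermal_roi.n_voxels} voxels, "
                 f"variance {self.decomposition.sigma2_therm:.4g}",
                 f"clamped voxels (sigma2_epi < sigma2_therm): "
                 f"{self.decomposition.clipped_count}"]
        if self.cardiac_freq is not None:
            lines.append(f"cardiac frequency: {self.cardiac_freq.f_c_hz:.3f} Hz "
                         f"(±{self.cardiac_freq.half_window_hz:g} Hz window)")
        lines.append("")
        lines.append(f"{'tissue':<8}{'sigma_physio %':>16}{'pulsatility %':>16}"
                     f"{'voxels':>9}")
        for cls in ("GM", "WM", "NAWM", "WMH", "CSF"):
            if cls not in self.sigma_summary:
                continue
            s = self.sigma_summary[cls]
            p = (self.pulsatility_summary or {}).get(cls, {"mean": float("nan")})
            lines.append(f"{cls:<8}{s['mean']:>16.4f}{p['mean']:>16.4f}"
                         f"{s['n_voxels']:>9d}")
        return "\n".join(lines)

    def save_maps(self, out_dir) -> dict:
        """Write metric maps as NIfTI, atomically (no partial outputs)."""
        os.makedirs(out_dir, exist_ok=True)
        written = {}
        with tempfile.TemporaryDirectory(dir=out_dir) as tmp:
            pending = []
            tmp_sigma = os.path.join(tmp, "sigma_physio.nii.gz")
            pio.write_metric_map(self.sigma_physio_map, tmp_sigma)
            pending.append((tmp_sigma, os.path.join(out_dir, "sigma_physio.nii.gz")))
            if self.pulsatility_map is not None:
                tmp_puls = os.path.join(tmp, "pulsatility.nii.gz")
                pio.write_metric_map(self.pulsatility_map, tmp_puls)
                pending.append((tmp_puls, os.path.join(out_dir, "pulsatility.nii.gz")))
            for src, dst in pending:
                os.replace(src, dst)
                written[os.path.basename(dst)] = dst
        return written

    def plot_map(self, metric: str = "sigma_physio", slice_index: int = 0,
                 ax=None):
        """Render one slice of a metric map (matplotlib)."""
        import matplotlib.pyplot as plt

        m = (self.sigma_physio_map if metric == "sigma_physio"
             else self.pulsatility_map)
        if m is None:
            raise ValidationError(f"no {metric} map on this fit")
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(m.values[:, :, slice_index].T, origin="lower",
                       interpolation="nearest")
        ax.set_title(f"{m.metric_name} (% of mean), slice {slice_index}")
        plt.colorbar(im, ax=ax)
        return ax


# ---------------------------------------------------------------------------
# Cohort level
# ---------------------------------------------------------------------------

GROUP_ORDER = ("YC", "EC", "SVD")
PAIRWISE = (("YC", "EC"), ("EC", "SVD"), ("YC", "SVD"))
METRIC_COLUMNS = {"sigma_physio": "sigma_physio_nawm",
                  "pulsatility": "pulsatility_nawm"}


class CohortModel:
    """The cohort statistical battery over a per-subject summary table."""

    def __init__(self, summary: pd.DataFrame, bonferroni_m: int = 3):
        if "group" not in summary.columns:
            raise ValidationError("summary table needs a 'group' column")
        self.summary = summary.reset_index(drop=True)
        self.bonferroni_m = bonferroni_m

    @classmethod
    def from_table(cls, path, **kw) -> "CohortModel":
        return cls(pio.read_summary_table(path), **kw)

    def _groups(self, column: str) -> dict:
        out = {}
        for g in GROUP_ORDER:
            vals = self.summary.loc[self.summary["group"] == g, column]
            vals = vals.dropna().to_numpy(dtype=float)
            if vals.size:
                out[g] = vals
        return out

    def fit(self) -> "CohortResults":
        tests: dict = {}
        skipped: list = []

        def try_test(name, fn):
            try:
                tests[name] = fn()
            except (ValidationError, KeyError) as exc:
                skipped.append((name, str(exc)))
                logger.info("skipped %s: %s", name, exc)

        df = self.summary

        for metric, col in METRIC_COLUMNS.items():
            if col not in df.columns or df[col].dropna().empty:
                skipped.append((f"anova_{metric}", f"no {col} values"))
                continue
            groups = self._groups(col)

            def anova(groups=groups, metric=metric):
                if len(groups) < 2:
                    raise ValidationError("fewer than 2 groups present")
                return stats.one_way_anova(
                    *groups.values(), test_name=f"anova_{metric}_nawm")
            try_test(f"anova_{metric}", anova)

            # Post-hoc pairwise t-tests with Bonferroni over the trio.
            pair_results = []
            for a, b in PAIRWISE:
                name = f"posthoc_{metric}_{a}_vs_{b}"

                def pair(a=a, b=b, groups=groups, name=name):
                    if a not in groups or b not in groups:
                        raise ValidationError(f"group {a} or {b} missing")
                    return stats.unpaired_t(groups[a], groups[b], test_name=name)
                try_test(name, pair)
                if name in tests:
                    pair_results.append(tests[name])
            if pair_results:
                flags = stats.bonferroni(
                    [t.p_value for t in pair_results], m=self.bonferroni_m)
                for t, f in zip(pair_results, flags):
                    t.bonferroni_adjusted = True
                    t.significant = bool(f)

            # ANCOVA: thermal noise alone, then + WM volume + WM PVE.
            for label, cov_cols in (
                ("thermal", ["thermal_variance"]),
                ("thermal_wmvol_pve", ["thermal_variance", "wm_volume", "wm_pve"]),
            ):
                name = f"ancova_{metric}_{label}"

                def anc(col=col, cov_cols=cov_cols, name=name):
                    sub = df[[col, "group"] + cov_cols].dropna()
                    if sub["group"].nunique() < 2:
                        raise ValidationError("fewer than 2 groups after NA drop")
                    return stats.ancova(
                        sub[col].to_numpy(float), sub["group"].to_numpy(),
                        sub[cov_cols].to_numpy(float), test_name=name)
                try_test(name, anc)

            # Paired NAWM vs WMH within SVD, with Cohen's d.
            wmh_col = col.replace("nawm", "wmh")
            name = f"paired_{metric}_nawm_vs_wmh"

            def paired(col=col, wmh_col=wmh_col, name=name, metric=metric):
                svd = df[(df["group"] == "SVD")][[col, wmh_col]].dropna()
                if len(svd) < 2:
                    raise ValidationError("fewer than 2 SVD subjects with WMH values")
                nawm = svd[col].to_numpy(float)
                wmh = svd[wmh_col].to_numpy(float)
                res = stats.paired_t(nawm, wmh, test_name=name)
                res.effect_size = stats.cohens_d(nawm, wmh, paired=False)
                res.extra["cohens_d_pooled"] = res.effect_size
                res.extra["cohens_d_paired"] = stats.cohens_d(nawm, wmh, paired=True)
                return res
            try_test(name, paired)

        # Head-motion group comparison (EC vs SVD) and correlations.
        def motion(df=df):
            groups = self._groups("cumulative_motion_mm")
            if "EC" not in groups or "SVD" not in groups:
                raise ValidationError("motion values missing for EC or SVD")
            res = stats.unpaired_t(groups["EC"], groups["SVD"],
                                   test_name="motion_EC_vs_SVD")
            res.extra["mean_EC"] = float(groups["EC"].mean())
            res.extra["mean_SVD"] = float(groups["SVD"].mean())
            return res
        if "cumulative_motion_mm" in df.columns:
            try_test("motion_EC_vs_SVD", motion)

        def wmh_corr(col):
            def inner(col=col):
                svd = df[df["group"] == "SVD"][[col, "wmh_volume"]].dropna()
                if len(svd) < 3:
                    raise ValidationError("fewer than 3 SVD subjects")
                return stats.pearson_corr(
                    svd["wmh_volume"].to_numpy(float), svd[col].to_numpy(float),
                    test_name=f"corr_wmh_volume_{col}")
            return inner
        for metric, col in METRIC_COLUMNS.items():
            if col in df.columns and "wmh_volume" in df.columns:
                try_test(f"corr_wmh_volume_{metric}", wmh_corr(col))

        # Diagnostics: variance homogeneity and normality per tissue metric.
        for metric, col in METRIC_COLUMNS.items():
            if col not in df.columns:
                continue

            def lev(col=col, metric=metric):
                groups = self._groups(col)
                if len(groups) < 2:
                    raise ValidationError("fewer than 2 groups")
                return stats.variance_homogeneity(
                    *groups.values(), test_name=f"levene_{metric}_nawm")
            try_test(f"levene_{metric}", lev)

            for g in GROUP_ORDER:
                name = f"shapiro_{metric}_{g}"

                def shap(col=col, g=g, name=name):
                    vals = self._groups(col).get(g)
                    if vals is None or vals.size < 3:
                        raise ValidationError(f"too few {g} subjects")
                    return stats.normality(vals, test_name=name)
                try_test(name, shap)

        # Linear age effect on WM sigma_physio (the wb-style verification).
        def age_reg():
            sub = df[["sigma_physio_nawm", "age_years"]].dropna()
            if len(sub) < 3:
                raise ValidationError("fewer than 3 subjects with age")
            return stats.linear_age_regression(
                sub["sigma_physio_nawm"].to_numpy(float),
                sub["age_years"].to_numpy(float),
                test_name="age_regression_sigma_physio")
        if {"sigma_physio_nawm", "age_years"} <= set(df.columns):
            try_test("age_regression_sigma_physio", age_reg)

        contrast_counts = self._contrast_counts()
        return CohortResults(model=self, tests=tests, skipped=skipped,
                             contrast_counts=contrast_counts)

    def _contrast_counts(self) -> pd.DataFrame:
        """Per-group counts of the intra-subject GM-vs-NAWM classifications."""
        rows = []
        for col, metric in (("sigma_contrast_class", "sigma_physio"),
                            ("pulsatility_contrast_class", "pulsatility")):
            if col not in self.summary.columns:
                continue
            for g in GROUP_ORDER:
                sub = self.summary[self.summary["group"] == g][col].dropna()
                sub = sub[sub.astype(str) != ""]
                if sub.empty:
                    continue
                rows.append({
                    "metric": metric, "group": g, "n": len(sub),
                    "NAWM<GM": int((sub == "NAWM<GM").sum()),
                    "NAWM=GM": int((sub == "NAWM=GM").sum()),
                    "NAWM>GM": int((sub == "NAWM>GM").sum()),
                })
        return pd.DataFrame(rows)


@dataclass
class CohortResults:
    """Results of the cohort battery: tests, skip reasons, contrast table."""

    model: CohortModel
    tests: dict
    skipped: list
    contrast_counts: pd.DataFrame

    def __getitem__(self, name: str) -> stats.TestResult:
        return self.tests[name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, t in self.tests.items():
            rows.append({
                "test": name, "statistic": t.statistic,
                "df": ",".join(f"{d:g}" for d in t.df),
                "p_value": t.p_value, "effect_size": t.effect_size,
                "bonferroni_adjusted": t.bonferroni_adjusted,
                "significant": t.significant, "note": t.note,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Cohort statistical battery", "=" * 34]
        for name, t in self.tests.items():
            flag = ""
            if t.bonferroni_adjusted:
                flag = "  [Bonferroni: " + ("sig]" if t.significant else "ns]")
            lines.append(str(t) + flag)
        if not self.contrast_counts.empty:
            lines.append("")
            lines.append("Intra-subject GM-vs-NAWM classification counts:")
            lines.append(self.contrast_counts.to_string(index=False))
        if self.skipped:
            lines.append("")
            lines.append("Skipped tests:")
            for name, reason in self.skipped:
                lines.append(f"  {name}: {reason}")
        return "\n".join(lines)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pipeline conveniences (used by the CLI)
# ---------------------------------------------------------------------------

def run_subject(config: RunConfig, bold: BoldSeries, masks: TissueMasks,
                pulse: Optional[PulseTrace] = None,
                record: Optional[SubjectRecord] = None,
                out_dir=None) -> PhysioNoiseResults:
    """Fit one subject and optionally write its maps (atomically)."""
    sid = record.subject_id if record is not None else "unknown"
    try:
        results = PhysioNoiseModel(bold, masks, pulse=pulse, record=record,
                                   config=config).fit()
    except Exception as exc:
        raise type(exc)(f"subject {sid}: {exc}") from exc
    if out_dir is not None:
        results.save_maps(out_dir)
    return results


def run_cohort(summary: pd.DataFrame, bonferroni_m: int = 3) -> CohortResults:
    """Fit the cohort battery over a per-subject summary table."""
    return CohortModel(summary, bonferroni_m=bonferroni_m).fit()
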