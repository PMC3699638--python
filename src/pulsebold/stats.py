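"""Cohort-level statistics over per-subject tissue summaries.

Implements the test battery used for the group analysis: one-way ANOVA over
the YC/EC/SVD cohorts, ANCOVA with nuisance covariates (thermal noise, WM
volume, WM partial-volume estimate), post-hoc pooled-variance t-tests with
Bonferroni correction, paired NAWM-vs-WMH tests with Cohen's d, voxelwise
intra-subject GM-vs-NAWM contrasts, variance-homogeneity and normality
diagnostics, Pearson correlations, and a linear age regression.

All p values are two-tailed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .io import ValidationError
from .metrics import VoxelMetricMap

logger = logging.getLogger("pulsebold")

ALPHA = 0.05


@dataclass
class TestResult:
    """One statistical test, reported in the F(df1,df2)/t(df)/r style."""

    test_name: str
    statistic: float
    df: tuple
    p_value: float
    effect_size: Optional[float] = None
    bonferroni_adjusted: bool = False
    significant: Optional[bool] = None
    note: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p value {self.p_value} outside [0, 1]")

    def __str__(self) -> str:
        df = ",".join(f"{d:g}" for d in self.df)
        s = f"{self.test_name}: stat({df}) = {self.statistic:.4g}, p = {self.p_value:.4g}"
        if self.effect_size is not None and np.isfinite(self.effect_size):
            s += f", effect size = {self.effect_size:.3g}"
        return s


def _as_groups(groups: Sequence) -> list:
    return [np.asarray(g, dtype=np.float64) for g in groups]


def one_way_anova(*groups, test_name: str = "one_way_anova") -> TestResult:
    """Between/within variance decomposition; F on (k-1, N-k) df."""
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValidationError("every group needs at least 2 observations")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0:
        f = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(f, df1, df2))
    return TestResult(test_name=test_name, statistic=float(f), df=(df1, df2),
                      p_value=p)


def _dummy_code(group_labels) -> np.ndarray:
    """k-1 treatment-coded columns for a categorical factor."""
    labels = np.asarray(group_labels)
    levels = sorted(set(labels.tolist()))
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]]), levels


def _ols_rss(y: np.ndarray, x: np.ndarray) -> tuple:
    """Residual sum of squares and model rank from least squares."""
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def ancova(values, group_labels, covariates=None,
           test_name: str = "ancova") -> TestResult:
    """Group F test from ``value ~ group + covariates`` model comparison.

    The group effect is tested by comparing the full model against the
    covariates-only model (a Type-III-style test); df = (k-1, N-k-p) for p
    covariates.  With no covariates this reduces exactly to one-way ANOVA.
    """
    y = np.asarray(values, dtype=np.float64)
    g_cols, levels = _dummy_code(group_labels)
    k = len(levels)
    if k < 2:
        raise ValidationError("ANCOVA needs at least 2 groups")
    n = y.size
    cov = (np.empty((n, 0)) if covariates is None
           else np.atleast_2d(np.asarray(covariates, dtype=np.float64)))
    if cov.size and cov.shape[0] != n:
        cov = cov.T
    if cov.shape[0] not in (n,) and cov.size:
        raise ValidationError("covariate matrix does not match outcome length")
    p = cov.shape[1]
    intercept = np.ones((n, 1))
    x_full = np.hstack([intercept, g_cols, cov])
    x_reduced = np.hstack([intercept, cov])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValidationError("rank-deficient design matrix in ANCOVA")
    if n <= k + p:
        raise ValidationError("too few subjects for this covariate set")
    rss_full, _ = _ols_rss(y, x_full)
    rss_reduced, _ = _ols_rss(y, x_reduced)
    df1, df2 = k - 1, n - k - p
    num = max(rss_reduced - rss_full, 0.0) / df1
    den = rss_full / df2
    if den == 0:
        f, pval = (np.inf, 0.0) if num > 0 else (0.0, 1.0)
    else:
        f = num / den
        pval = float(sps.f.sf(f, df1, df2))
    return TestResult(test_name=test_name, statistic=float(f), df=(df1, df2),
                      p_value=pval, extra={"n_covariates": p})


def paired_t(values_a, values_b, test_name: str = "paired_t") -> TestResult:
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size != b.size or a.size < 2:
        raise ValidationError("paired test needs equal lengths >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return TestResult(test_name=test_name, statistic=np.nan, df=(a.size - 1,),
                          p_value=np.nan, note="zero variance of differences")
    t, p = sps.ttest_rel(a, b)
    return TestResult(test_name=test_name, statistic=float(t), df=(a.size - 1,),
                      p_value=float(p))


def unpaired_t(values_a, values_b, equal_var: bool = True,
               test_name: str = "unpaired_t") -> TestResult:
    """Two-sample t-test; pooled variance by default (Welch via flag)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    if np.allclose(np.concatenate([a, b]).std(ddof=1), 0.0):
        return TestResult(test_name=test_name, statistic=np.nan,
                          df=(a.size + b.size - 2,), p_value=np.nan,
                          note="zero variance")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    return TestResult(test_name=test_name, statistic=float(res.statistic),
                      df=(df,), p_value=float(res.pvalue))


def cohens_d(values_a, values_b, paired: bool = False) -> float:
    """Cohen's d effect size.

    Default is the classic pooled-SD form, ``(mean_a - mean_b) / s_pooled``;
    with ``paired=True`` the mean difference is scaled by the SD of the
    paired differences instead.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    if paired:
        if a.size != b.size:
            raise ValidationError("paired effect size needs equal lengths")
        d = a - b
        sd = d.std(ddof=1)
        return float(d.mean() / sd) if sd > 0 else float("nan")
    sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
           / (a.size + b.size - 2))
    if sp2 <= 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def variance_homogeneity(*groups, test_name: str = "levene") -> TestResult:
    """Levene's test on absolute deviations from the group means."""
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise ValidationError("Levene needs at least 2 groups")
    stat, p = sps.levene(*groups, center="mean")
    k = len(groups)
    n = sum(g.size for g in groups)
    return TestResult(test_name=test_name, statistic=float(stat),
                      df=(k - 1, n - k), p_value=float(p))


def normality(values, test_name: str = "shapiro_wilk") -> TestResult:
    """Shapiro-Wilk W; scipy's implementation of the Royston algorithm."""
    v = np.asarray(values, dtype=np.float64)
    if not 3 <= v.size <= 2000:
        raise ValidationError("Shapiro-Wilk requires 3 <= n <= 2000")
    w, p = sps.shapiro(v)
    return TestResult(test_name=test_name, statistic=float(w), df=(v.size,),
                      p_value=float(p))


def pearson_corr(x, y, test_name: str = "pearson") -> TestResult:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValidationError("correlation needs equal lengths >= 3")
    if x.std() == 0 or y.std() == 0:
        return TestResult(test_name=test_name, statistic=np.nan, df=(x.size - 2,),
                          p_value=np.nan, note="constant input")
    r, p = sps.pearsonr(x, y)
    return TestResult(test_name=test_name, statistic=float(r), df=(x.size - 2,),
                      p_value=float(p), effect_size=float(r))


def linear_age_regression(metric, age, extra_covariates=None,
                          test_name: str = "age_regression") -> TestResult:
    """Linear regression of a metric on age, optionally covariate-adjusted.

    Reports the age slope, Pearson r of the simple fit, the two-tailed p of
    the age coefficient, and the covariate-adjusted p when extras (e.g. slice
    thickness) are supplied.
    """
    import statsmodels.api as sm

    y = np.asarray(metric, dtype=np.float64)
    a = np.asarray(age, dtype=np.float64)
    if y.size != a.size or y.size < 3:
        raise ValidationError("regression needs equal lengths >= 3")
    if a.std() == 0:
        return TestResult(test_name=test_name, statistic=np.nan, df=(y.size - 2,),
                          p_value=np.nan, note="constant predictor")
    simple = sps.linregress(a, y)
    extra = {"slope": float(simple.slope), "r": float(simple.rvalue)}
    if extra_covariates is not None:
        cov = np.atleast_2d(np.asarray(extra_covariates, dtype=np.float64))
        if cov.shape[0] != y.size:
            cov = cov.T
        x = sm.add_constant(np.column_stack([a, cov]))
        fit = sm.OLS(y, x).fit()
        extra["adjusted_p"] = float(fit.pvalues[1])
        extra["adjusted_slope"] = float(fit.params[1])
    return TestResult(test_name=test_name, statistic=float(simple.rvalue),
                      df=(y.size - 2,), p_value=float(simple.pvalue),
                      effect_size=float(simple.rvalue), extra=extra)


def intra_subject_tissue_contrast(metric_map: VoxelMetricMap, masks,
                                  class_a: str = "GM", class_b: str = "NAWM",
                                  alpha: float = ALPHA) -> TestResult:
    """Voxelwise unpaired t between two tissue classes within one subject.

    Classifies the subject as ``NAWM<GM`` (b significantly below a),
    ``NAWM>GM``, or ``NAWM=GM`` (no significant difference at alpha).
    """
    grids = dict(masks.labels)
    nawm = masks.nawm()
    if nawm is not None:
        grids["NAWM"] = nawm
    for c in (class_a, class_b):
        if c not in grids or not grids[c].any():
            return TestResult(test_name="tissue_contrast", statistic=np.nan,
                              df=(0,), p_value=np.nan,
                              note=f"class {c} empty; comparison skipped")
    va = metric_map.values[grids[class_a]]
    vb = metric_map.values[grids[class_b]]
    va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
    if va.size < 2 or vb.size < 2:
        return TestResult(test_name="tissue_contrast", statistic=np.nan,
                          df=(0,), p_value=np.nan, note="too few defined voxels")
    res = unpaired_t(va, vb, test_name=f"{class_b}_vs_{class_a}_voxelwise")
    if np.isfinite(res.p_value) and res.p_value < alpha:
        label = f"{class_b}<{class_a}" if vb.mean() < va.mean() else f"{class_b}>{class_a}"
    else:
        label = f"{class_b}={class_a}"
    res.extra["classification"] = label
    res.significant = bool(np.isfinite(res.p_value) and res.p_value < alpha)
    return res


def bonferroni(p_values, m: Optional[int] = None, alpha: float = ALPHA):
    """Bonferroni family-wise correction: significant iff p < alpha/m."""
    p = np.asarray(p_values, dtype=np.float64)
    if m is None:
        m = p.size
    if m < 1:
        raise ValidationError("number of comparisons must be >= 1")
    return p < alpha / m
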