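"""ROC curves, Mann-Whitney AUC, DeLong variance/CI and the paired DeLong test.

The AUC is computed through the Mann-Whitney identity
``AUC = P(case > control) + 0.5 * P(case = control)`` and therefore equals
the trapezoidal area under the empirical ROC curve, ties contributing
diagonal segments.  Variances follow DeLong's structural-component
construction: per-case placements ``V10`` (fraction of controls below the
case, ties half-weighted) and per-control placements ``V01``; the AUC
variance is ``var(V10)/m + var(V01)/n`` and the paired test for two markers
measured on the same samples uses the placement covariances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class ROCComparison:
    """Paired comparison of two markers' AUCs on the same samples."""

    assay1: str
    assay2: str
    n: int
    auc1: float
    auc2: float
    auc_diff: float
    diff_ci: tuple[float, float]
    p_value: float


def _as_groups(case_values, control_values):
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    return cases, controls


def placements(case_values, control_values) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components (V10 per case, V01 per control)."""
    cases, controls = _as_groups(case_values, control_values)
    cs, ks = np.sort(cases), np.sort(controls)
    below = np.searchsorted(ks, cases, side="left")
    ties = np.searchsorted(ks, cases, side="right") - below
    v10 = (below + 0.5 * ties) / controls.size
    above = cases.size - np.searchsorted(cs, controls, side="right")
    ties_c = np.searchsorted(cs, controls, side="right") - np.searchsorted(
        cs, controls, side="left"
    )
    v01 = (above + 0.5 * ties_c) / cases.size
    return v10, v01


def auc_mann_whitney(case_values, control_values) -> float:
    """AUC via the Mann-Whitney identity (ties half-weighted)."""
    v10, _ = placements(case_values, control_values)
    return float(v10.mean())


def delong_variance(case_values, control_values) -> float:
    """DeLong variance of the Mann-Whitney AUC; needs >= 2 per group."""
    cases, controls = _as_groups(case_values, control_values)
    if cases.size < 2 or controls.size < 2:
        raise ValueError("DeLong variance requires at least 2 cases and 2 controls")
    v10, v01 = placements(cases, controls)
    return float(v10.var(ddof=1) / cases.size + v01.var(ddof=1) / controls.size)


def delong_ci(case_values, control_values, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC with its DeLong normal-approximation CI, clipped to [0, 1]."""
    auc = auc_mann_whitney(case_values, control_values)
    se = delong_variance(case_values, control_values) ** 0.5
    z = stats.norm.ppf(1 - alpha / 2)
    return auc, (max(0.0, auc - z * se), min(1.0, auc + z * se))


def roc_curve(case_values, control_values) -> ROCCurve:
    """Empirical ROC curve over every achievable cutpoint (>= rule).

    Thresholds run from above the maximum (sens 0, FPR 0) down to below the
    minimum (sens 1, FPR 1); the trapezoidal area equals the Mann-Whitney
    AUC exactly.
    """
    cases, controls = _as_groups(case_values, control_values)
    pooled = np.unique(np.concatenate([cases, controls]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    span = max(pooled[-1] - pooled[0], 1.0)
    thr = np.concatenate([[pooled[-1] + span], mids[::-1], [pooled[0] - span]])
    cs, ks = np.sort(cases), np.sort(controls)
    sens = (cases.size - np.searchsorted(cs, thr, side="left")) / cases.size
    fpr = (controls.size - np.searchsorted(ks, thr, side="left")) / controls.size
    auc, ci = delong_ci(cases, controls)
    return ROCCurve(
        thresholds=thr,
        sensitivity=sens,
        one_minus_specificity=fpr,
        auc=auc,
        auc_ci=ci,
        n_cases=int(cases.size),
        n_controls=int(controls.size),
    )


def delong_paired_test(
    assay1_values,
    assay2_values,
    labels,
    *,
    assay1: str = "assay1",
    assay2: str = "assay2",
) -> ROCComparison:
    """DeLong's test for the difference of two paired AUCs.

    ``labels`` is boolean/0-1 (True = case); the two value vectors must be
    the same samples in the same order.  Samples with a missing (NaN) value
    in either marker are dropped (pairwise-complete selection) and ``n``
    reports the pairs actually used.
    """
    x = np.asarray(assay1_values, dtype=float)
    y = np.asarray(assay2_values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if not (x.shape == y.shape == lab.shape):
        raise ValueError("assay value vectors and labels must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y, lab = x[keep], y[keep], lab[keep]
    m, n = int(lab.sum()), int((~lab).sum())
    if m < 2 or n < 2:
        raise ValueError("paired DeLong test requires >= 2 cases and >= 2 controls")
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for i, vals in enumerate((x, y)):
        v10[i], v01[i] = placements(vals[lab], vals[~lab])
        aucs[i] = v10[i].mean()
    s10 = np.cov(v10, ddof=1)
    s01 = np.cov(v01, ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = float(aucs[0] - aucs[1])
    if var_diff <= 0 or np.isclose(var_diff, 0.0):
        p = 1.0 if np.isclose(diff, 0.0) else 0.0
        ci = (diff, diff)
    else:
        se = var_diff**0.5
        z = diff / se
        p = float(2 * stats.norm.sf(abs(z)))
        ci = (diff - 1.96 * se, diff + 1.96 * se)
    return ROCComparison(
        assay1=assay1,
        assay2=assay2,
        n=m + n,
        auc1=float(aucs[0]),
        auc2=float(aucs[1]),
        auc_diff=diff,
        diff_ci=ci,
        p_value=p,
    )


def welch_t_test(group1, group2) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Satterthwaite df, two-sided p)."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("Welch t-test requires >= 2 values per group")
    res = stats.ttest_ind(g1, g2, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
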