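"""Positivity-threshold calibration under repeated stratified cross-validation.

Two threshold rules are calibrated for each (analyte, assay):

* ``chisq`` — the cutpoint maximising the Pearson chi-square statistic of the
  case/control x positive/negative 2x2 table (ties broken towards the
  largest threshold, i.e. towards specificity, the screening priority);
* ``spec98`` — the cutpoint placing 98% of the training controls below it,
  so training specificity is at least 98% by construction.

A sample is called positive when ``value >= threshold``.  Thresholds are
fitted inside 100 balanced (status-stratified) 10-fold cross-validations and
sensitivity/specificity are assessed on the held-out folds only, yielding
1000 held-out evaluations per (analyte, assay, method) that are summarised
as mean with an empirical 95% percentile interval (plus median and IQR).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

METHODS = ("chisq", "spec98")


def chisq_statistic(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square of the 2x2 table [[a, b], [c, d]], no continuity correction.

    a = cases positive, b = cases negative, c = controls positive,
    d = controls negative.  Returns 0.0 when any margin is zero.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def _chisq_vec(a, b, c, d):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = n * (a * d - b * c) ** 2 / denom
    return np.where(denom == 0, 0.0, chi)


def candidate_thresholds(case_values, control_values) -> np.ndarray:
    """All cutpoints that can produce distinct 2x2 tables under the >= rule.

    Midpoints between consecutive distinct pooled values, plus one sentinel
    below the minimum (everyone positive) and one above the maximum
    (everyone negative).
    """
    pooled = np.unique(np.concatenate([np.asarray(case_values, dtype=float),
                                       np.asarray(control_values, dtype=float)]))
    if pooled.size == 0:
        raise ValueError("no values supplied")
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    span = max(pooled[-1] - pooled[0], 1.0)
    return np.concatenate([[pooled[0] - span], mids, [pooled[-1] + span]])


def optimal_threshold_chisq(
    case_values, control_values, tie_break: str = "largest"
) -> float:
    """Candidate threshold maximising the chi-square of the induced 2x2 table.

    Exact ties at the maximum are broken towards the largest (default) or
    smallest threshold.  Unless every candidate scores zero, the returned
    threshold never classifies everyone identically (the degenerate sentinel
    cuts have a zero margin and hence chi-square 0).
    """
    cases = np.sort(np.asarray(case_values, dtype=float))
    controls = np.sort(np.asarray(control_values, dtype=float))
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    cands = candidate_thresholds(cases, controls)
    a = cases.size - np.searchsorted(cases, cands, side="left")
    c = controls.size - np.searchsorted(controls, cands, side="left")
    chi = _chisq_vec(a, cases.size - a, c, controls.size - c)
    best = chi.max()
    tied = np.flatnonzero(chi >= best * (1 - 1e-12) if best > 0 else chi == best)
    if tie_break == "largest":
        return float(cands[tied[-1]])
    if tie_break == "smallest":
        return float(cands[tied[0]])
    raise ValueError(f"unknown tie_break {tie_break!r}")


def threshold_spec98(control_values, level: float = 0.98) -> float:
    """Smallest cutpoint leaving at least ``level`` of the controls strictly below.

    Implemented as the ceil(level*n)-th control order statistic, lifted to
    the midpoint towards the next distinct control value (or just above it
    when all remaining controls tie) so that the >= positivity rule attains
    training specificity >= ``level``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    controls = np.sort(np.asarray(control_values, dtype=float))
    if controls.size == 0:
        raise ValueError("controls must be non-empty")
    m = math.ceil(level * controls.size)
    base = controls[m - 1]
    higher = controls[controls > base]
    if higher.size:
        return float((base + higher[0]) / 2.0)
    return float(np.nextafter(base, np.inf))


def evaluate_threshold(threshold: float, case_values, control_values) -> tuple[float, float]:
    """(sensitivity, specificity) of the ``value >= threshold`` rule."""
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    sensitivity = float(np.mean(cases >= threshold))
    specificity = float(np.mean(controls < threshold))
    return sensitivity, specificity


def fit_threshold(method: str, case_values, control_values, *, level: float = 0.98,
                  tie_break: str = "largest") -> float:
    """Dispatch to the requested threshold rule on training data."""
    if method == "chisq":
        return optimal_threshold_chisq(case_values, control_values, tie_break=tie_break)
    if method == "spec98":
        return threshold_spec98(control_values, level=level)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def fold_seed(seed: int, repeat: int) -> int:
    """Deterministic per-repeat fold seed; shared by every module that
    partitions the same cohort so fold structures coincide across analyses."""
    return int(np.random.SeedSequence([int(seed), int(repeat)]).generate_state(1)[0] % (2**31))


def stratified_folds(status: np.ndarray, k: int, seed: int, repeat: int):
    """Yield (train_idx, test_idx) for one balanced k-fold partition.

    "Balanced" means stratified by case/control status: each fold preserves
    the global case fraction to within one sample.
    """
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed(seed, repeat))
    yield from skf.split(np.zeros(len(status)), status)


def _sample_view(table: pd.DataFrame, analyte: str, assay: str) -> pd.DataFrame:
    sub = table[
        (table["analyte"] == analyte)
        & (table["assay"] == assay)
        & (table["replicate_index"].fillna(1) == 1)
    ]
    return sub.sort_values("sample_id").reset_index(drop=True)


def cross_validate_thresholds(
    table: pd.DataFrame,
    method: str,
    n_repeats: int = 100,
    k: int = 10,
    seed: int = 0,
    *,
    level: float = 0.98,
    tie_break: str = "largest",
) -> pd.DataFrame:
    """Held-out threshold evaluations for every (analyte, assay) in ``table``.

    Per repeat an independent status-stratified partition into ``k`` folds is
    drawn; the threshold is fitted on the k-1 training folds and evaluated on
    the held-out fold.  Returns ``n_repeats * k`` rows per (analyte, assay)
    with columns analyte, assay, method, repeat, fold, threshold,
    sensitivity, specificity.  Deterministic given ``seed``; repeat ``r`` is
    reproducible in isolation because its fold seed depends only on
    ``(seed, r)``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    rows = []
    pairs = table[["analyte", "assay"]].drop_duplicates().itertuples(index=False)
    for analyte, assay in pairs:
        sub = _sample_view(table, analyte, assay)
        values = sub["value"].to_numpy(dtype=float)
        is_case = (sub["status"] == "case").to_numpy()
        n_cases, n_controls = int(is_case.sum()), int((~is_case).sum())
        if n_cases < k:
            raise ValueError(
                f"stratum cases for ({analyte}, {assay}): {n_cases} samples < {k} folds"
            )
        if n_controls < k:
            raise ValueError(
                f"stratum controls for ({analyte}, {assay}): {n_controls} samples < {k} folds"
            )
        for repeat in range(1, n_repeats + 1):
            for fold, (train, test) in enumerate(
                stratified_folds(is_case, k, seed, repeat), start=1
            ):
                thr = fit_threshold(
                    method,
                    values[train][is_case[train]],
                    values[train][~is_case[train]],
                    level=level,
                    tie_break=tie_break,
                )
                sens, spec = evaluate_threshold(
                    thr, values[test][is_case[test]], values[test][~is_case[test]]
                )
                rows.append(
                    (analyte, assay, method, repeat, fold, thr, sens, spec)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "analyte",
            "assay",
            "method",
            "repeat",
            "fold",
            "threshold",
            "sensitivity",
            "specificity",
        ],
    )


def _summary_block(x: np.ndarray, prefix: str, ci: str) -> dict:
    if ci == "percentile":
        lo, hi = np.percentile(x, [2.5, 97.5])
    elif ci == "normal":
        half = 1.96 * x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0
        lo, hi = x.mean() - half, x.mean() + half
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    q25, q75 = np.percentile(x, [25, 75])
    return {
        f"{prefix}_mean": float(x.mean()),
        f"{prefix}_ci_low": float(lo),
        f"{prefix}_ci_high": float(hi),
        f"{prefix}_median": float(np.median(x)),
        f"{prefix}_q25": float(q25),
        f"{prefix}_q75": float(q75),
    }


def summarize_cv(results: pd.DataFrame, ci: str = "percentile") -> pd.DataFrame:
    """Mean, 95% interval, median and IQR of threshold/sensitivity/specificity
    per (analyte, assay, method) over the held-out fold evaluations.

    ``ci='percentile'`` (default) uses the empirical 2.5th/97.5th percentiles
    of the fold values; ``ci='normal'`` the normal approximation for the mean.
    """
    if len(results) == 0:
        raise ValueError("empty results")
    rows = []
    for (analyte, assay, method), grp in results.groupby(["analyte", "assay", "method"]):
        if len(grp) < 2:
            raise ValueError(f"need >= 2 fold rows for ({analyte}, {assay}, {method})")
        row = {"analyte": analyte, "assay": assay, "method": method, "n_folds": len(grp)}
        for col in ("threshold", "sensitivity", "specificity"):
            row.update(_summary_block(grp[col].to_numpy(dtype=float), col, ci))
        rows.append(row)
    return pd.DataFrame(rows)
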