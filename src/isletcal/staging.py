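"""Multi-autoantibody positivity counts and staging performance.

Presence of at least two islet autoantibodies (rule "AAb2") defines stage 1
(normoglycemic) or stage 2 (dysglycemic) type 1 diabetes; "AAb1" (at least
one) is the screening-oriented relaxation.  Per-analyte thresholds are
fitted independently on the training folds of the same stratified
cross-validation partitions used for single-marker calibration (the fold
seed depends only on the master seed and repeat index), then each held-out
sample's 0-4 positive-marker count and the derived staging flags are
evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .thresholds import METHODS, evaluate_threshold, fit_threshold, stratified_folds

RULES = (1, 2)
SUBGROUP_ORDER = ("PBC", "DOC", "BDC", "patient")


@dataclass(frozen=True)
class StagingResult:
    """Positive-marker count and staging flags for one sample."""

    sample_id: str
    n_positive: int
    stage_flag_1: bool  # >= 1 autoantibody
    stage_flag_2: bool  # >= 2 autoantibodies (stage 1/2 criterion)


@dataclass(frozen=True)
class StagingCVResult:
    """Fold-level and summarised staging performance.

    fold_results: one row per (repeat, fold, rule) with held-out
        sensitivity/specificity.
    summary: mean + 95% percentile interval per rule.
    subgroup_proportions: per (repeat, fold, subgroup) the proportions of
        samples positive for 0-4 markers (boxplot-ready).
    """

    assay: str
    method: str
    fold_results: pd.DataFrame
    summary: pd.DataFrame
    subgroup_proportions: pd.DataFrame


def collapse_variant_markers(
    table: pd.DataFrame,
    variants=("ZnT8RA", "ZnT8WA", "ZnT8QA"),
    name: str = "ZnT8A",
) -> pd.DataFrame:
    """Collapse epitope-variant rows into one marker by the maximum level.

    A triple-variant radiobinding screen (ZnT8 arginine/tryptophan/glutamine
    at residue 325) reports one level per variant; staging treats ZnT8A as a
    single marker, so the per-sample maximum across variants is used.  The
    collapsed rows keep ``truth_positive`` as the OR over variants when that
    column is present.  Rows of other analytes pass through unchanged.
    """
    mask = table["analyte"].isin(variants)
    if not mask.any():
        return table
    rest, trip = table[~mask], table[mask]
    keys = ["sample_id", "status", "subgroup", "specimen", "assay", "replicate_index"]
    agg = {"value": "max"}
    if "truth_positive" in trip.columns:
        agg["truth_positive"] = "any"
    collapsed = trip.groupby(keys, as_index=False, dropna=False).agg(agg)
    collapsed["analyte"] = name
    return pd.concat([rest, collapsed], ignore_index=True)[list(table.columns)]


def count_positives(sample_levels: dict, thresholds: dict) -> StagingResult:
    """Count analytes with ``value >= threshold`` for one sample.

    A missing (None/NaN) analyte level is treated as a negative call with a
    warning; an analyte measured without a threshold is an error.
    """
    missing_thr = [a for a in sample_levels if a not in thresholds]
    if missing_thr:
        raise ValueError(f"no threshold for measured analyte(s) {missing_thr}")
    n_positive = 0
    for analyte, value in sample_levels.items():
        if value is None or (isinstance(value, float) and np.isnan(value)):
            warnings.warn(f"missing level for {analyte}; treated as negative")
            continue
        if value >= thresholds[analyte]:
            n_positive += 1
    sid = str(sample_levels.get("sample_id", ""))
    return StagingResult(sid, n_positive, n_positive >= 1, n_positive >= 2)


def _wide_table(table: pd.DataFrame, assay: str, analytes=None) -> pd.DataFrame:
    sub = table[(table["assay"] == assay) & (table["replicate_index"].fillna(1) == 1)]
    if len(sub) == 0:
        raise ValueError(f"no measurements for assay {assay!r}")
    analytes = sorted(sub["analyte"].unique()) if analytes is None else list(analytes)
    missing = [a for a in analytes if a not in set(sub["analyte"])]
    if missing:
        raise ValueError(f"assay {assay!r} lacks analyte(s) {missing}")
    wide = sub.pivot_table(
        index="sample_id", columns="analyte", values="value", aggfunc="first"
    )[analytes]
    meta = sub.drop_duplicates("sample_id").set_index("sample_id")[["status", "subgroup"]]
    wide = wide.join(meta).sort_index().reset_index()
    if wide[analytes].isna().any().any():
        warnings.warn("samples with missing analyte levels treated as negative")
    return wide


def _counts(values: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    # NaN (missing measurement) compares False -> negative call
    with np.errstate(invalid="ignore"):
        return (values >= thresholds).sum(axis=1)


def subgroup_breakdown(
    table: pd.DataFrame, thresholds: dict, assay: str
) -> pd.DataFrame:
    """Distribution of 0-4 positive-marker counts per subgroup under fixed
    thresholds; one row per subgroup with proportions summing to 1."""
    analytes = sorted(thresholds)
    wide = _wide_table(table, assay, analytes)
    unknown = set(wide["subgroup"]) - set(SUBGROUP_ORDER)
    if unknown:
        raise ValueError(f"unknown subgroup label(s) {sorted(unknown)}")
    thr = np.array([thresholds[a] for a in analytes], dtype=float)
    counts = _counts(wide[analytes].to_numpy(dtype=float), thr)
    return _breakdown_frame(wide["subgroup"].to_numpy(), counts, len(analytes))


def _breakdown_frame(subgroups: np.ndarray, counts: np.ndarray, n_analytes: int,
                     **extra) -> pd.DataFrame:
    rows = []
    for group in SUBGROUP_ORDER:
        mask = subgroups == group
        if not mask.any():
            continue
        dist = np.bincount(counts[mask], minlength=n_analytes + 1) / mask.sum()
        row = dict(extra, subgroup=group, n=int(mask.sum()))
        row.update({f"prop_{i}": dist[i] for i in range(n_analytes + 1)})
        rows.append(row)
    return pd.DataFrame(rows)


def staging_cv(
    table: pd.DataFrame,
    assay: str,
    method: str,
    n_repeats: int = 100,
    k: int = 10,
    seed: int = 0,
    *,
    control_set: str = "all",
    level: float = 0.98,
    analytes=None,
) -> StagingCVResult:
    """Cross-validated multi-marker staging performance for one assay.

    Within each fold of the shared stratified partitions, the four
    per-analyte thresholds are fitted independently on the training folds;
    sensitivity (cases with >= r markers) and specificity (controls with
    < r markers) are evaluated on the held-out fold for rules r = 1, 2,
    together with the per-subgroup 0-4 count distribution.

    ``control_set='PBC'`` restricts the controls used for fitting and
    evaluation to the population-based group, mirroring the alternative
    reference-population analysis.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    wide = _wide_table(table, assay, analytes)
    if control_set == "PBC":
        wide = wide[(wide["status"] == "case") | (wide["subgroup"] == "PBC")]
        wide = wide.reset_index(drop=True)
    elif control_set != "all":
        raise ValueError(f"control_set must be 'all' or 'PBC', got {control_set!r}")
    analyte_cols = [c for c in wide.columns if c not in ("sample_id", "status", "subgroup")]
    values = wide[analyte_cols].to_numpy(dtype=float)
    is_case = (wide["status"] == "case").to_numpy()
    subgroups = wide["subgroup"].to_numpy()

    fold_rows, breakdowns = [], []
    for repeat in range(1, n_repeats + 1):
        for fold, (train, test) in enumerate(
            stratified_folds(is_case, k, seed, repeat), start=1
        ):
            thr = np.empty(len(analyte_cols))
            for j in range(len(analyte_cols)):
                col = values[train, j]
                case_vals = col[is_case[train]]
                ctrl_vals = col[~is_case[train]]
                thr[j] = fit_threshold(
                    method,
                    case_vals[~np.isnan(case_vals)],
                    ctrl_vals[~np.isnan(ctrl_vals)],
                    level=level,
                )
            counts = _counts(values[test], thr)
            for rule in RULES:
                sens = float(np.mean(counts[is_case[test]] >= rule))
                spec = float(np.mean(counts[~is_case[test]] < rule))
                fold_rows.append((repeat, fold, rule, sens, spec))
            breakdowns.append(
                _breakdown_frame(
                    subgroups[test], counts, len(analyte_cols), repeat=repeat, fold=fold
                )
            )
    fold_results = pd.DataFrame(
        fold_rows, columns=["repeat", "fold", "rule", "sensitivity", "specificity"]
    )
    summary_rows = []
    for rule, grp in fold_results.groupby("rule"):
        row = {"assay": assay, "method": method, "rule": f"AAb{rule}", "n_folds": len(grp)}
        for col in ("sensitivity", "specificity"):
            x = grp[col].to_numpy()
            lo, hi = np.percentile(x, [2.5, 97.5])
            row.update(
                {
                    f"{col}_mean": float(x.mean()),
                    f"{col}_ci_low": float(lo),
                    f"{col}_ci_high": float(hi),
                }
            )
        summary_rows.append(row)
    return StagingCVResult(
        assay=assay,
        method=method,
        fold_results=fold_results,
        summary=pd.DataFrame(summary_rows),
        subgroup_proportions=pd.concat(breakdowns, ignore_index=True),
    )
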