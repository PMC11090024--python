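"""Normalisation of raw assay values onto the analysis scale.

Radiobinding-assay (RBA) concentrations can be zero or negative after
calibration-curve readoff; those are imputed to half the smallest positive
observed value for that analyte and the series is then log2-transformed.
ADAP dCt readouts are taken as a direct measure (no transform).  All assays
are oriented at load time so that larger values mean more antibody, which
lets a single ``value >= threshold`` positivity convention serve the whole
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import TABLE_COLUMNS

REQUIRED_COLUMNS = (
    "sample_id",
    "status",
    "subgroup",
    "specimen",
    "analyte",
    "assay",
    "replicate_index",
    "value",
)

VALID_STATUS = {"case", "control"}
VALID_SUBGROUPS = {"PBC", "DOC", "BDC", "patient"}


class LoadError(ValueError):
    """Raised when an input CSV fails validation."""


@dataclass(frozen=True)
class AssayRule:
    """How to bring one assay's raw values onto the analysis scale.

    larger_is_positive: whether larger raw values mean more antibody; when
        False values are negated at load time.
    log2: apply nonpositive-value imputation followed by log2 (RBA-style
        concentration units); dCt-style readouts leave this False.
    """

    larger_is_positive: bool = True
    log2: bool = False


#: Default orientation map for the study's three assay platforms.
DEFAULT_ORIENTATION = {
    "RBA": AssayRule(larger_is_positive=True, log2=True),
    "ADAP_CRC": AssayRule(larger_is_positive=True, log2=False),
    "ADAP_Enable": AssayRule(larger_is_positive=True, log2=False),
}


@dataclass(frozen=True)
class ImputationReport:
    """Bookkeeping for one imputation pass."""

    n_imputed: int
    imputation_value: float | None

    def __post_init__(self) -> None:
        if self.n_imputed > 0 and not (self.imputation_value or 0) > 0:
            raise ValueError("imputation_value must be > 0 when values were imputed")


def impute_nonpositive(values) -> tuple[np.ndarray, ImputationReport]:
    """Replace values <= 0 by (minimum positive observed value) / 2.

    "Minimum observed value" is read as the minimum *positive* observed
    value: any other reading could yield a nonpositive imputation, which
    would break the subsequent log2 transform.
    """
    arr = np.asarray(values, dtype=float)
    mask = arr <= 0
    n_imputed = int(mask.sum())
    if n_imputed == 0:
        return arr.copy(), ImputationReport(0, None)
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("cannot impute: no value is strictly positive")
    base = float(positive.min()) / 2.0
    out = arr.copy()
    out[mask] = base
    return out, ImputationReport(n_imputed, base)


def log2_transform(values) -> np.ndarray:
    """Elementwise log2; input must be strictly positive (impute first)."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError(
            "log2_transform requires strictly positive values; "
            "run impute_nonpositive first"
        )
    return np.log2(arr)


def load_measurements(
    path, orientation_map: dict[str, AssayRule] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-format measurement CSV and normalise it onto the analysis scale.

    Returns ``(table, report)`` where ``report`` has one row per
    (analyte, assay) with the number of imputed values, the imputation value
    and the transform applied.  Imputation bases are computed per
    (analyte, assay) over the full file, before any cross-validation split.
    """
    orientation_map = DEFAULT_ORIENTATION if orientation_map is None else orientation_map
    raw = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise LoadError(f"missing required columns: {missing}")

    numeric = pd.to_numeric(raw["value"], errors="coerce")
    bad = raw.index[numeric.isna() & raw["value"].notna()]
    if len(bad) > 0:
        # +2: header line plus 1-based indexing, i.e. the line number in the file
        raise LoadError(f"non-numeric value at CSV line {bad[0] + 2}")
    if numeric.isna().any():
        raise LoadError(f"missing value at CSV line {raw.index[numeric.isna()][0] + 2}")
    table = raw.copy()
    table["value"] = numeric.astype(float)

    unknown_assays = sorted(set(table["assay"]) - set(orientation_map))
    if unknown_assays:
        raise LoadError(f"unknown assay(s) {unknown_assays}: no orientation rule")
    bad_status = sorted(set(table["status"]) - VALID_STATUS)
    if bad_status:
        raise LoadError(f"unknown status label(s) {bad_status}")
    bad_sub = sorted(set(table["subgroup"]) - VALID_SUBGROUPS)
    if bad_sub:
        raise LoadError(f"unknown subgroup label(s) {bad_sub}")
    dup = table.duplicated(subset=["sample_id", "analyte", "assay", "replicate_index"])
    if dup.any():
        raise LoadError(
            f"duplicate (sample_id, analyte, assay, replicate_index) at CSV line "
            f"{table.index[dup][0] + 2}"
        )

    reports = []
    for (analyte, assay), idx in table.groupby(["analyte", "assay"]).groups.items():
        rule = orientation_map[assay]
        vals = table.loc[idx, "value"].to_numpy()
        n_imputed, imp_value = 0, None
        if rule.log2:
            vals, rep = impute_nonpositive(vals)
            n_imputed, imp_value = rep.n_imputed, rep.imputation_value
            vals = log2_transform(vals)
        if not rule.larger_is_positive:
            vals = -vals
        table.loc[idx, "value"] = vals
        reports.append(
            {
                "analyte": analyte,
                "assay": assay,
                "n_imputed": n_imputed,
                "imputation_value": imp_value,
                "transform": "log2" if rule.log2 else "none",
                "negated": not rule.larger_is_positive,
            }
        )
    cols = [c for c in TABLE_COLUMNS if c in table.columns]
    return table[cols], pd.DataFrame(reports)
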