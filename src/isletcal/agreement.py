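"""Replicate (intra-assay) and inter-assay agreement statistics.

All agreement is computed on the analysis (log2 / dCt) scale: the mean
paired difference (bias), the standard deviation of paired differences
(sddiff), Bland-Altman 95% limits of agreement, and Pearson's r with a
Fisher-z confidence interval.  Correlations are reported separately for
cases and controls because control sera sit near the assay floor, where
between-assay correlation is expected to be low.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AgreementStats:
    """Agreement between two paired measurement series."""

    n: int
    bias: float
    sddiff: float
    loa: tuple[float, float]
    pearson_r: float | None
    r_ci: tuple[float, float] | None
    note: str | None = None


def _fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return (r, r)
    z = math.atanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
    return (math.tanh(z - half), math.tanh(z + half))


def paired_agreement(x, y) -> AgreementStats:
    """Bias, sddiff, Bland-Altman limits and Pearson r for paired vectors.

    Differences are ``d = y - x``; ``bias = mean(d)`` and ``sddiff`` its
    sample SD, the limits of agreement ``bias +/- 1.96 * sddiff``.  If either
    vector has zero variance the correlation is undefined and reported as
    missing with a reason.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("paired agreement requires n >= 3")
    d = y - x
    bias = float(d.mean())
    sddiff = float(d.std(ddof=1))
    loa = (bias - 1.96 * sddiff, bias + 1.96 * sddiff)
    if np.isclose(x.std(ddof=1), 0.0) or np.isclose(y.std(ddof=1), 0.0):
        return AgreementStats(n, bias, sddiff, loa, None, None,
                              note="r undefined: zero variance in one series")
    r = float(stats.pearsonr(x, y).statistic)
    return AgreementStats(n, bias, sddiff, loa, r, _fisher_ci(r, n))


def duplicate_agreement(table: pd.DataFrame) -> pd.DataFrame:
    """Per (analyte, assay) agreement between replicate 1 and replicate 2.

    Expects a long table containing ``replicate_index`` values 1 and 2 for
    the duplicated samples; pairs on (sample_id, analyte, assay).
    """
    dup = table[table["replicate_index"] == 2]
    rows = []
    for (analyte, assay), second in dup.groupby(["analyte", "assay"]):
        first = table[
            (table["analyte"] == analyte)
            & (table["assay"] == assay)
            & (table["replicate_index"] == 1)
            & table["sample_id"].isin(second["sample_id"])
        ]
        merged = first.merge(
            second[["sample_id", "value"]], on="sample_id", suffixes=("_1", "_2")
        )
        st = paired_agreement(merged["value_1"], merged["value_2"])
        rows.append(_stats_row(st, analyte=analyte, assay=assay))
    return pd.DataFrame(rows)


def _stats_row(st: AgreementStats, **keys) -> dict:
    row = dict(keys)
    row.update(
        n=st.n,
        bias=st.bias,
        sddiff=st.sddiff,
        loa_low=st.loa[0],
        loa_high=st.loa[1],
        pearson_r=st.pearson_r,
        r_ci_low=None if st.r_ci is None else st.r_ci[0],
        r_ci_high=None if st.r_ci is None else st.r_ci[1],
        note=st.note,
    )
    return row


def correlation_by_stratum(
    table: pd.DataFrame, assay_pair: tuple[str, str]
) -> pd.DataFrame:
    """Inter-assay agreement per analyte for strata all / cases / controls.

    Pairs first-replicate values of the two assays on shared sample_ids.
    Strata with fewer than 3 pairs are skipped with a warning.
    """
    a1, a2 = assay_pair
    rows = []
    first = table[table["replicate_index"].fillna(1) == 1]
    for analyte, grp in first.groupby("analyte"):
        w1 = grp[grp["assay"] == a1][["sample_id", "status", "value"]]
        w2 = grp[grp["assay"] == a2][["sample_id", "value"]]
        merged = w1.merge(w2, on="sample_id", suffixes=("_1", "_2"))
        for stratum in ("all", "cases", "controls"):
            if stratum == "cases":
                sel = merged[merged["status"] == "case"]
            elif stratum == "controls":
                sel = merged[merged["status"] == "control"]
            else:
                sel = merged
            if len(sel) < 3:
                warnings.warn(
                    f"stratum {stratum!r} for {analyte} ({a1} vs {a2}) has "
                    f"{len(sel)} pairs; skipped"
                )
                continue
            st = paired_agreement(sel["value_1"], sel["value_2"])
            rows.append(
                _stats_row(st, analyte=analyte, assay1=a1, assay2=a2, stratum=stratum)
            )
    return pd.DataFrame(rows)
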