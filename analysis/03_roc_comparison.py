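"""Diagnostic accuracy: paired ROC/AUC comparison between assay platforms.

For each autoantibody and each pair of assays measured on the same samples,
computes both AUCs, their difference with a DeLong 95% CI, and DeLong's
paired test p-value, plus a Welch t-test comparing patient and control
levels per (analyte, assay).
"""

import argparse
from pathlib import Path

import pandas as pd

from isletcal.roc import delong_paired_test, welch_t_test


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--input", type=Path, default=Path("results/cohort.csv"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = pd.read_csv(args.input)
    first = table[table["replicate_index"].fillna(1) == 1]
    args.outdir.mkdir(parents=True, exist_ok=True)

    assays = list(pd.unique(first["assay"]))
    rows, welch_rows = [], []
    for analyte, grp in first.groupby("analyte"):
        for _, sub in grp.groupby("assay"):
            t, df, p = welch_t_test(
                sub.loc[sub["status"] == "case", "value"],
                sub.loc[sub["status"] == "control", "value"],
            )
            welch_rows.append(
                {"analyte": analyte, "assay": sub["assay"].iloc[0], "t": t, "df": df, "p": p}
            )
        for i in range(len(assays)):
            for j in range(i + 1, len(assays)):
                w1 = grp[grp["assay"] == assays[i]][["sample_id", "status", "value"]]
                w2 = grp[grp["assay"] == assays[j]][["sample_id", "value"]]
                merged = w1.merge(w2, on="sample_id", suffixes=("_1", "_2"))
                cmp = delong_paired_test(
                    merged["value_1"].to_numpy(),
                    merged["value_2"].to_numpy(),
                    (merged["status"] == "case").to_numpy(),
                    assay1=assays[i],
                    assay2=assays[j],
                )
                rows.append(
                    {
                        "analyte": analyte,
                        "assay1": cmp.assay1,
                        "assay2": cmp.assay2,
                        "n": cmp.n,
                        "auc1": cmp.auc1,
                        "auc2": cmp.auc2,
                        "auc_diff": cmp.auc_diff,
                        "diff_ci_low": cmp.diff_ci[0],
                        "diff_ci_high": cmp.diff_ci[1],
                        "p_value": cmp.p_value,
                    }
                )
    out = pd.DataFrame(rows)
    out.to_csv(args.outdir / "roc_comparisons.csv", index=False)
    pd.DataFrame(welch_rows).to_csv(args.outdir / "welch_tests.csv", index=False)
    print("paired AUC comparisons:")
    print(out.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
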