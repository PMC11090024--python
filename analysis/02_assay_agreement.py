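"""Replicate and inter-assay agreement.

Quantifies intra-assay agreement on the duplicated patient samples (bias,
sddiff, Bland-Altman limits, Pearson r) and inter-assay correlation for each
platform pair, split by stratum (all / patients / controls).  Patients
correlate strongly across platforms because true antibody level drives both
readouts; controls sit at the assay floor and correlate weakly.
"""

import argparse
from pathlib import Path

import pandas as pd

from isletcal.agreement import correlation_by_stratum, duplicate_agreement


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--input", type=Path, default=Path("results/cohort.csv"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = pd.read_csv(args.input)
    args.outdir.mkdir(parents=True, exist_ok=True)

    dup = duplicate_agreement(table)
    dup.to_csv(args.outdir / "agreement_duplicates.csv", index=False)
    print("intra-assay duplicate agreement (per analyte, assay):")
    print(dup[["analyte", "assay", "n", "bias", "sddiff", "pearson_r"]].round(3).to_string(index=False))

    assays = list(pd.unique(table["assay"]))
    frames = []
    for i in range(len(assays)):
        for j in range(i + 1, len(assays)):
            frames.append(correlation_by_stratum(table, (assays[i], assays[j])))
    inter = pd.concat(frames, ignore_index=True)
    inter.to_csv(args.outdir / "agreement_inter_assay.csv", index=False)
    pivot = inter.pivot_table(index=["analyte", "assay1", "assay2"], columns="stratum",
                              values="pearson_r")
    print("\ninter-assay Pearson r by stratum:")
    print(pivot.round(3).to_string())


if __name__ == "__main__":
    main()
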