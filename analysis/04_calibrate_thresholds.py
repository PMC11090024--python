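"""Cross-validated positivity thresholds (chisq and Spec98).

Runs 100 balanced 10-fold cross-validations per (analyte, assay), fits the
chi-square-optimal and the 98%-training-specificity cutpoints on the
training folds, evaluates sensitivity/specificity on the held-out folds,
and writes the mean / 95% percentile-interval summary over the 1000 fold
evaluations (the layout of a threshold-calibration table).
"""

import argparse
from pathlib import Path

import pandas as pd

from isletcal.thresholds import cross_validate_thresholds, summarize_cv


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--input", type=Path, default=Path("results/cohort.csv"))
    parser.add_argument("--method", choices=["chisq", "spec98", "both"], default="both")
    parser.add_argument("--repeats", type=int, default=100)
    parser.add_argument("--folds", type=int, default=10)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--controls", choices=["all", "PBC"], default="all")
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--write-folds", action="store_true",
                        help="also write the per-fold results")
    args = parser.parse_args()

    table = pd.read_csv(args.input)
    if args.controls == "PBC":
        table = table[(table["status"] == "case") | (table["subgroup"] == "PBC")]
    methods = ["chisq", "spec98"] if args.method == "both" else [args.method]

    folds, summaries = [], []
    for method in methods:
        res = cross_validate_thresholds(
            table, method, n_repeats=args.repeats, k=args.folds, seed=args.seed
        )
        folds.append(res)
        summaries.append(summarize_cv(res))
    summary = pd.concat(summaries, ignore_index=True)

    args.outdir.mkdir(parents=True, exist_ok=True)
    tag = "" if args.controls == "all" else "_pbc"
    summary.to_csv(args.outdir / f"thresholds_summary{tag}.csv", index=False)
    if args.write_folds:
        pd.concat(folds, ignore_index=True).to_csv(
            args.outdir / f"thresholds_folds{tag}.csv", index=False
        )

    show = summary[
        ["analyte", "assay", "method", "threshold_mean", "threshold_ci_low",
         "threshold_ci_high", "sensitivity_mean", "sensitivity_ci_low",
         "sensitivity_ci_high", "specificity_mean", "specificity_ci_low",
         "specificity_ci_high"]
    ]
    print(f"threshold calibration vs {args.controls} controls "
          f"({args.repeats} x {args.folds}-fold CV):")
    print(show.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
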