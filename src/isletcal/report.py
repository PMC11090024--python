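"""End-to-end pipeline orchestration.

One run configuration drives simulate (or load) -> preprocess -> agreement
-> ROC comparison -> threshold calibration -> staging, and writes the
summary tables as CSV together with a machine-readable manifest of every
seed and decision, sufficient to reproduce each number in the bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import agreement, preprocess, roc, staging, thresholds
from .synthetic_data import CohortConfig, config_from_yaml, simulate_cohort, simulate_duplicates, write_table

#: Historical fixed cutoffs on the original unit scales; carried as metadata
#: only (the pipeline always recalibrates thresholds by cross-validation).
LEGACY_CUTOFFS = {
    "GADA": "34 U/mL (WHO units)",
    "IA-2A": "5 U/mL (WHO units)",
    "IAA": "0.79 relative units (in-house)",
}


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one of ``cohort`` (synthetic generator config) or ``input_path``
    (measurement CSV) must be set.
    """

    cohort: CohortConfig | None = None
    input_path: str | None = None
    n_repeats: int = 100
    k_folds: int = 10
    seed: int = 0
    methods: tuple[str, ...] = ("chisq", "spec98")
    control_set: str = "all"
    staging_assays: tuple[str, ...] | None = None
    roc_comparisons: tuple[tuple[str, str], ...] | None = None
    n_duplicates: int = 200
    spec_level: float = 0.98
    legacy_cutoffs: dict = field(default_factory=lambda: dict(LEGACY_CUTOFFS))

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_path is None):
            raise ValueError("exactly one of cohort config or input_path must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cohort = raw.pop("cohort", None)
        if cohort is not None:
            for key in ("analytes", "assays"):
                if key in cohort:
                    cohort[key] = tuple(cohort[key])
            cohort = CohortConfig(**cohort)
        for key in ("methods", "staging_assays"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        if raw.get("roc_comparisons") is not None:
            raw["roc_comparisons"] = tuple(tuple(p) for p in raw["roc_comparisons"])
        return cls(cohort=cohort, **raw)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # propagate with the failing stage named
            raise PipelineError(f"stage {name}: {exc}") from exc

    return wrap


def _default_pairs(assays) -> tuple[tuple[str, str], ...]:
    return tuple(
        (assays[i], assays[j]) for i in range(len(assays)) for j in range(i + 1, len(assays))
    )


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every analysis stage and write the report bundle under ``outdir``.

    Returns the in-memory tables: agreement_duplicates, agreement_inter_assay,
    roc_comparisons, thresholds_folds, thresholds_summary, staging_summary,
    staging_subgroups, plus the manifest dict.  Deterministic given the
    seeds in ``config``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    if config.cohort is not None:
        table = _stage("simulate")(simulate_cohort, config.cohort)
        dup = None
        if config.n_duplicates:
            n_avail = table.loc[table["status"] == "case", "sample_id"].nunique()
            dup = _stage("simulate")(
                simulate_duplicates, table, min(config.n_duplicates, n_avail), config.cohort
            )
            table = pd.concat([table, dup], ignore_index=True)
        write_table(table, outdir / "measurements.csv")
        report = None
    else:
        table, report = _stage("preprocess")(preprocess.load_measurements, config.input_path)
        report.to_csv(outdir / "preprocess_report.csv", index=False)
    bundle["measurements"] = table

    assays = tuple(pd.unique(table["assay"]))
    analytes = tuple(pd.unique(table["analyte"]))

    if (table["replicate_index"] == 2).any():
        bundle["agreement_duplicates"] = _stage("agreement")(
            agreement.duplicate_agreement, table
        )
        bundle["agreement_duplicates"].to_csv(outdir / "agreement_duplicates.csv", index=False)
    pairs = config.roc_comparisons or _default_pairs(assays)
    if pairs:  # pairwise stages need at least two assays
        inter = [
            _stage("agreement")(agreement.correlation_by_stratum, table, pair)
            for pair in pairs
        ]
        bundle["agreement_inter_assay"] = pd.concat(inter, ignore_index=True)
        bundle["agreement_inter_assay"].to_csv(
            outdir / "agreement_inter_assay.csv", index=False
        )

    first = table[table["replicate_index"].fillna(1) == 1]
    roc_rows = []
    for analyte in analytes if pairs else []:
        grp = first[first["analyte"] == analyte]
        for a1, a2 in pairs:
            w1 = grp[grp["assay"] == a1][["sample_id", "status", "value"]]
            w2 = grp[grp["assay"] == a2][["sample_id", "value"]]
            merged = w1.merge(w2, on="sample_id", suffixes=("_1", "_2"))
            cmp = _stage("roc")(
                roc.delong_paired_test,
                merged["value_1"].to_numpy(),
                merged["value_2"].to_numpy(),
                (merged["status"] == "case").to_numpy(),
                assay1=a1,
                assay2=a2,
            )
            roc_rows.append(
                {
                    "analyte": analyte,
                    "assay1": a1,
                    "assay2": a2,
                    "n": cmp.n,
                    "auc1": cmp.auc1,
                    "auc2": cmp.auc2,
                    "auc_diff": cmp.auc_diff,
                    "diff_ci_low": cmp.diff_ci[0],
                    "diff_ci_high": cmp.diff_ci[1],
                    "p_value": cmp.p_value,
                }
            )
    if pairs:
        bundle["roc_comparisons"] = pd.DataFrame(roc_rows)
        bundle["roc_comparisons"].to_csv(outdir / "roc_comparisons.csv", index=False)

    cv_table = first
    if config.control_set == "PBC":
        cv_table = first[(first["status"] == "case") | (first["subgroup"] == "PBC")]
    folds, summaries = [], []
    for method in config.methods:
        res = _stage("thresholds")(
            thresholds.cross_validate_thresholds,
            cv_table,
            method,
            config.n_repeats,
            config.k_folds,
            config.seed,
            level=config.spec_level,
        )
        folds.append(res)
        summaries.append(thresholds.summarize_cv(res))
    bundle["thresholds_folds"] = pd.concat(folds, ignore_index=True)
    bundle["thresholds_summary"] = pd.concat(summaries, ignore_index=True)
    bundle["thresholds_folds"].to_csv(outdir / "thresholds_folds.csv", index=False)
    bundle["thresholds_summary"].to_csv(outdir / "thresholds_summary.csv", index=False)

    staging_summaries, staging_subgroups = [], []
    for assay in config.staging_assays or assays:
        for method in config.methods:
            res = _stage("staging")(
                staging.staging_cv,
                table,
                assay,
                method,
                config.n_repeats,
                config.k_folds,
                config.seed,
                control_set=config.control_set,
                level=config.spec_level,
            )
            staging_summaries.append(res.summary)
            sub = res.subgroup_proportions.copy()
            sub.insert(0, "assay", assay)
            sub.insert(1, "method", method)
            staging_subgroups.append(sub)
    bundle["staging_summary"] = pd.concat(staging_summaries, ignore_index=True)
    bundle["staging_subgroups"] = pd.concat(staging_subgroups, ignore_index=True)
    bundle["staging_summary"].to_csv(outdir / "staging_summary.csv", index=False)
    bundle["staging_subgroups"].to_csv(outdir / "staging_subgroups.csv", index=False)

    manifest = {
        "seed": config.seed,
        "cohort_seed": None if config.cohort is None else config.cohort.seed,
        "input_path": config.input_path,
        "n_repeats": config.n_repeats,
        "k_folds": config.k_folds,
        "methods": list(config.methods),
        "control_set": config.control_set,
        "spec_level": config.spec_level,
        "n_duplicates": config.n_duplicates,
        "positivity_rule": "value >= threshold",
        "ci_method": "empirical 2.5/97.5 percentiles over held-out folds",
        "chisq_tie_break": "largest threshold (favors specificity)",
        "legacy_cutoffs_metadata_only": config.legacy_cutoffs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle
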