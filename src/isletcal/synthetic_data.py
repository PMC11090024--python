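"""Synthetic islet-autoantibody cohort generator.

Emulates the measurement structure of a childhood type 1 diabetes screening
study: four autoantibody markers (GADA, IA-2A, IAA, ZnT8A) measured on each
sample by one radiobinding assay (RBA) and two automated agglutination-PCR
(ADAP) platforms, in newly diagnosed patients and three control groups
(population-based PBC, doctor's-office DOC and blood-donor BDC).

All values are generated directly on the analysis scale (log2-unit-like for
RBA, dCt-like for ADAP), oriented so that larger always means more antibody.
Each sample carries a latent per-analyte positivity flag; positives for an
analyte share a standard-normal latent trait across assays (so paired assays
correlate strongly, Pearson r = ``cross_assay_correlation``), while
autoantibody-negative samples draw independent assay noise from the control
distribution (so paired assays are essentially uncorrelated among negatives,
as observed for real control sera).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

CONTROL_GROUPS = ("PBC", "DOC", "BDC")
DEFAULT_ANALYTES = ("GADA", "IA-2A", "IAA", "ZnT8A")
DEFAULT_ASSAYS = ("RBA", "ADAP_CRC", "ADAP_Enable")

#: Column order of a measurement table (truth_positive only in synthetic data).
TABLE_COLUMNS = (
    "sample_id",
    "status",
    "subgroup",
    "specimen",
    "analyte",
    "assay",
    "replicate_index",
    "value",
    "truth_positive",
)


class ConfigError(ValueError):
    """Raised for an invalid :class:`CohortConfig`, naming the offending field."""


def _param(spec, analyte: str, assay: str | None = None, *, field_name: str = "") -> float:
    """Resolve a scalar-or-nested parameter to a float for (analyte[, assay]).

    Accepts a plain number (applies everywhere), a mapping keyed by analyte,
    or a mapping of analyte -> mapping keyed by assay.
    """
    value = spec
    if isinstance(value, Mapping):
        if analyte not in value:
            raise ConfigError(f"{field_name}: no entry for analyte {analyte!r}")
        value = value[analyte]
    if isinstance(value, Mapping):
        if assay is None or assay not in value:
            raise ConfigError(f"{field_name}: no entry for assay {assay!r} (analyte {analyte!r})")
        value = value[assay]
    return float(value)


@dataclass(frozen=True)
class CohortConfig:
    """Ground-truth parameters of a simulated case/control cohort.

    Level parameters (``control_mean`` etc.) may be scalars, per-analyte
    mappings or per-(analyte, assay) nested mappings; they live on the
    transformed analysis scale.  Defaults mirror the study cohort sizes
    (2300 patients; 1504/456/535 controls) and are order-of-magnitude
    plausible for well-behaved serology markers.
    """

    n_cases: int = 2300
    n_controls_by_group: Mapping[str, int] = field(
        default_factory=lambda: {"PBC": 1504, "DOC": 456, "BDC": 535}
    )
    analytes: tuple[str, ...] = DEFAULT_ANALYTES
    assays: tuple[str, ...] = DEFAULT_ASSAYS
    positive_fraction: Mapping[str, float] | float = field(
        default_factory=lambda: {"GADA": 0.90, "IA-2A": 0.80, "IAA": 0.75, "ZnT8A": 0.70}
    )
    background_positive_fraction: float = 0.01
    control_mean: object = 0.0
    control_sd: object = 1.0
    positive_mean: object = 4.0
    positive_sd: object = 1.5
    cross_assay_correlation: float = 0.8
    subgroup_shift: Mapping[str, float] = field(
        default_factory=lambda: {"PBC": -0.5, "DOC": 0.0, "BDC": 0.0}
    )
    replicate_bias: object = 0.05
    replicate_sddiff: object = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_cases) < 0:
            raise ConfigError("n_cases: must be >= 0")
        for group, n in self.n_controls_by_group.items():
            if group not in CONTROL_GROUPS:
                raise ConfigError(f"n_controls_by_group: unknown group {group!r}")
            if int(n) < 0:
                raise ConfigError(f"n_controls_by_group[{group!r}]: must be >= 0")
        if not self.analytes:
            raise ConfigError("analytes: must be non-empty")
        if not self.assays:
            raise ConfigError("assays: must be non-empty")
        if not 0.0 <= float(self.background_positive_fraction) <= 1.0:
            raise ConfigError("background_positive_fraction: must be in [0, 1]")
        if not 0.0 <= float(self.cross_assay_correlation) < 1.0:
            raise ConfigError("cross_assay_correlation: must be in [0, 1)")
        for analyte in self.analytes:
            p = _param(self.positive_fraction, analyte, field_name="positive_fraction")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"positive_fraction[{analyte!r}]: must be in [0, 1]")
            for assay in self.assays:
                mu_c = _param(self.control_mean, analyte, assay, field_name="control_mean")
                mu_p = _param(self.positive_mean, analyte, assay, field_name="positive_mean")
                sd_c = _param(self.control_sd, analyte, assay, field_name="control_sd")
                sd_p = _param(self.positive_sd, analyte, assay, field_name="positive_sd")
                if sd_c <= 0:
                    raise ConfigError(f"control_sd[{analyte!r}][{assay!r}]: must be > 0")
                if sd_p <= 0:
                    raise ConfigError(f"positive_sd[{analyte!r}][{assay!r}]: must be > 0")
                if not mu_p > mu_c:
                    raise ConfigError(
                        f"positive_mean[{analyte!r}][{assay!r}]: must exceed control_mean "
                        "(larger transformed value = more antibody)"
                    )
                if _param(self.replicate_sddiff, analyte, assay, field_name="replicate_sddiff") < 0:
                    raise ConfigError(f"replicate_sddiff[{analyte!r}][{assay!r}]: must be >= 0")
        for group in self.subgroup_shift:
            if group not in CONTROL_GROUPS:
                raise ConfigError(f"subgroup_shift: unknown group {group!r}")


def _sample_frame(config: CohortConfig) -> pd.DataFrame:
    ids, status, subgroup, specimen = [], [], [], []
    for i in range(int(config.n_cases)):
        ids.append(f"BDD{i + 1:05d}")
        status.append("case")
        subgroup.append("patient")
        specimen.append("serum")
    for group in CONTROL_GROUPS:
        n = int(config.n_controls_by_group.get(group, 0))
        # PBC samples are EDTA plasma in the study design; carried as metadata only.
        spec_type = "plasma" if group == "PBC" else "serum"
        for i in range(n):
            ids.append(f"{group}{i + 1:05d}")
            status.append("control")
            subgroup.append(group)
            specimen.append(spec_type)
    return pd.DataFrame(
        {
            "sample_id": ids,
            "status": status,
            "subgroup": subgroup,
            "specimen": specimen,
        }
    )


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a long-format measurement table for every (sample, analyte, assay).

    Per analyte a latent positivity flag is drawn (cases with the analyte's
    ``positive_fraction``, controls with ``background_positive_fraction``).
    Positive values are ``positive_mean + positive_sd * (sqrt(rho)*T +
    sqrt(1-rho)*e)`` with trait ``T`` shared across assays; negative values
    are independent draws from the control distribution.  Control-subgroup
    offsets are added to all measurements of the sample.  Deterministic for
    a given ``config.seed``.
    """
    samples = _sample_frame(config)
    n = len(samples)
    rng = np.random.default_rng([1, int(config.seed)])
    is_case = (samples["status"] == "case").to_numpy()
    shift = samples["subgroup"].map(
        lambda g: float(config.subgroup_shift.get(g, 0.0)) if g != "patient" else 0.0
    ).to_numpy()
    rho = float(config.cross_assay_correlation)

    frames = []
    for analyte in config.analytes:
        p = _param(config.positive_fraction, analyte, field_name="positive_fraction")
        p_pos = np.where(is_case, p, float(config.background_positive_fraction))
        flag = rng.random(n) < p_pos
        trait = rng.standard_normal(n)
        for assay in config.assays:
            noise = rng.standard_normal(n)
            mu_c = _param(config.control_mean, analyte, assay, field_name="control_mean")
            sd_c = _param(config.control_sd, analyte, assay, field_name="control_sd")
            mu_p = _param(config.positive_mean, analyte, assay, field_name="positive_mean")
            sd_p = _param(config.positive_sd, analyte, assay, field_name="positive_sd")
            shared = math.sqrt(rho) * trait + math.sqrt(1.0 - rho) * noise
            value = np.where(flag, mu_p + sd_p * shared, mu_c + sd_c * noise) + shift
            frame = samples.copy()
            frame["analyte"] = analyte
            frame["assay"] = assay
            frame["replicate_index"] = 1
            frame["value"] = value
            frame["truth_positive"] = flag
            frames.append(frame)
    table = pd.concat(frames, ignore_index=True)[list(TABLE_COLUMNS)]
    return table


def simulate_duplicates(
    table: pd.DataFrame, n_samples: int, config: CohortConfig
) -> pd.DataFrame:
    """Second-replicate rows for ``n_samples`` randomly chosen cases.

    The replicate value is ``value + replicate_bias + Normal(0, replicate_sddiff)``,
    mimicking samples re-run at different plate positions.  Returns only the
    new rows (``replicate_index == 2``); concatenate with ``table`` if a
    combined table is wanted.
    """
    case_ids = np.sort(table.loc[table["status"] == "case", "sample_id"].unique())
    if n_samples > len(case_ids):
        raise ValueError(
            f"n_samples={n_samples} exceeds the {len(case_ids)} available case samples"
        )
    rng = np.random.default_rng([2, int(config.seed)])
    chosen = rng.choice(case_ids, size=int(n_samples), replace=False)
    first = table[
        table["sample_id"].isin(chosen) & (table["replicate_index"] == 1)
    ].copy()
    bias = np.array(
        [
            _param(config.replicate_bias, a, b, field_name="replicate_bias")
            for a, b in zip(first["analyte"], first["assay"])
        ]
    )
    sddiff = np.array(
        [
            _param(config.replicate_sddiff, a, b, field_name="replicate_sddiff")
            for a, b in zip(first["analyte"], first["assay"])
        ]
    )
    first["value"] = first["value"].to_numpy() + bias + rng.standard_normal(len(first)) * sddiff
    first["replicate_index"] = 2
    return first.reset_index(drop=True)


def write_table(table: pd.DataFrame, path) -> None:
    """Write a measurement table as CSV with the canonical column order."""
    cols = [c for c in TABLE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def config_from_yaml(path) -> CohortConfig:
    """Load a :class:`CohortConfig` from a YAML mapping; ``seed`` is required."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError("config file: expected a YAML mapping")
    if "seed" not in raw:
        raise ConfigError("seed: required in cohort config")
    kwargs = dict(raw)
    if "analytes" in kwargs:
        kwargs["analytes"] = tuple(kwargs["analytes"])
    if "assays" in kwargs:
        kwargs["assays"] = tuple(kwargs["assays"])
    return CohortConfig(**kwargs)
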