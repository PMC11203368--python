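"""Run configuration and sample sheet validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields as dc_fields
import pandas as pd
import yaml

from .arms import DEFAULT_EXCLUDED_ARMS

#: closed vocabulary of sample-sheet group labels
GROUP_LABELS = ("HBD", "TN-blood", "tissue", "preR", "preS", "postR", "postS")


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline with their defaults.

    Defaults follow the study's analysis settings: GWZ threshold 5, mapping
    quality 15, DMR FDR 0.05, 75% missingness cutoff, 1 kb TSS half-window,
    the (<0.45, [0.55, 0.70]) VAF window with >= 10 alt reads, kappa cutoff
    0.3 and a 5% signature-presence fraction.
    """

    seed: int = 0
    gwz_threshold: float = 5.0
    min_mapq: int = 15
    exclude_arms: tuple[str, ...] = DEFAULT_EXCLUDED_ARMS
    alpha: float = 0.05
    max_missing_frac: float = 0.75
    window_halfwidth: int = 1000
    vaf_low_max: float = 0.45
    vaf_high: tuple[float, float] = (0.55, 0.70)
    min_alt_reads: int = 10
    kappa_threshold: float = 0.3
    presence_min_fraction: float = 0.05
    # synthetic-cohort settings (the study conditions of a simulated run)
    sim_tumor_fraction: float = 0.2
    sim_n_regions: int = 2000
    sim_dmr_frac: float = 0.1
    sim_effect_log2fc: float = 1.0
    sim_dispersion: float = 0.1
    sim_depth_arm: int = 100_000
    sim_depth_variants: int = 200
    sim_n_somatic: int = 2000
    sim_n_germline: int = 500
    sim_log_hr: float = 0.6931471805599453  # log 2
    out_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        checks = [
            (self.gwz_threshold > 0, "gwz_threshold must be > 0"),
            (self.min_mapq >= 0, "min_mapq must be >= 0"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (0 <= self.max_missing_frac <= 1, "max_missing_frac in [0, 1]"),
            (self.window_halfwidth > 0, "window_halfwidth must be > 0"),
            (0 < self.vaf_low_max < 1, "vaf_low_max in (0, 1)"),
            (0 < self.vaf_high[0] <= self.vaf_high[1] <= 1,
             "vaf_high must be an ordered window in (0, 1]"),
            (self.min_alt_reads >= 0, "min_alt_reads must be >= 0"),
            (0 <= self.kappa_threshold <= 1, "kappa_threshold in [0, 1]"),
            (0 <= self.presence_min_fraction <= 1,
             "presence_min_fraction in [0, 1]"),
            (0 <= self.sim_tumor_fraction <= 1, "sim_tumor_fraction in [0, 1]"),
            (0 <= self.sim_dmr_frac <= 1, "sim_dmr_frac in [0, 1]"),
            (self.sim_dispersion >= 0, "sim_dispersion must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)
        self.exclude_arms = tuple(self.exclude_arms)
        self.vaf_high = tuple(self.vaf_high)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable short hash identifying the parameter set.

        The output directory is excluded: where results land does not change
        what they are.
        """
        params = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, subject_id, group, and optional timepoint,
    ttf_time, ttf_event, tumor_fraction columns.

    Group labels come from the closed vocabulary; the resistant/sensitive
    dichotomy (progression within six months of starting PARPi) is carried in
    the sheet, never computed, and tumor fractions are externally estimated
    numbers used only for reporting.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sample_id", "subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    bad = set(df["group"]) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"{path}: unknown group label(s) {sorted(bad)}")
    if "ttf_time" in df.columns:
        times = df["ttf_time"].dropna()
        if (times <= 0).any():
            raise ValueError(f"{path}: ttf_time must be positive")
    return df
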