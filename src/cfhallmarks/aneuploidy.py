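"""Genome-wide aneuploidy Z-score (GWZ) from per-chromosome-arm read counts.

Plasma cfDNA sequenced with an arm-level LINE-1 amplicon assay yields one read
count per chromosome arm.  Each sample's counts are normalized to arm
fractions; per arm, the fraction is studentized against a panel of healthy
diploid donors (subtract the panel mean, divide by the panel standard
deviation), and the squared z-scores are summed over arms into a single GWZ.
Samples at or above the threshold (default 5) are classified aneuploid, a
level associated with tumor fractions above ~10%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .arms import DEFAULT_EXCLUDED_ARMS

DEFAULT_MIN_MAPQ = 15
DEFAULT_GWZ_THRESHOLD = 5.0


@dataclass
class ArmCountProfile:
    """Per-arm read counts for one sample."""

    sample_id: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        bad = {a: c for a, c in self.counts.items() if c < 0}
        if bad:
            raise ValueError(f"negative arm counts: {bad}")
        if self.total <= 0:
            raise ValueError(f"sample {self.sample_id!r}: total arm count must be > 0")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def arm_set(self) -> frozenset[str]:
        return frozenset(self.counts)


@dataclass
class ReferencePanel:
    """Mean and standard deviation of normalized arm fractions over healthy donors."""

    arm_mean: dict[str, float]
    arm_sd: dict[str, float]
    n_ref: int
    arm_set: tuple[str, ...]


@dataclass
class GWZResult:
    sample_id: str
    arm_z: dict[str, float]
    gwz: float
    threshold: float
    aneuploid: bool = field(init=False)

    def __post_init__(self) -> None:
        self.aneuploid = self.gwz >= self.threshold


def filter_reads(
    records: Iterable[tuple[str, int]],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    exclude_arms: Sequence[str] = DEFAULT_EXCLUDED_ARMS,
    sample_id: str = "sample",
) -> ArmCountProfile:
    """Count reads per arm, discarding low-mapping-quality reads and excluded arms.

    ``records`` are (arm, mapq) pairs; a read is kept iff mapq >= ``min_mapq``
    (boundary inclusive) and its arm is not in ``exclude_arms``.
    """
    excluded = set(exclude_arms)
    counts: dict[str, int] = {}
    n_seen = 0
    for arm, mapq in records:
        n_seen += 1
        if mapq < min_mapq or arm in excluded:
            continue
        counts[arm] = counts.get(arm, 0) + 1
    if n_seen == 0:
        raise ValueError("no reads supplied")
    if not counts:
        raise ValueError("no usable reads after mapq/arm filtering")
    return ArmCountProfile(sample_id=sample_id, counts=counts)


def normalize_arm_counts(profile: ArmCountProfile) -> dict[str, float]:
    """Per-sample arm fractions of the total retained read count (sum to 1)."""
    total = profile.total
    if total <= 0:
        raise ValueError("zero total read count")
    return {arm: c / total for arm, c in profile.counts.items()}


def build_panel(profiles: Sequence[ArmCountProfile]) -> ReferencePanel:
    """Build a healthy-donor reference panel of per-arm fraction means and SDs.

    SDs use the n-1 denominator (panels are small, typically under ten donors).
    A degenerate arm with zero spread makes studentization undefined and is an
    error rather than a silent infinity.
    """
    if len(profiles) < 2:
        raise ValueError("reference panel needs at least 2 profiles")
    arm_sets = {p.arm_set for p in profiles}
    if len(arm_sets) != 1:
        raise ValueError("panel profiles have differing arm sets")
    arm_set = tuple(sorted(arm_sets.pop()))
    fractions = np.array(
        [[normalize_arm_counts(p)[a] for a in arm_set] for p in profiles]
    )
    mean = fractions.mean(axis=0)
    sd = fractions.std(axis=0, ddof=1)
    degenerate = [a for a, s in zip(arm_set, sd) if s == 0]
    if degenerate:
        raise ValueError(f"zero panel standard deviation for arm(s): {degenerate}")
    return ReferencePanel(
        arm_mean=dict(zip(arm_set, mean.tolist())),
        arm_sd=dict(zip(arm_set, sd.tolist())),
        n_ref=len(profiles),
        arm_set=arm_set,
    )


def gwz_score(
    profile: ArmCountProfile,
    panel: ReferencePanel,
    threshold: float = DEFAULT_GWZ_THRESHOLD,
) -> GWZResult:
    """Score one sample against the panel: z per arm, GWZ = sum of squared z.

    Classification is inclusive at the threshold (GWZ >= threshold is aneuploid).
    """
    profile_arms = profile.arm_set
    panel_arms = frozenset(panel.arm_set)
    if profile_arms != panel_arms:
        missing = sorted(panel_arms - profile_arms)
        extra = sorted(profile_arms - panel_arms)
        raise ValueError(
            f"arm set mismatch with panel: missing={missing} extra={extra}"
        )
    fractions = normalize_arm_counts(profile)
    arm_z = {
        a: (fractions[a] - panel.arm_mean[a]) / panel.arm_sd[a]
        for a in panel.arm_set
    }
    gwz = math.fsum(z * z for z in arm_z.values())
    return GWZResult(
        sample_id=profile.sample_id, arm_z=arm_z, gwz=gwz, threshold=threshold
    )


def gwz_table(
    profiles: Sequence[ArmCountProfile],
    panel: ReferencePanel,
    threshold: float = DEFAULT_GWZ_THRESHOLD,
):
    """Score many samples; returns a pandas DataFrame (sample, gwz, aneuploid, z_<arm>...)."""
    import pandas as pd

    rows = []
    for p in profiles:
        res = gwz_score(p, panel, threshold=threshold)
        row = {"sample": res.sample_id, "gwz": res.gwz, "aneuploid": res.aneuploid}
        row.update({f"z_{a}": z for a, z in res.arm_z.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def expected_null_gwz(n_arms: int, panel_size: int) -> float:
    """Expected GWZ of a healthy sample scored against a size-m panel.

    Each studentized deviate (x - xbar_m)/s_m is t-distributed up to the
    sqrt(1 + 1/m) spread factor, so its square has expectation
    (1 + 1/m) * (m-1)/(m-3); arms add linearly.
    """
    m = panel_size
    if m <= 3:
        raise ValueError("expectation undefined for panel size <= 3")
    return n_arms * (1 + 1 / m) * (m - 1) / (m - 3)
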