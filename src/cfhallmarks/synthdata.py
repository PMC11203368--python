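"""Synthetic cohort generator with known ground truth.

The patient data behind this workflow are not publicly deposited, so every
downstream stage is exercised on simulated inputs that emulate the study's
measurements: per-chromosome-arm read-count profiles of healthy and
tumor-bearing plasma at a chosen tumor fraction, TSS-window methylation count
matrices with negative-binomial noise and planted hyper-/hypomethylated
regions per subject group, somatic-plus-germline variant tables with
trinucleotide spectra drawn from a signature mixture, and exponential
time-to-treatment-failure outcomes linked to a covariate.  Every generator
records the planted parameters in a :class:`SimTruth` so recovery tests can
assert against the truth, and is bit-reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arms import DEFAULT_ARM_SET, baseline_arm_fractions
from .aneuploidy import ArmCountProfile
from .medseq import RegionCountMatrix
from .signatures import VARIANT_COLUMNS

#: subject groups of the cohort design
GROUPS = ("HBD", "TN-blood", "tissue", "preR", "preS", "postR", "postS")


@dataclass
class SimTruth:
    """Planted parameters of a simulation: what the pipeline should recover."""

    tumor_fraction: float = 0.0
    arm_cn_profile: dict[str, int] = field(default_factory=dict)
    dmr_truth: dict[str, tuple[str, float]] = field(default_factory=dict)
    dmr_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    dispersion: float = 0.1
    signature_weights: dict[str, float] = field(default_factory=dict)
    log_hazard_ratio: float = 0.0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.signature_weights:
            total = sum(self.signature_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"signature weights sum to {total}, expected 1"
                )

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# arm read counts


def case_arm_fractions(
    baseline: Mapping[str, float], cn_profile: Mapping[str, int], tf: float
) -> dict[str, float]:
    """Expected arm fractions of a tumor-bearing sample.

    Each arm's baseline weight is scaled by (1 - tf) + tf * CN / 2 (a diploid
    arm has CN 2 and scale 1) and the vector is renormalized.
    """
    unknown = set(cn_profile) - set(baseline)
    if unknown:
        raise ValueError(f"unknown arm(s) in cn_profile: {sorted(unknown)}")
    scaled = {
        a: f * ((1 - tf) + tf * cn_profile.get(a, 2) / 2)
        for a, f in baseline.items()
    }
    total = sum(scaled.values())
    return {a: v / total for a, v in scaled.items()}


def gen_arm_counts(
    panel_size: int,
    n_cases: int,
    truth: SimTruth,
    depth: int = 100_000,
    arm_set: Sequence[str] = DEFAULT_ARM_SET,
) -> tuple[list[ArmCountProfile], list[ArmCountProfile], SimTruth]:
    """Simulate healthy-panel and case arm-count profiles.

    Healthy samples are multinomial draws of ``depth`` reads over the
    length-proportional baseline arm fractions; case samples use the baseline
    perturbed by the planted copy-number profile at the planted tumor
    fraction.  Returns (panel profiles, case profiles, truth).
    """
    if depth < 1000:
        raise ValueError("depth must be >= 1000")
    rng = np.random.default_rng(truth.seed)
    arm_set = tuple(arm_set)
    baseline = baseline_arm_fractions(arm_set)
    case_frac = case_arm_fractions(baseline, truth.arm_cn_profile,
                                   truth.tumor_fraction)
    base_p = np.array([baseline[a] for a in arm_set])
    case_p = np.array([case_frac[a] for a in arm_set])
    panel = [
        ArmCountProfile(
            sample_id=f"HBD{i + 1}",
            counts=dict(zip(arm_set, rng.multinomial(depth, base_p).tolist())),
        )
        for i in range(panel_size)
    ]
    cases = [
        ArmCountProfile(
            sample_id=f"case{i + 1}",
            counts=dict(zip(arm_set, rng.multinomial(depth, case_p).tolist())),
        )
        for i in range(n_cases)
    ]
    return panel, cases, truth


# ---------------------------------------------------------------------------
# methylation counts


def gen_methyl_counts(
    n_regions: int,
    group_sizes: Mapping[str, int],
    dmr_frac: float,
    effect_log2fc: float,
    truth: SimTruth,
    mean_log_mu: float = 4.5,
    sd_log_mu: float = 1.0,
    effect_groups: Sequence[str] | None = None,
    group_effect_probability: float = 1.0,
    hyper_fraction: float = 0.7,
    size_factor_range: tuple[float, float] = (0.7, 1.4),
) -> tuple[RegionCountMatrix, SimTruth]:
    """Simulate a TSS-window count matrix with planted DMRs.

    Counts are NB(mean_region * group effect * sample size factor, common
    dispersion).  A ``dmr_frac`` fraction of regions (deterministically
    ``round(dmr_frac * n_regions)`` of them) carries ``effect_log2fc`` in the
    designated groups; each designated group is affected independently with
    ``group_effect_probability`` (1.0 plants the effect everywhere), and a
    ``hyper_fraction`` of true DMRs is hypermethylated, the rest
    hypomethylated — cancer methylomes show both directions with a hyper
    excess at TSS windows.  Truth records every true DMR with its planted
    fold change and affected groups.
    """
    if not 0.0 <= dmr_frac <= 1.0:
        raise ValueError("dmr_frac must be in [0, 1]")
    for g, n in group_sizes.items():
        if n < 3:
            raise ValueError(f"group {g!r} needs >= 3 samples")
    if n_regions < 100:
        raise ValueError("need at least 100 regions")
    rng = np.random.default_rng(truth.seed)
    regions = [f"TSS{i:05d}" for i in range(n_regions)]
    samples, labels = [], {}
    for g, n in group_sizes.items():
        for i in range(n):
            sid = f"{g}_{i + 1}"
            samples.append(sid)
            labels[sid] = g
    if effect_groups is None:
        effect_groups = [g for g in group_sizes if g != "HBD"]

    mu = np.exp(rng.normal(mean_log_mu, sd_log_mu, size=n_regions))
    sf = rng.uniform(*size_factor_range, size=len(samples))

    n_dmr = int(round(dmr_frac * n_regions)) if effect_log2fc != 0 else 0
    dmr_idx = rng.choice(n_regions, size=n_dmr, replace=False) if n_dmr else []
    signs = np.where(rng.random(n_dmr) < hyper_fraction, 1.0, -1.0)

    log2fc_mat = np.zeros((n_regions, len(samples)))
    dmr_truth: dict[str, tuple[str, float]] = {}
    dmr_groups: dict[str, tuple[str, ...]] = {}
    for j, (idx, sign) in enumerate(zip(dmr_idx, signs)):
        affected = tuple(
            g for g in effect_groups
            if group_effect_probability >= 1.0
            or rng.random() < group_effect_probability
        )
        if not affected:
            continue
        lfc = sign * effect_log2fc
        region = regions[idx]
        dmr_truth[region] = ("+".join(affected) + " vs HBD", lfc)
        dmr_groups[region] = affected
        for k, s in enumerate(samples):
            if labels[s] in affected:
                log2fc_mat[idx, k] = lfc

    mean_mat = mu[:, None] * (2.0 ** log2fc_mat) * sf[None, :]
    disp = truth.dispersion
    if disp > 0:
        # NB as gamma-poisson: shape 1/disp, scale mu*disp
        counts = rng.poisson(rng.gamma(1.0 / disp, disp * mean_mat))
    else:
        counts = rng.poisson(mean_mat)
    truth.dmr_truth = dmr_truth
    truth.dmr_groups = dmr_groups
    truth.extra["planted_size_factors"] = dict(zip(samples, sf.tolist()))
    matrix = RegionCountMatrix(
        counts=pd.DataFrame(counts, index=regions, columns=samples),
        groups=pd.Series(labels),
        region_chrom={r: str((i % 22) + 1) for i, r in enumerate(regions)},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# variants


def _context_of_channel(channel: str) -> tuple[str, str, str]:
    """(ref, alt, context) of a pyrimidine-centered channel label."""
    five, ref, alt, three = channel[0], channel[2], channel[4], channel[6]
    return ref, alt, five + ref + three


def gen_variants(
    n_somatic: int,
    n_germline: int,
    truth: SimTruth,
    signatures: pd.DataFrame,
    depth: int = 200,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a variant table mixing somatic and germline-like SNVs.

    Somatic alt-read counts are Binomial(depth, tf/2) (heterozygous,
    copy-neutral); germline VAFs center on 0.5 (het) or 1.0 (hom, 30% of
    germline variants).  Somatic trinucleotide channels are drawn from the
    planted signature mixture; germline channels are uniform.  The returned
    table carries ``is_somatic`` and ``true_signature`` truth columns.
    """
    if signatures.shape[1] == 0:
        raise ValueError("empty signature catalog")
    unknown = set(truth.signature_weights) - set(signatures.columns)
    if unknown:
        raise ValueError(f"weights for unknown signature(s): {sorted(unknown)}")
    rng = np.random.default_rng(truth.seed)
    tf = truth.tumor_fraction
    sig_names = list(truth.signature_weights)
    weights = np.array([truth.signature_weights[s] for s in sig_names])
    channels = list(signatures.index)

    rows = []
    for i in range(n_somatic):
        sig = sig_names[rng.choice(len(sig_names), p=weights)]
        probs = signatures[sig].to_numpy()
        ch = channels[rng.choice(len(channels), p=probs / probs.sum())]
        ref, alt, context = _context_of_channel(ch)
        alt_reads = rng.binomial(depth, max(tf / 2, 1e-9))
        rows.append(
            {"chrom": str(rng.integers(1, 23)), "pos": int(rng.integers(1, 10**8)),
             "ref": ref, "alt": alt, "alt_reads": int(alt_reads), "depth": depth,
             "context": context, "is_somatic": True, "true_signature": sig,
             "true_channel": ch}
        )
    for i in range(n_germline):
        ch = channels[rng.integers(len(channels))]
        ref, alt, context = _context_of_channel(ch)
        vaf = 1.0 if rng.random() < 0.3 else 0.5
        alt_reads = rng.binomial(depth, vaf)
        rows.append(
            {"chrom": str(rng.integers(1, 23)), "pos": int(rng.integers(1, 10**8)),
             "ref": ref, "alt": alt, "alt_reads": int(alt_reads), "depth": depth,
             "context": context, "is_somatic": False, "true_signature": None,
             "true_channel": ch}
        )
    variants = pd.DataFrame(rows, columns=list(VARIANT_COLUMNS)
                            + ["is_somatic", "true_signature", "true_channel"])
    return variants, truth


# ---------------------------------------------------------------------------
# survival


def gen_survival(
    n: int,
    covariate: Sequence[float],
    log_hr: float,
    seed: int,
    baseline_hazard: float = 0.1,
    censoring_fraction: float = 0.0,
) -> pd.DataFrame:
    """Exponential survival times with hazard h0 * exp(log_hr * x).

    All subjects are events by default (time to treatment failure ends at
    progression or at stopping therapy, so it is observed for everyone); an
    optional ``censoring_fraction`` marks a random subset censored at their
    drawn time.  Returns a DataFrame (time, event, covariate).
    """
    if n < 10:
        raise ValueError("need n >= 10")
    x = np.asarray(covariate, dtype=float)
    if len(x) != n:
        raise ValueError("covariate length must equal n")
    rng = np.random.default_rng(seed)
    hazard = baseline_hazard * np.exp(log_hr * x)
    time = rng.exponential(1.0 / hazard)
    event = np.ones(n, dtype=int)
    if censoring_fraction > 0:
        censored = rng.random(n) < censoring_fraction
        event[censored] = 0
    return pd.DataFrame({"time": time, "event": event, "covariate": x})
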