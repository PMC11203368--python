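"""TSS-window methylation count matrices and differential methylation calling.

Methylation-dependent restriction-enzyme sequencing (LpnPI digestion) yields
32-bp fragments centered on methylated CpG sites; site-level count scores are
aggregated into 2-kb windows around transcription start sites, filtered
(autosomes only; regions with zero counts in more than 75% of samples are
dropped), normalized with median-of-ratios size factors, and tested for
differential methylation between a case subset and the healthy-blood-donor
reference with a negative-binomial log-linear Wald test.

The test is a documented simplification of the DESeq2 workflow: per-region
method-of-moments dispersion shrunk 50/50 (in log space) toward a log-linear
mean-dispersion trend, a two-parameter NB GLM with the log size factor as
offset, a Wald statistic on the group coefficient against the normal
reference, and Benjamini-Hochberg adjustment across tested regions.  There is
no outlier replacement, independent filtering or fold-change shrinkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hallmarks import bh_adjust

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}

DEFAULT_WINDOW_HALFWIDTH = 1000
DEFAULT_MAX_MISSING_FRAC = 0.75
DEFAULT_ALPHA = 0.05


@dataclass
class RegionAnnotation:
    """A TSS-anchored window: [tss - halfwidth, tss + halfwidth), 1-based."""

    region_id: str
    chrom: str
    tss: int
    strand: str = "+"
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH

    def __post_init__(self) -> None:
        if self.window_halfwidth <= 0:
            raise ValueError("window_halfwidth must be positive")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class RegionCountMatrix:
    """Region-by-sample methylation counts with group labels.

    ``counts`` is a regions x samples integer DataFrame; ``groups`` maps each
    sample to its subject group (HBD, TN-blood, tissue, preR, preS, postR,
    postS in the cohort design, but any labels are accepted);
    ``region_chrom`` carries the chromosome of each region when known.
    """

    counts: pd.DataFrame
    groups: pd.Series
    size_factors: pd.Series | None = None
    region_chrom: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def regions(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, samples: Sequence[str]) -> "RegionCountMatrix":
        sf = None if self.size_factors is None else self.size_factors[list(samples)]
        return RegionCountMatrix(
            counts=self.counts[list(samples)],
            groups=self.groups[list(samples)],
            size_factors=sf,
            region_chrom=self.region_chrom,
        )


# ---------------------------------------------------------------------------
# site-level filtering and aggregation


def filter_site_reads(
    reads: Iterable[tuple[str, int, str]],
    site_index: set[tuple[str, int]],
    center_offset: int = 16,
) -> tuple[dict[tuple[str, int], int], float]:
    """Count reads supported by an annotated CpG site at the central offset.

    ``reads`` are (chrom, 1-based start, sequence) records of 32-bp snippets.
    A read passes iff the CpG dinucleotide sits at positions 16/17 of the read
    and the cytosine position is an annotated site; passing reads increment
    that site's count.  Returns (site counts, fraction of reads passing).
    """
    if not site_index:
        raise ValueError("empty site index")
    counts: dict[tuple[str, int], int] = {}
    n_total = n_pass = 0
    for chrom, start, seq in reads:
        n_total += 1
        if len(seq) < center_offset + 1:
            continue
        if seq[center_offset - 1: center_offset + 1] != "CG":
            continue
        site = (chrom, start + center_offset - 1)
        if site not in site_index:
            continue
        counts[site] = counts.get(site, 0) + 1
        n_pass += 1
    if n_total == 0:
        raise ValueError("empty read set")
    return counts, n_pass / n_total


def aggregate_tss(
    site_counts: pd.DataFrame,
    annotations: Sequence[RegionAnnotation],
    groups: Mapping[str, str] | None = None,
) -> RegionCountMatrix:
    """Aggregate CpG-site counts into TSS windows.

    ``site_counts`` has columns (chrom, pos, sample, count).  A site with
    tss - halfwidth <= pos < tss + halfwidth contributes to the region,
    strand-independently; a site inside several overlapping windows
    contributes to each of them.  Annotations on chromosomes absent from the
    site table produce a warning and an all-zero row.
    """
    samples = sorted(site_counts["sample"].unique())
    by_chrom = {
        chrom: grp.sort_values("pos")
        for chrom, grp in site_counts.groupby("chrom")
    }
    mat = np.zeros((len(annotations), len(samples)), dtype=int)
    sample_pos = {s: j for j, s in enumerate(samples)}
    region_chrom = {}
    for i, ann in enumerate(annotations):
        region_chrom[ann.region_id] = ann.chrom
        if ann.chrom not in by_chrom:
            warnings.warn(
                f"region {ann.region_id}: chromosome {ann.chrom} absent from "
                "site counts; emitting zeros", stacklevel=2,
            )
            continue
        sites = by_chrom[ann.chrom]
        lo = ann.tss - ann.window_halfwidth
        hi = ann.tss + ann.window_halfwidth  # half-open upper bound
        pos = sites["pos"].to_numpy()
        a, b = np.searchsorted(pos, lo, "left"), np.searchsorted(pos, hi, "left")
        for row in sites.iloc[a:b].itertuples(index=False):
            mat[i, sample_pos[row.sample]] += row.count
    counts = pd.DataFrame(
        mat, index=[a.region_id for a in annotations], columns=samples
    )
    if groups is None:
        groups = {s: "unknown" for s in samples}
    return RegionCountMatrix(
        counts=counts, groups=pd.Series(groups), region_chrom=region_chrom
    )


def region_filter(
    matrix: RegionCountMatrix,
    max_missing_frac: float = DEFAULT_MAX_MISSING_FRAC,
    autosomes_only: bool = True,
) -> RegionCountMatrix:
    """Drop non-autosomal regions and regions missing in too many samples.

    A region is dropped when it has zero counts in strictly more than
    ``max_missing_frac`` of samples (zero in exactly that fraction is kept).
    """
    counts = matrix.counts
    keep = pd.Series(True, index=counts.index)
    if autosomes_only:
        if not matrix.region_chrom:
            raise ValueError("autosome filtering requires region chromosomes")
        keep &= pd.Series(
            {r: matrix.region_chrom.get(r) in AUTOSOMES for r in counts.index}
        )
    missing_frac = (counts == 0).sum(axis=1) / counts.shape[1]
    keep &= missing_frac <= max_missing_frac
    if not keep.any():
        raise ValueError("all regions removed by filtering")
    return RegionCountMatrix(
        counts=counts[keep],
        groups=matrix.groups,
        size_factors=matrix.size_factors,
        region_chrom=matrix.region_chrom,
    )


# ---------------------------------------------------------------------------
# normalization


def size_factors(matrix: RegionCountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Only regions with nonzero counts in every sample enter: for each such
    region the per-sample ratio to the region's geometric mean is formed, and
    the factor is the per-sample median of those ratios.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no region with nonzero counts in every sample")
    sub = counts[all_pos]
    log_geomean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geomean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=matrix.counts.columns, name="size_factor")


def sqrt_normalize(matrix: RegionCountMatrix) -> pd.DataFrame:
    """sqrt(count / size factor), the transform used for downstream screens
    and clustering."""
    sf = matrix.size_factors
    if sf is None:
        sf = size_factors(matrix)
    return np.sqrt(matrix.counts / sf[matrix.counts.columns])


# ---------------------------------------------------------------------------
# NB Wald differential methylation test


def _mom_dispersion(y_norm: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Pooled per-region method-of-moments NB dispersion on normalized counts."""
    num = np.zeros(y_norm.shape[0])
    den = np.zeros(y_norm.shape[0])
    for idx in group_idx:
        sub = y_norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / m**2
        a = np.where(np.isfinite(a), a, 0.0)
        w = len(idx) - 1
        num += w * a
        den += w
    return num / den


def _dispersion_trend(alpha_mom: np.ndarray, basemean: np.ndarray) -> np.ndarray:
    """Fit log(alpha) ~ a + b log(mean) on regions with usable estimates and
    predict for all regions; falls back to the median dispersion when the
    regression is degenerate."""
    usable = (alpha_mom > 1e-6) & (basemean > 0)
    fallback = np.median(alpha_mom[alpha_mom > 0]) if (alpha_mom > 0).any() else 0.01
    if usable.sum() < 10:
        return np.full_like(alpha_mom, max(fallback, 1e-6))
    x = np.log(basemean[usable])
    z = np.log(alpha_mom[usable])
    b, a = np.polyfit(x, z, 1)
    with np.errstate(divide="ignore"):
        pred = np.where(basemean > 0, np.exp(a + b * np.log(basemean)), fallback)
    return np.clip(pred, 1e-6, 10.0)


def _nb_glm_two_group(
    y: np.ndarray,
    case: np.ndarray,
    log_sf: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Vectorized IRLS for per-region NB GLMs with design (intercept, case).

    ``y`` is regions x samples, ``case`` the 0/1 indicator over samples,
    ``log_sf`` the per-sample offset and ``alpha`` the per-region dispersion.
    Returns (beta0, beta1, se1): natural-log coefficients and the Wald
    standard error of the group coefficient.
    """
    R, n = y.shape
    sf = np.exp(log_sf)
    y_norm = y / sf
    eps = 1e-8
    m_ref = np.maximum(y_norm[:, case == 0].mean(axis=1), eps)
    m_case = np.maximum(y_norm[:, case == 1].mean(axis=1), eps)
    beta0 = np.log(m_ref)
    beta1 = np.log(m_case) - beta0
    a = alpha[:, None]
    for _ in range(max_iter):
        eta = beta0[:, None] + np.outer(beta1, case) + log_sf[None, :]
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + a * mu)
        z = (eta - log_sf[None, :]) + (y - mu) / mu
        # normal equations for the 2-column design, solved per region
        s00 = w.sum(axis=1)
        s01 = (w * case).sum(axis=1)
        s11 = s01  # case is 0/1 so case^2 = case
        t0 = (w * z).sum(axis=1)
        t1 = (w * case * z).sum(axis=1)
        det = s00 * s11 - s01 * s01
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        new0 = (s11 * t0 - s01 * t1) / det
        new1 = (s00 * t1 - s01 * t0) / det
        new1 = np.clip(new1, -30, 30)
        new0 = np.clip(new0, -30, 30)
        delta = np.maximum(np.abs(new0 - beta0), np.abs(new1 - beta1))
        beta0, beta1 = new0, new1
        if delta.max() < tol:
            break
    eta = beta0[:, None] + np.outer(beta1, case) + log_sf[None, :]
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + a * mu)
    s00 = w.sum(axis=1)
    s01 = (w * case).sum(axis=1)
    det = s00 * s01 - s01 * s01
    det = np.where(np.abs(det) < 1e-12, 1e-12, det)
    se1 = np.sqrt(np.abs(s00 / det))
    return beta0, beta1, se1


def dmr_test(
    matrix: RegionCountMatrix,
    case_groups: Sequence[str] | str,
    ref_group: str = "HBD",
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Call differentially methylated regions for a case subset vs a reference.

    Returns one row per tested region: ``region_id, basemean, log2fc, wald,
    p, q, direction, dmr``; regions with all-zero counts on both sides are
    excluded and carry no record.  A region is a DMR iff its BH-adjusted
    p-value is below ``alpha``; direction is hyper for positive log2fc.
    """
    if isinstance(case_groups, str):
        case_groups = [case_groups]
    case_samples = [s for s in matrix.samples
                    if matrix.groups[s] in set(case_groups)]
    ref_samples = [s for s in matrix.samples if matrix.groups[s] == ref_group]
    if len(case_samples) < 3 or len(ref_samples) < 3:
        raise ValueError(
            f"need >= 3 samples per side (case={len(case_samples)}, "
            f"ref={len(ref_samples)})"
        )
    sub = matrix.counts[ref_samples + case_samples]
    arr = sub.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    arr = arr.astype(float)
    tested = arr.sum(axis=1) > 0
    arr = arr[tested]
    region_ids = sub.index[tested]

    if matrix.size_factors is not None:
        sf = matrix.size_factors[ref_samples + case_samples].to_numpy()
    else:
        sf = size_factors(
            RegionCountMatrix(counts=sub, groups=matrix.groups[sub.columns])
        ).to_numpy()
    log_sf = np.log(sf)
    case = np.array([0] * len(ref_samples) + [1] * len(case_samples), dtype=float)

    y_norm = arr / sf
    basemean = y_norm.mean(axis=1)
    group_idx = [np.flatnonzero(case == 0), np.flatnonzero(case == 1)]
    alpha_mom = _mom_dispersion(y_norm, group_idx)
    alpha_trend = _dispersion_trend(np.maximum(alpha_mom, 0), basemean)
    # 50/50 geometric shrinkage of the region estimate toward the trend
    alpha_shrunk = np.exp(
        0.5 * np.log(np.clip(alpha_mom, 1e-6, 10.0))
        + 0.5 * np.log(alpha_trend)
    )
    beta0, beta1, se1 = _nb_glm_two_group(arr, case, log_sf, alpha_shrunk)
    wald = beta1 / se1
    p = 2 * stats.norm.sf(np.abs(wald))
    q = bh_adjust(p)
    log2fc = beta1 / np.log(2)
    out = pd.DataFrame(
        {
            "region_id": region_ids,
            "basemean": basemean,
            "log2fc": log2fc,
            "dispersion": alpha_shrunk,
            "wald": wald,
            "p": p,
            "q": q,
            "direction": np.where(log2fc > 0, "hyper", "hypo"),
            "dmr": q < alpha,
        }
    ).reset_index(drop=True)
    return out


def significant_dmrs(dmr_table: pd.DataFrame) -> pd.DataFrame:
    return dmr_table[dmr_table["dmr"]].reset_index(drop=True)
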