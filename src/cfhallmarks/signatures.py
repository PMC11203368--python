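"""Somatic-variant enrichment and mutational-signature refitting.

Exome variants from plasma cfDNA are dominated by germline SNPs. The filters
here enrich tumor-derived SNVs (alt-read support, a VAF window that excludes
the heterozygous 50% band, subtraction of a healthy-donor panel), classify the
survivors into the 96 pyrimidine-centered trinucleotide substitution channels
(SBS96), and refit per-sample channel spectra against a reference signature
catalog by non-negative least squares.  A signature's per-sample fraction is
the number of mutations attributed to it divided by all mutations in the
sample; presence is called at a configurable minimum fraction.

Variant tables are plain pandas DataFrames with columns
``chrom, pos, ref, alt, alt_reads, depth, context`` (``vaf`` is derived).
Indel (ID83) channels are not classified from sequence; precomputed ID count
tables can be refitted with the same solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from . import hallmarks as _hallmarks

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")

#: fixed channel order: substitution-major (C>A..T>G), then 5' base, then 3' base
SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "alt_reads", "depth", "context")


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, context: str) -> str:
    """SBS96 channel of an SNV, collapsing purine references to the pyrimidine strand."""
    if len(context) != 3 or context[1] != ref:
        raise ValueError(
            f"context {context!r} does not center on ref allele {ref!r}"
        )
    if ref in ("G", "A"):
        context = revcomp(context)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


@dataclass
class MutationCatalog:
    """Per-sample counts over the 96 SBS channels."""

    sample_id: str
    counts: pd.Series  # indexed by SBS96_CHANNELS

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ExposureResult:
    """Mutations attributed to each reference signature for one sample."""

    sample_id: str
    exposures: pd.Series  # signature -> mutations attributed (>= 0)
    total: int
    residual: float

    @property
    def fractions(self) -> pd.Series:
        if self.total == 0:
            return self.exposures * 0.0
        return self.exposures / self.total


def add_vaf(variants: pd.DataFrame) -> pd.DataFrame:
    out = variants.copy()
    out["vaf"] = out["alt_reads"] / out["depth"]
    return out


def vaf_filter(
    variants: pd.DataFrame,
    min_alt: int = 10,
    low_max: float = 0.45,
    high: tuple[float, float] = (0.55, 0.70),
) -> pd.DataFrame:
    """Enrich somatic variants: >= ``min_alt`` alt reads and VAF < ``low_max``
    or within the closed ``high`` window.

    The low band keeps subclonal tumor variants below the heterozygous 50%
    cloud; the high band recovers variants on gained alleles while excluding
    homozygous germline SNPs near 100%.
    """
    v = add_vaf(variants)
    keep = (v["alt_reads"] >= min_alt) & (
        (v["vaf"] < low_max) | ((v["vaf"] >= high[0]) & (v["vaf"] <= high[1]))
    )
    out = v[keep].reset_index(drop=True)
    if out.empty:
        warnings.warn("vaf_filter removed every variant", stacklevel=2)
    return out


def subtract_panel(
    variants: pd.DataFrame, panel_variants: set[tuple[str, int, str, str]]
) -> pd.DataFrame:
    """Remove variants whose (chrom, pos, ref, alt) key was seen in healthy donors."""
    if not panel_variants:
        return variants.reset_index(drop=True)
    keys = list(zip(variants["chrom"], variants["pos"], variants["ref"], variants["alt"]))
    keep = [k not in panel_variants for k in keys]
    return variants[keep].reset_index(drop=True)


def build_sbs96(variants: pd.DataFrame, sample_id: str = "sample") -> MutationCatalog:
    """Classify SNVs into the fixed 96-channel order; total equals the SNV count."""
    counts = pd.Series(0, index=list(SBS96_CHANNELS), dtype=int)
    for row in variants.itertuples(index=False):
        if len(row.ref) != 1 or len(row.alt) != 1:
            continue  # only SNVs are classified
        try:
            ch = channel_of(row.ref, row.alt, row.context)
        except ValueError as exc:
            raise ValueError(f"bad variant record {tuple(row)}: {exc}") from exc
        counts[ch] += 1
    return MutationCatalog(sample_id=sample_id, counts=counts)


def read_signature_catalog(path) -> pd.DataFrame:
    """Signature catalog TSV: rows = 96 channels (first column), columns = signatures."""
    cat = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    validate_signature_catalog(cat)
    return cat


def validate_signature_catalog(catalog: pd.DataFrame) -> None:
    if catalog.empty or catalog.shape[1] == 0:
        raise ValueError("empty signature catalog")
    if (catalog.values < 0).any():
        raise ValueError("signature catalog has negative entries")
    colsums = catalog.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        bad = colsums[~np.isclose(colsums, 1.0, atol=1e-6)].index.tolist()
        raise ValueError(f"signature columns do not sum to 1: {bad}")


def fit_exposures(catalog: MutationCatalog, reference: pd.DataFrame) -> ExposureResult:
    """Refit a 96-channel spectrum against reference signatures.

    Solves min_{e >= 0} || counts - P e ||_2 with P the channel-by-signature
    probability matrix; exposures are mutation counts attributed per signature.
    """
    validate_signature_catalog(reference)
    if set(reference.index) != set(catalog.counts.index):
        raise ValueError("channel sets of catalog and reference differ")
    P = reference.loc[catalog.counts.index].to_numpy(dtype=float)
    y = catalog.counts.to_numpy(dtype=float)
    e, resid = nnls(P, y)
    exposures = pd.Series(e, index=reference.columns)
    return ExposureResult(
        sample_id=catalog.sample_id,
        exposures=exposures,
        total=catalog.total,
        residual=float(resid),
    )


def presence_call(result: ExposureResult, min_fraction: float = 0.05) -> set[str]:
    """Signatures attributed at least ``min_fraction`` of the sample's mutations."""
    fr = result.fractions
    return set(fr.index[fr >= min_fraction])


def group_presence_test(
    presence: dict[str, set[str]],
    groups: dict[str, str],
    signature: str,
) -> dict:
    """2x2 presence-by-group test for one signature.

    Returns the table ([[present, absent]] per group), the uncorrected
    chi-square p and the two-sided Fisher p.  With a degenerate margin the
    chi-square is undefined and only Fisher is reported.
    """
    group_names = sorted(set(groups.values()))
    if len(group_names) != 2:
        raise ValueError(f"need exactly two groups, got {group_names}")
    table = []
    for g in group_names:
        samples = [s for s, grp in groups.items() if grp == g]
        n_present = sum(signature in presence[s] for s in samples)
        table.append([n_present, len(samples) - n_present])
    table_arr = np.asarray(table)
    fisher_p = _hallmarks.fisher_2x2(table_arr)
    try:
        chi2, chi2_p = _hallmarks.chi2_2x2(table_arr)
    except ValueError:
        warnings.warn(
            f"degenerate margin for {signature}; chi-square skipped", stacklevel=2
        )
        chi2, chi2_p = float("nan"), float("nan")
    return {
        "signature": signature,
        "groups": group_names,
        "table": table,
        "chi2": chi2,
        "chi2_p": chi2_p,
        "fisher_p": fisher_p,
    }


def synthetic_signatures(n_signatures: int = 3, concentration: float = 0.15,
                         seed: int = 7) -> pd.DataFrame:
    """A small synthetic signature catalog for tests and simulations.

    Each signature concentrates most of its mass on its own block of channels
    (disjoint across signatures) with a flat ``concentration`` floor elsewhere,
    keeping the columns well separated and the refit identifiable.  This is a
    synthetic stand-in, not any published signature set.
    """
    rng = np.random.default_rng(seed)
    n_ch = len(SBS96_CHANNELS)
    block = n_ch // n_signatures
    cols = {}
    for k in range(n_signatures):
        profile = np.full(n_ch, concentration / n_ch)
        idx = np.arange(k * block, (k + 1) * block)
        profile[idx] += (1 - concentration) * rng.dirichlet(np.ones(len(idx)))
        cols[f"SBS_sim{k + 1}"] = profile / profile.sum()
    return pd.DataFrame(cols, index=list(SBS96_CHANNELS))
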