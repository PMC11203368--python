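"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: tab-separated tables for counts and results, BED
for TSS annotations (0-based half-open on disk, 1-based internally), GMT for
gene sets, minimal VCF for variant tables (AD/DP in FORMAT, trinucleotide
context in an INFO tag) and JSON for simulation truth.  VCF parsing goes
through pysam.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import pandas as pd
import pysam

from .aneuploidy import ArmCountProfile
from .medseq import RegionAnnotation, RegionCountMatrix, DEFAULT_WINDOW_HALFWIDTH


# ---------------------------------------------------------------------------
# arm counts


def write_arm_counts(profiles: Sequence[ArmCountProfile], path) -> None:
    rows = [
        {"sample": p.sample_id, "arm": arm, "count": c}
        for p in profiles
        for arm, c in sorted(p.counts.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_arm_counts(path) -> list[ArmCountProfile]:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ("sample", "arm", "count"), path)
    return [
        ArmCountProfile(
            sample_id=str(sample),
            counts=dict(zip(grp["arm"], grp["count"].astype(int))),
        )
        for sample, grp in df.groupby("sample", sort=True)
    ]


def read_arm_reads(path) -> dict[str, list[tuple[str, int]]]:
    """Per-read table (sample, arm, mapq) -> per-sample (arm, mapq) records."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ("sample", "arm", "mapq"), path)
    return {
        str(sample): list(zip(grp["arm"], grp["mapq"].astype(int)))
        for sample, grp in df.groupby("sample", sort=True)
    }


# ---------------------------------------------------------------------------
# region count matrices and group labels


def write_region_matrix(matrix: RegionCountMatrix, counts_path, groups_path=None) -> None:
    matrix.counts.rename_axis("region").to_csv(counts_path, sep="\t")
    if groups_path is not None:
        matrix.groups.rename_axis("sample").rename("group").to_csv(
            groups_path, sep="\t"
        )


def read_region_matrix(counts_path, groups_path=None,
                       region_chrom: Mapping[str, str] | None = None) -> RegionCountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    if groups_path is not None:
        groups = pd.read_csv(groups_path, sep="\t", index_col=0, comment="#")["group"]
    else:
        groups = pd.Series({s: "unknown" for s in counts.columns})
    return RegionCountMatrix(
        counts=counts.astype(int),
        groups=groups.astype(str),
        region_chrom=dict(region_chrom or {}),
    )


# ---------------------------------------------------------------------------
# BED (TSS annotations)


def read_tss_bed(path, window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH) -> list[RegionAnnotation]:
    """BED4+ with strand in column 6: 0-based half-open on disk.

    The TSS is the 5' end of the feature by strand: start + 1 (1-based) on
    '+', end on '-'.  A single-base feature ``chr1 999 1000 +`` therefore
    maps to internal TSS position 1000.
    """
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need >= 4 BED columns")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "+"
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            tss = start_i + 1 if strand != "-" else end_i
            annotations.append(
                RegionAnnotation(
                    region_id=name, chrom=chrom, tss=tss, strand=strand,
                    window_halfwidth=window_halfwidth,
                )
            )
    if not annotations:
        raise ValueError(f"{path}: no usable BED records")
    return annotations


def write_tss_bed(annotations: Sequence[RegionAnnotation], path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(
                f"{a.chrom}\t{a.tss - 1}\t{a.tss}\t{a.region_id}\t0\t{a.strand}\n"
            )


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT needs term, description, >= 1 gene"
                )
            sets[fields[0]] = {g for g in fields[2:] if g}
    if not sets:
        raise ValueError(f"{path}: no gene sets")
    return sets


def write_gmt(sets: Mapping[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, description, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# VCF variant tables


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=TNC,Number=1,Type=String,Description="Trinucleotide context on the reference strand, centered on POS">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(variants: pd.DataFrame, path, sample_id: str = "SAMPLE") -> None:
    """Minimal single-sample VCF with AD/DP genotype fields and a TNC INFO tag."""
    contigs = sorted(variants["chrom"].astype(str).unique(), key=str)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_id}\n")
        ordered = variants.sort_values(["chrom", "pos"], kind="stable")
        for r in ordered.itertuples(index=False):
            ref_reads = int(r.depth) - int(r.alt_reads)
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                f"TNC={r.context}\tAD:DP\t{ref_reads},{int(r.alt_reads)}:"
                f"{int(r.depth)}\n"
            )


def read_vcf(path, context_tag: str = "TNC", fasta=None) -> pd.DataFrame:
    """Read a VCF into the variant-table DataFrame.

    The trinucleotide context comes from ``context_tag`` in INFO or, when
    absent, from ``fasta`` (a pyfaidx.Fasta-like mapping).  Missing AD or DP
    FORMAT fields are an error naming the key.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if len(rec.samples) != 1:
                raise ValueError("expected a single-sample VCF")
            sample = rec.samples[0]
            for key in ("AD", "DP"):
                if key not in sample or sample[key] is None:
                    raise ValueError(
                        f"{path}: record {rec.chrom}:{rec.pos} missing FORMAT "
                        f"key {key}"
                    )
            ad, depth = sample["AD"], int(sample["DP"])
            alt_reads = int(ad[1])
            if context_tag in rec.info:
                context = str(rec.info[context_tag])
            elif fasta is not None:
                seq = fasta[rec.chrom][rec.pos - 2: rec.pos + 1]
                context = str(seq).upper()
            else:
                raise ValueError(
                    f"{path}: record {rec.chrom}:{rec.pos} has no {context_tag} "
                    "INFO tag and no FASTA was supplied"
                )
            rows.append(
                {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                 "alt": rec.alts[0], "alt_reads": alt_reads, "depth": depth,
                 "context": context}
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "alt_reads", "depth",
                       "context"]
    )


def read_panel_variants(path) -> set[tuple[str, int, str, str]]:
    """Donor-panel variant TSV (chrom, pos, ref, alt) -> exact-match key set."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ("chrom", "pos", "ref", "alt"), path)
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples(index=False)
    }


def write_panel_variants(keys, path) -> None:
    pd.DataFrame(sorted(keys), columns=["chrom", "pos", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# survival and truth


def write_survival(df: pd.DataFrame, path) -> None:
    df.rename_axis("sample").to_csv(path, sep="\t")


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    _require_columns(df, ("time", "event"), path)
    if (df["time"] <= 0).any():
        raise ValueError(f"{path}: survival times must be positive")
    return df


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, default=str)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
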