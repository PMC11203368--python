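"""End-to-end synthetic-cohort pipeline.

Chains the stages of the cfDNA workflow in dependency order on a simulated
cohort with known truth: arm-count simulation and GWZ aneuploidy calls,
methylation-count simulation with per-subset DMR testing, hallmark set
algebra with the Cox TTF screen and enrichment, and variant simulation with
signature refitting and group presence tests.  Every output table carries the
configuration hash and seed in a leading comment line, and the whole run is a
pure function of the configuration: identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import aneuploidy, hallmarks, io, medseq, signatures, synthdata
from .config import RunConfig

#: fixed per-stage seed offsets (keeps every derived seed below 2**31)
_STAGE_OFFSETS = {"arms": 11, "methyl": 23, "variants": 37, "survival": 53,
                  "terms": 71}


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    return (cfg.seed * 1_000 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cfhallmarks config={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage on a synthetic cohort; returns the result bundle.

    The bundle maps stage names to in-memory results; all tables are also
    written under ``out_dir`` together with the simulation truth and a run
    manifest.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": cfg.to_dict(), "config_hash": cfg.config_hash()}

    # --- stage 1: aneuploidy -------------------------------------------------
    arm_truth = synthdata.SimTruth(
        tumor_fraction=cfg.sim_tumor_fraction,
        arm_cn_profile={"8q": 4, "3p": 1},  # a canonical gain and a loss
        seed=_stage_seed(cfg, "arms"),
    )
    panel_profiles, case_profiles, _ = synthdata.gen_arm_counts(
        panel_size=8, n_cases=6, truth=arm_truth, depth=cfg.sim_depth_arm
    )
    panel = aneuploidy.build_panel(panel_profiles)
    gwz = aneuploidy.gwz_table(case_profiles, panel, threshold=cfg.gwz_threshold)
    _write_tsv(gwz, out / "gwz.tsv", cfg)
    io.write_arm_counts(panel_profiles + case_profiles, out / "arm_counts.tsv")
    bundle["gwz"] = gwz

    # --- stage 2: methylation DMRs ------------------------------------------
    group_sizes = {"HBD": 8, "TN-blood": 4, "tissue": 6,
                   "preR": 5, "preS": 5, "postR": 5, "postS": 5}
    methyl_truth = synthdata.SimTruth(
        dispersion=cfg.sim_dispersion, seed=_stage_seed(cfg, "methyl")
    )
    matrix, methyl_truth = synthdata.gen_methyl_counts(
        n_regions=cfg.sim_n_regions,
        group_sizes=group_sizes,
        dmr_frac=cfg.sim_dmr_frac,
        effect_log2fc=cfg.sim_effect_log2fc,
        truth=methyl_truth,
        effect_groups=["tissue", "preR", "preS", "postR", "postS"],
        group_effect_probability=0.6,
    )
    matrix = medseq.region_filter(
        matrix, max_missing_frac=cfg.max_missing_frac, autosomes_only=True
    )
    matrix.size_factors = medseq.size_factors(matrix)
    io.write_region_matrix(matrix, out / "region_counts.tsv", out / "groups.tsv")
    io.write_truth(methyl_truth, out / "truth_methyl.json")

    subset_contrasts = {
        "pre": ["preR", "preS"], "post": ["postR", "postS"],
        "preR": ["preR"], "preS": ["preS"], "postR": ["postR"],
        "postS": ["postS"], "tissue": ["tissue"], "TN-blood": ["TN-blood"],
    }
    dmr_tables: dict[str, pd.DataFrame] = {}
    dmr_sets: dict[str, hallmarks.DMRSet] = {}
    for name, groups in subset_contrasts.items():
        table = medseq.dmr_test(matrix, groups, ref_group="HBD", alpha=cfg.alpha)
        dmr_tables[name] = table
        _write_tsv(table, out / f"dmr_{name}.tsv", cfg)
        sig = medseq.significant_dmrs(table)
        dmr_sets[name] = hallmarks.DMRSet(
            name=name, contrast=f"{'+'.join(groups)} vs HBD",
            log2fc=dict(zip(sig["region_id"], sig["log2fc"])),
            q=dict(zip(sig["region_id"], sig["q"])),
        )
    bundle["dmr_tables"] = dmr_tables

    # --- stage 3: hallmarks, TTF screen, enrichment --------------------------
    marks = hallmarks.define_hallmarks(dmr_sets)
    hallmark_rows = [
        {"hallmark": h.name, "region": r, "provenance": h.provenance[r],
         "log2fc": h.log2fc[r]}
        for h in marks.values() for r in sorted(h.region_ids)
    ]
    _write_tsv(pd.DataFrame(hallmark_rows), out / "hallmarks.tsv", cfg)
    overlap = hallmarks.hallmark_overlap(marks)
    (out / "hallmark_overlap.json").write_text(json.dumps(overlap, indent=1))
    bundle["hallmarks"] = marks
    bundle["hallmark_overlap"] = overlap

    # TTF for the ten pre-treatment patients, hazard tied to the first planted
    # DMR's normalized methylation
    pre_samples = [s for s in matrix.samples
                   if matrix.groups[s] in ("preR", "preS")]
    normalized = medseq.sqrt_normalize(matrix)
    true_dmrs = [r for r in methyl_truth.dmr_truth if r in normalized.index]
    covar_region = true_dmrs[0] if true_dmrs else normalized.index[0]
    covariate = normalized.loc[covar_region, pre_samples].to_numpy()
    cov_std = (covariate - covariate.mean()) / (covariate.std() or 1.0)
    surv = synthdata.gen_survival(
        n=len(pre_samples), covariate=cov_std, log_hr=cfg.sim_log_hr,
        seed=_stage_seed(cfg, "survival"),
    )
    surv.index = pd.Index(pre_samples, name="sample")
    io.write_survival(surv, out / "survival.tsv")
    pre_regions = sorted(dmr_sets["pre"].region_ids)
    if pre_regions:
        cox = hallmarks.cox_screen(
            normalized.loc[pre_regions, pre_samples],
            time=surv["time"].to_dict(), event=surv["event"].to_dict(),
            alpha=cfg.alpha,
        )
        _write_tsv(cox, out / "cox_pre.tsv", cfg)
        bundle["cox_pre"] = cox

    # enrichment of each hallmark against a synthetic term database
    background = set(matrix.regions)
    rng = np.random.default_rng(_stage_seed(cfg, "terms"))
    universe = sorted(background)
    terms: dict[str, set[str]] = {
        f"TERM{i:02d}": set(rng.choice(universe, size=40, replace=False))
        for i in range(10)
    }
    for name, h in marks.items():
        if len(h.region_ids) >= 5:
            spiked = sorted(h.region_ids)[: min(20, len(h.region_ids))]
            terms[f"TERM_{name}"] = set(spiked) | set(
                rng.choice(universe, size=10, replace=False)
            )
    io.write_gmt(terms, out / "terms.gmt")
    enrichment: dict[str, pd.DataFrame] = {}
    for name, h in marks.items():
        if not h.region_ids:
            continue
        table = hallmarks.enrich(h.region_ids, terms, background)
        enrichment[name] = table
        _write_tsv(table.drop(columns="overlap_genes"),
                   out / f"enrichment_{name}.tsv", cfg)
    bundle["enrichment"] = enrichment

    # --- stage 4: mutational signatures --------------------------------------
    catalog = signatures.synthetic_signatures(n_signatures=3)
    weights = {"SBS_sim1": 0.6, "SBS_sim2": 0.3, "SBS_sim3": 0.1}
    sample_groups = {f"R{i + 1}": "resistant" for i in range(4)}
    sample_groups.update({f"S{i + 1}": "sensitive" for i in range(4)})
    exposures_rows, presence = [], {}
    panel_keys: set = set()
    for j, (sample, grp) in enumerate(sample_groups.items()):
        var_truth = synthdata.SimTruth(
            tumor_fraction=cfg.sim_tumor_fraction,
            signature_weights=weights,
            seed=_stage_seed(cfg, "variants") + j,
        )
        variants, _ = synthdata.gen_variants(
            n_somatic=cfg.sim_n_somatic, n_germline=cfg.sim_n_germline,
            truth=var_truth, signatures=catalog, depth=cfg.sim_depth_variants,
        )
        germ = variants[~variants["is_somatic"]]
        panel_keys |= {
            (r.chrom, r.pos, r.ref, r.alt) for r in germ.itertuples(index=False)
        }
        kept = signatures.vaf_filter(
            variants, min_alt=cfg.min_alt_reads, low_max=cfg.vaf_low_max,
            high=cfg.vaf_high,
        )
        kept = signatures.subtract_panel(kept, panel_keys)
        cat = signatures.build_sbs96(kept, sample_id=sample)
        fit = signatures.fit_exposures(cat, catalog)
        presence[sample] = signatures.presence_call(
            fit, min_fraction=cfg.presence_min_fraction
        )
        row = {"sample": sample, "group": grp, "total": fit.total,
               "residual": fit.residual}
        row.update({f"frac_{s}": f for s, f in fit.fractions.items()})
        exposures_rows.append(row)
    exposures = pd.DataFrame(exposures_rows)
    _write_tsv(exposures, out / "signature_exposures.tsv", cfg)
    presence_df = pd.DataFrame(
        [{"sample": s, "group": sample_groups[s],
          **{sig: sig in present for sig in catalog.columns}}
         for s, present in presence.items()]
    )
    _write_tsv(presence_df, out / "signature_presence.tsv", cfg)
    group_tests = pd.DataFrame([
        signatures.group_presence_test(presence, sample_groups, sig)
        for sig in catalog.columns
    ])
    _write_tsv(group_tests.astype(str), out / "signature_group_tests.tsv", cfg)
    bundle["exposures"] = exposures
    bundle["presence"] = presence_df
    bundle["group_tests"] = group_tests

    manifest = {
        "config_hash": cfg.config_hash(), "seed": cfg.seed,
        "outputs": sorted(
            [p.name for p in out.iterdir()] + ["run_manifest.json"]
        ),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    return bundle
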