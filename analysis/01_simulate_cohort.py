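"""Simulate the synthetic study cohort and write every downstream input.

Emits, under results/sim/: per-arm read counts for a healthy panel plus
post-treatment cases (tumor fraction 0.2, 8q gain + 3p loss), a TSS-window
methylation count matrix for all subject groups with planted DMRs, one VCF
per patient with somatic variants drawn from a 3-signature mixture plus
germline-like SNPs, TTF survival times tied to a planted methylation
covariate, and the ground-truth JSON files the later steps are checked
against.
"""

import argparse
import json
from pathlib import Path

from cfhallmarks import io, medseq, synthdata
from cfhallmarks import signatures as sig
from cfhallmarks.synthdata import SimTruth

GROUP_SIZES = {"HBD": 8, "TN-blood": 4, "tissue": 6,
               "preR": 5, "preS": 5, "postR": 5, "postS": 5}
SIGNATURE_WEIGHTS = {"SBS_sim1": 0.6, "SBS_sim2": 0.3, "SBS_sim3": 0.1}
PATIENTS = [f"R{i+1}" for i in range(4)] + [f"S{i+1}" for i in range(4)]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    # arm counts: 8-donor reference panel + 6 tumor-bearing cases
    arm_truth = SimTruth(tumor_fraction=0.2, arm_cn_profile={"8q": 4, "3p": 1},
                         seed=args.seed * 100 + 1)
    panel, cases, _ = synthdata.gen_arm_counts(8, 6, arm_truth, depth=100_000)
    io.write_arm_counts(panel + cases, out / "arm_counts.tsv")
    (out / "panel_samples.txt").write_text(
        "\n".join(p.sample_id for p in panel) + "\n"
    )
    io.write_truth(arm_truth, out / "truth_arms.json")

    # methylation counts with planted DMRs in the disease groups
    methyl_truth = SimTruth(dispersion=0.1, seed=args.seed * 100 + 2)
    matrix, methyl_truth = synthdata.gen_methyl_counts(
        2000, GROUP_SIZES, dmr_frac=0.1, effect_log2fc=1.0,
        truth=methyl_truth,
        effect_groups=["tissue", "preR", "preS", "postR", "postS"],
        group_effect_probability=0.6,
    )
    io.write_region_matrix(matrix, out / "region_counts.tsv",
                           out / "groups.tsv")
    io.write_truth(methyl_truth, out / "truth_methyl.json")

    # variants: one VCF per patient; germline keys pooled into a donor panel
    catalog = sig.synthetic_signatures(n_signatures=3)
    catalog.rename_axis("channel").to_csv(out / "signature_catalog.tsv",
                                          sep="\t")
    panel_keys = set()
    for j, patient in enumerate(PATIENTS):
        var_truth = SimTruth(tumor_fraction=0.2,
                             signature_weights=SIGNATURE_WEIGHTS,
                             seed=args.seed * 100 + 10 + j)
        variants, _ = synthdata.gen_variants(
            800, 200, var_truth, catalog, depth=200
        )
        io.write_vcf(variants, out / f"variants_{patient}.vcf",
                     sample_id=patient)
        variants.to_csv(out / f"variants_{patient}.truth.tsv", sep="\t",
                        index=False)
        germ = variants[~variants["is_somatic"]]
        panel_keys |= {(r.chrom, r.pos, r.ref, r.alt)
                       for r in germ.itertuples(index=False)}
    io.write_panel_variants(panel_keys, out / "donor_panel.tsv")

    # term database for enrichment: random background terms plus terms
    # concentrated in the planted DMR regions
    import numpy as np

    rng = np.random.default_rng(args.seed * 100 + 4)
    universe = list(matrix.regions)
    terms = {
        f"TERM{i:02d}": set(rng.choice(universe, size=40, replace=False))
        for i in range(10)
    }
    planted = sorted(methyl_truth.dmr_truth)
    for k in range(3):
        core = rng.choice(planted, size=min(25, len(planted)), replace=False)
        noise = rng.choice(universe, size=15, replace=False)
        terms[f"TERM_PLANTED{k + 1}"] = set(core) | set(noise)
    io.write_gmt(terms, out / "terms.gmt")

    # TTF survival for the ten pre-treatment patients, hazard tied to the
    # first planted DMR's normalized methylation
    matrix.size_factors = medseq.size_factors(matrix)
    normalized = medseq.sqrt_normalize(matrix)
    pre = [s for s in matrix.samples if matrix.groups[s] in ("preR", "preS")]
    region = next(iter(methyl_truth.dmr_truth))
    x = normalized.loc[region, pre]
    x_std = (x - x.mean()) / x.std()
    surv = synthdata.gen_survival(len(pre), x_std.to_numpy(), log_hr=0.7,
                                  seed=args.seed * 100 + 3)
    surv.index = x.index.rename("sample")
    io.write_survival(surv, out / "survival.tsv")

    n_files = len(list(out.iterdir()))
    print(f"simulated cohort written to {out} ({n_files} files)")
    print(f"  groups: {json.dumps(GROUP_SIZES)}")
    print(f"  planted DMRs: {len(methyl_truth.dmr_truth)} of 2000 regions")
    print(f"  signature mixture: {SIGNATURE_WEIGHTS}")


if __name__ == "__main__":
    main()
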