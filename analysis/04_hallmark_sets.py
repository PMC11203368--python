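"""Derive the DTE/PP/PR hallmark DMR sets and their downstream statistics.

Combines the per-subset DMR tables by set algebra (unique DMRs of each
defining comparison, restricted to tumor-tissue DMRs), screens pre-treatment
DMRs for association with time to treatment failure by Cox regression,
enriches each hallmark against the simulated term database with kappa
clustering of the significant terms, and clusters the pre/post samples on
the sqrt-normalized hallmark regions.
"""

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from cfhallmarks import hallmarks as hm
from cfhallmarks import io


def load_dmr_sets(tables_dir: Path) -> dict:
    sets = {}
    for name in hm.REQUIRED_SUBSETS:
        table = pd.read_csv(tables_dir / f"dmr_{name}.tsv", sep="\t")
        sigt = table[table["dmr"]]
        sets[name] = hm.DMRSet(
            name=name, contrast=f"{name} vs HBD",
            log2fc=dict(zip(sigt["region_id"], sigt["log2fc"])),
            q=dict(zip(sigt["region_id"], sigt["q"])),
        )
    return sets


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--tables", type=Path, default=Path("results/tables"))
    args = ap.parse_args()

    marks = hm.define_hallmarks(load_dmr_sets(args.tables))
    rows = [
        {"hallmark": h.name, "region": r, "provenance": h.provenance[r],
         "log2fc": h.log2fc[r]}
        for h in marks.values() for r in sorted(h.region_ids)
    ]
    pd.DataFrame(rows).to_csv(args.tables / "hallmarks.tsv", sep="\t",
                              index=False)
    for h in marks.values():
        sides = ", ".join(f"{k}: {v}" for k, v in sorted(h.side_counts().items()))
        print(f"{h.name}: {len(h)} DMRs ({sides})")
    overlap = hm.hallmark_overlap(marks)
    (args.tables / "hallmark_overlap.json").write_text(
        json.dumps(overlap, indent=1)
    )
    print(f"hallmark overlap: {overlap}")

    # Cox TTF screen over the pre-treatment DMRs
    surv = io.read_survival(args.sim / "survival.tsv")
    normalized = pd.read_csv(args.tables / "normalized_matrix.tsv", sep="\t",
                             index_col=0, comment="#")
    pre_set = load_dmr_sets(args.tables)["pre"]
    pre_regions = sorted(pre_set.region_ids & set(normalized.index))
    cox = hm.cox_screen(
        normalized.loc[pre_regions, surv.index],
        time=surv["time"].to_dict(), event=surv["event"].to_dict(),
    )
    cox.to_csv(args.tables / "cox_pre.tsv", sep="\t", index=False)
    n_sig = int(cox["significant"].sum())
    print(f"Cox TTF screen: {n_sig}/{len(cox)} pre-treatment DMRs at p < 0.05")
    per_mark = {
        name: int(cox[cox["region"].isin(h.region_ids)]["significant"].sum())
        for name, h in marks.items()
    }
    print(f"TTF-associated DMRs per hallmark: {per_mark}")

    # enrichment + kappa clustering against the simulated term database
    background = set(normalized.index)
    terms = io.read_gmt(args.sim / "terms.gmt") \
        if (args.sim / "terms.gmt").exists() else None
    if terms:
        for name, h in marks.items():
            if not h.region_ids:
                continue
            table = hm.enrich(h.region_ids, terms, background)
            table.drop(columns="overlap_genes").to_csv(
                args.tables / f"enrichment_{name}.tsv", sep="\t", index=False
            )
            passing = table[table["passes_filter"]]
            if len(passing):
                clusters = hm.kappa_cluster(
                    {r["term"]: set(r["overlap_genes"])
                     for _, r in passing.iterrows()},
                    dict(zip(passing["term"], passing["p"])),
                )
                reps = [c["representative"] for c in clusters]
                print(f"{name}: {len(passing)} enriched terms in "
                      f"{len(clusters)} kappa clusters (reps: {reps})")
            else:
                print(f"{name}: no term passes the enrichment filter")

    # sample clustering on the largest hallmark
    biggest = max(marks.values(), key=len)
    cohort = [c for c in normalized.columns
              if c.split("_")[0] in ("preR", "preS", "postR", "postS")]
    sub = normalized.loc[sorted(biggest.region_ids), cohort]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, order = hm.cluster_samples(sub)
    (args.tables / "sample_cluster_order.txt").write_text(
        "\n".join(order) + "\n"
    )
    print(f"sample dendrogram order ({biggest.name} regions): {order}")


if __name__ == "__main__":
    main()
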