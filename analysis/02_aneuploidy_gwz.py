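"""Score the simulated plasma samples for aneuploidy.

Builds the healthy-donor reference panel from the simulated arm counts,
studentizes each case sample's arm fractions against it, and reports the
genome-wide z-score (GWZ) with the threshold-5 aneuploidy call.
"""

import argparse
from pathlib import Path

from cfhallmarks import aneuploidy, io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/tables"))
    ap.add_argument("--threshold", type=float, default=5.0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    profiles = io.read_arm_counts(args.sim / "arm_counts.tsv")
    panel_ids = set(
        (args.sim / "panel_samples.txt").read_text().split()
    )
    panel = aneuploidy.build_panel(
        [p for p in profiles if p.sample_id in panel_ids]
    )
    cases = [p for p in profiles if p.sample_id not in panel_ids]
    table = aneuploidy.gwz_table(cases, panel, threshold=args.threshold)
    table.to_csv(args.out / "gwz.tsv", sep="\t", index=False)

    n_aneuploid = int(table["aneuploid"].sum())
    print(f"panel: {panel.n_ref} healthy donors, {len(panel.arm_set)} arms")
    print(f"{n_aneuploid}/{len(table)} case samples aneuploid at "
          f"GWZ >= {args.threshold}")
    print(table[["sample", "gwz", "aneuploid"]].to_string(index=False))


if __name__ == "__main__":
    main()
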