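"""Reproduce the published cohort-level 2x2 statistics.

The patient-level data are not deposited, but every group comparison the
study prints comes with its 2x2 counts; recomputing the uncorrected
chi-square from those counts reproduces the printed p-values, which anchors
the test implementations used throughout the pipeline.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cfhallmarks import hallmarks as hm

COMPARISONS = [
    ("FIGO stage (IIIB/IIIC vs IV)", [[9, 12], [6, 4]], "0.372"),
    ("Surgical outcome (complete vs incomplete)", [[10, 12], [3, 3]], "0.843"),
    ("Previous chemotherapy lines (1-2 vs 3-4)", [[14, 14], [1, 2]], "0.583"),
    ("SBS26 presence (resistant vs sensitive)", [[0, 14], [4, 12]], "0.04"),
    ("Hallmark DMR asymmetry (pre 274/30 vs post 190/57)",
     [[274, 30], [190, 57]], "<0.001"),
    ("TTF-DMR enrichment (PP 40/304 vs DTE 25/352)",
     [[40, 264], [25, 327]], "<0.03"),
    ("TTF-DMR enrichment (PP 40/304 vs PR 17/247)",
     [[40, 264], [17, 230]], "<0.03"),
]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/tables"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for label, table, printed in COMPARISONS:
        chi2, p = hm.chi2_2x2(table)
        fisher = hm.fisher_2x2(table)
        rows.append({"comparison": label, "table": json.dumps(table),
                     "chi2": round(chi2, 4), "chi2_p": round(p, 6),
                     "fisher_p": round(fisher, 6), "printed_p": printed})
        print(f"{label}: chi2 = {chi2:.3f}, p = {p:.4g} "
              f"(printed {printed}), Fisher p = {fisher:.4g}")
    pd.DataFrame(rows).to_csv(args.out / "cohort_statistics.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
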