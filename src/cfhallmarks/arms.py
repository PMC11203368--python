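"""Chromosome-arm reference table.

Arm lengths (bp, approximate, GRCh38 cytoband boundaries) drive the baseline
arm-fraction vector of the read-count simulator and define the default arm
universe of the aneuploidy module.  The short arms of the acrocentric
chromosomes 13, 14, 15 and 22 carry too few LINE-1 elements to be assayed by
arm-level amplicon sequencing and are excluded by default; sex chromosomes are
excluded as well (all-female cohort, avoids X-dosage artifacts).  Both
exclusion lists are configuration, not hard-coded behaviour.
"""

from __future__ import annotations

# chromosome -> (p-arm length, q-arm length), GRCh38, rounded to 0.1 Mb
_ARM_LENGTHS_MB: dict[str, tuple[float, float]] = {
    "1": (123.4, 125.6),
    "2": (93.9, 148.3),
    "3": (90.9, 107.4),
    "4": (50.0, 140.2),
    "5": (48.8, 132.7),
    "6": (59.8, 111.0),
    "7": (60.1, 99.2),
    "8": (45.2, 99.9),
    "9": (43.0, 95.4),
    "10": (39.8, 94.0),
    "11": (53.4, 81.7),
    "12": (35.5, 97.8),
    "13": (17.7, 96.7),
    "14": (17.2, 89.8),
    "15": (19.0, 83.0),
    "16": (36.8, 53.5),
    "17": (25.1, 58.2),
    "18": (18.5, 61.9),
    "19": (26.2, 32.4),
    "20": (28.1, 36.3),
    "21": (12.0, 34.7),
    "22": (15.0, 35.8),
}

#: arms dropped from the default universe (acrocentric short arms)
DEFAULT_EXCLUDED_ARMS: tuple[str, ...] = ("13p", "14p", "15p", "22p")

#: all 44 autosomal arms in karyotype order
ALL_AUTOSOMAL_ARMS: tuple[str, ...] = tuple(
    f"{chrom}{arm}" for chrom in _ARM_LENGTHS_MB for arm in ("p", "q")
)

#: the 40-arm default universe: autosomes minus the acrocentric exclusions
DEFAULT_ARM_SET: tuple[str, ...] = tuple(
    a for a in ALL_AUTOSOMAL_ARMS if a not in DEFAULT_EXCLUDED_ARMS
)


def arm_length(arm: str) -> float:
    """Length of a chromosome arm in megabases.

    Raises ``KeyError`` with the offending label for unknown arms.
    """
    chrom, side = arm[:-1], arm[-1]
    if chrom not in _ARM_LENGTHS_MB or side not in ("p", "q"):
        raise KeyError(f"unknown chromosome arm: {arm!r}")
    p, q = _ARM_LENGTHS_MB[chrom]
    return p if side == "p" else q


def baseline_arm_fractions(arm_set: tuple[str, ...] = DEFAULT_ARM_SET) -> dict[str, float]:
    """Length-proportional arm fractions over ``arm_set``, summing to 1."""
    lengths = {a: arm_length(a) for a in arm_set}
    total = sum(lengths.values())
    return {a: length / total for a, length in lengths.items()}
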