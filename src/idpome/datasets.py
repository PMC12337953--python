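"""Published summary count tables from a comparative survey of six retinal
proteomes (a healthy-retina reference set, an inherited-retinal-disease gene
panel, and four disease proteomes: age-related macular degeneration,
glaucoma, and diabetic retinopathy with and without gliosis).

Only *counts* are carried here — per-quadrant CH–CDF assignments, per-tier
disorder classifications, proteome sizes, and reference-overlap splits — so
that the contingency statistics and percentage arithmetic those surveys
report can be recomputed from data shipped with the package, without any
external download. The per-protein scores behind the counts came from
external trained predictors and are not reproduced here.

Note: the healthy-reference quadrant row sums to 12,819 while the stated
proteome size is 12,844; both figures are preserved as printed.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "PROTEOME_NAMES",
    "proteome_sizes",
    "quadrant_counts",
    "tier_counts",
    "overlap_counts",
]

#: Row order used by all tables below.
PROTEOME_NAMES = ["HPA", "RetNet", "AMD", "Glaucoma", "DR(-)G", "DR(+)G"]

_SIZES = {
    "HPA": 12_844,
    "RetNet": 331,
    "AMD": 158,
    "Glaucoma": 32,
    "DR(-)G": 172,
    "DR(+)G": 103,
}

_QUADRANTS = {
    #            Q1    Q2    Q3   Q4
    "HPA":      [7396, 3291, 1671, 461],
    "RetNet":   [209,  82,   39,   1],
    "AMD":      [119,  15,   18,   6],
    "Glaucoma": [23,   5,    1,    3],
    "DR(-)G":   [112,  31,   27,   2],
    "DR(+)G":   [73,   20,   9,    1],
}

_TIERS = {
    # HighlyDisordered, HighlyOrdered, ModeratelyDisordered, ModeratelyOrdered
    "HPA":      [7970, 19, 4371, 459],
    "RetNet":   [187,  0,  125,  19],
    "AMD":      [70,   0,  76,   12],
    "Glaucoma": [14,   0,  17,   1],
    "DR(-)G":   [77,   0,  88,   7],
    "DR(+)G":   [48,   0,  55,   0],
}

_OVERLAP = {
    # overlap with the healthy reference, unique to the disease set
    "RetNet":   [290, 41],
    "AMD":      [110, 48],
    "Glaucoma": [22, 10],
    "DR(-)G":   [153, 19],
    "DR(+)G":   [97, 6],
}


def proteome_sizes() -> pd.Series:
    """Stated protein count per proteome."""
    return pd.Series(_SIZES, name="n_proteins").loc[PROTEOME_NAMES]


def quadrant_counts() -> pd.DataFrame:
    """CH–CDF quadrant counts (rows: proteomes; columns: Q1–Q4)."""
    return pd.DataFrame.from_dict(
        _QUADRANTS, orient="index", columns=["Q1", "Q2", "Q3", "Q4"]
    ).loc[PROTEOME_NAMES]


def tier_counts() -> pd.DataFrame:
    """Disorder-tier counts (rows: proteomes; columns: the four tiers)."""
    return pd.DataFrame.from_dict(
        _TIERS,
        orient="index",
        columns=[
            "HighlyDisordered",
            "HighlyOrdered",
            "ModeratelyDisordered",
            "ModeratelyOrderedOrMildlyFlexible",
        ],
    ).loc[PROTEOME_NAMES]


def overlap_counts() -> pd.DataFrame:
    """Overlap-vs-unique counts of each disease set against the healthy reference."""
    return pd.DataFrame.from_dict(
        _OVERLAP, orient="index", columns=["overlap", "unique"]
    ).loc[[n for n in PROTEOME_NAMES if n != "HPA"]]
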