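"""Charge–hydropathy (CH) and cumulative-distribution-function (CDF) analysis.

The CH score is the whole-sequence linear discriminant
``CH = |<R>| − 2.785·<H> + 1.151`` (absolute mean net charge vs mean
normalized Kyte–Doolittle hydropathy); positive CH lies on the extended,
natively-unfolded side of the boundary line.

The CDF analysis evaluates, for each of seven disorder-score thresholds
(default 0.1 … 0.7), the fraction of a protein's residues at or below the
threshold, and compares the resulting 7-point curve to a boundary curve.
Because the built-in profiles are not the predictor the classical boundary
was trained on, the boundary here is *calibrated*: at each threshold it is
the midpoint between the mean curves of an ordered and a disordered
reference set (synthetic archetype proteomes by default). The scalar CDF
score is the mean signed distance of a protein's curve above its boundary;
positive = ordered side (ordered proteins accumulate low disorder scores
early, pushing their curve up).

Joint quadrants follow the conventional semantics: Q1 (CH ≤ 0, CDF ≥ 0)
structured; Q2 (CH ≤ 0, CDF < 0) molten-globule/hybrid; Q3 (CH > 0,
CDF < 0) highly disordered; Q4 (CH > 0, CDF ≥ 0) mixed. Zeros are
tie-broken to the ordered side of each axis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .disorder import (
    CH_INTERCEPT,
    CH_SLOPE,
    NORMALIZED_KD,
    RESIDUE_CHARGE,
    DisorderProfile,
    foldindex_profile,
)
from .io import Proteome

__all__ = [
    "DEFAULT_CDF_THRESHOLDS",
    "Quadrant",
    "CDFBoundary",
    "CHCDFPoint",
    "ch_score",
    "cdf_curve",
    "calibrate_cdf_boundary",
    "cdf_score",
    "assign_quadrant",
    "chcdf_points",
    "quadrant_contingency",
]

DEFAULT_CDF_THRESHOLDS = np.round(np.arange(1, 8) * 0.1, 10)


class Quadrant(str, enum.Enum):
    Q1 = "Q1"  # structured
    Q2 = "Q2"  # molten globule / hybrid
    Q3 = "Q3"  # highly disordered
    Q4 = "Q4"  # CH-disordered, CDF-ordered

QUADRANT_ORDER = [Quadrant.Q1, Quadrant.Q2, Quadrant.Q3, Quadrant.Q4]


@dataclass(frozen=True)
class CDFBoundary:
    """Calibrated CDF boundary: 7 thresholds and 7 boundary fractions."""

    thresholds: np.ndarray
    boundary_values: np.ndarray

    def __post_init__(self) -> None:
        thr = np.asarray(self.thresholds, float)
        val = np.asarray(self.boundary_values, float)
        if thr.shape != val.shape or thr.ndim != 1:
            raise ValueError("thresholds and boundary values must be 1-D and aligned")
        if not np.all(np.diff(thr) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if val.min() < 0.0 or val.max() > 1.0:
            raise ValueError("boundary values must lie in [0, 1]")
        object.__setattr__(self, "thresholds", thr)
        object.__setattr__(self, "boundary_values", val)


@dataclass(frozen=True)
class CHCDFPoint:
    protein_id: str
    ch: float
    cdf: float
    quadrant: Quadrant


def ch_score(sequence: str) -> float:
    """Whole-sequence CH score; CH > 0 marks the disordered side."""
    h = np.mean([NORMALIZED_KD[aa] for aa in sequence])
    r = abs(np.mean([RESIDUE_CHARGE.get(aa, 0.0) for aa in sequence]))
    return float(r - CH_SLOPE * h + CH_INTERCEPT)


def cdf_curve(
    profile: DisorderProfile,
    thresholds: np.ndarray = DEFAULT_CDF_THRESHOLDS,
) -> np.ndarray:
    """Fraction of residues with score ≤ t, for each threshold t."""
    scores = profile.scores
    return np.array([np.mean(scores <= t) for t in np.asarray(thresholds, float)])


def calibrate_cdf_boundary(
    ordered_set: Proteome,
    disordered_set: Proteome,
    predictor: Callable[..., DisorderProfile] = foldindex_profile,
    thresholds: np.ndarray = DEFAULT_CDF_THRESHOLDS,
) -> CDFBoundary:
    """Midpoint boundary between the mean CDF curves of two reference sets.

    Deterministic given the sets. Raises if the two mean curves coincide at
    every threshold (nothing to separate).
    """
    if len(ordered_set) == 0 or len(disordered_set) == 0:
        raise ValueError("calibration sets must be non-empty")

    def mean_curve(proteome: Proteome) -> np.ndarray:
        curves = [
            cdf_curve(predictor(rec.sequence, rec.id), thresholds) for rec in proteome
        ]
        return np.mean(curves, axis=0)

    mo, md = mean_curve(ordered_set), mean_curve(disordered_set)
    if np.allclose(mo, md):
        raise ValueError("degenerate calibration: reference sets have identical mean CDF curves")
    return CDFBoundary(np.asarray(thresholds, float), (mo + md) / 2.0)


def cdf_score(curve: np.ndarray, boundary: CDFBoundary) -> float:
    """Mean signed distance of *curve* above the boundary; positive = ordered."""
    curve = np.asarray(curve, float)
    if curve.shape != boundary.boundary_values.shape:
        raise ValueError("curve and boundary evaluate different thresholds")
    return float(np.mean(curve - boundary.boundary_values))


def assign_quadrant(ch: float, cdf: float) -> Quadrant:
    """Sign-region quadrant; boundary values go to the ordered side."""
    if not (np.isfinite(ch) and np.isfinite(cdf)):
        raise ValueError("CH and CDF scores must be finite")
    if ch <= 0.0:
        return Quadrant.Q1 if cdf >= 0.0 else Quadrant.Q2
    return Quadrant.Q4 if cdf >= 0.0 else Quadrant.Q3


def chcdf_points(
    proteome: Proteome,
    boundary: CDFBoundary,
    predictor: Callable[..., DisorderProfile] = foldindex_profile,
) -> pd.DataFrame:
    """Per-protein CH score, CDF score, and quadrant for one proteome."""
    rows = []
    for rec in proteome:
        ch = ch_score(rec.sequence)
        curve = cdf_curve(predictor(rec.sequence, rec.id), boundary.thresholds)
        cdf = cdf_score(curve, boundary)
        rows.append((rec.id, ch, cdf, assign_quadrant(ch, cdf).value))
    return pd.DataFrame(rows, columns=["protein_id", "ch", "cdf", "quadrant"])


def quadrant_contingency(
    proteome_points: Mapping[str, pd.DataFrame | Sequence[Quadrant | str]],
) -> pd.DataFrame:
    """Proteome × quadrant count table (rows: proteomes, columns Q1–Q4).

    Accepts either the DataFrames from :func:`chcdf_points` or plain
    sequences of quadrant labels. Row sums equal the number of assigned
    proteins per proteome.
    """
    table = {}
    for name, points in proteome_points.items():
        if isinstance(points, pd.DataFrame):
            labels = points["quadrant"]
        else:
            labels = pd.Series([q.value if isinstance(q, Quadrant) else str(q) for q in points])
        counts = labels.value_counts()
        table[name] = [int(counts.get(q.value, 0)) for q in QUADRANT_ORDER]
    return pd.DataFrame.from_dict(
        table, orient="index", columns=[q.value for q in QUADRANT_ORDER]
    )
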