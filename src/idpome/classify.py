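"""ADS/PPDR aggregation and disorder-tier classification.

ADS (average disorder score) is the mean per-residue score of a protein,
in [0, 1]. PPDR (percentage of predicted disordered residues) is the percent
of residues scoring strictly above 0.5. Proteins are binned into four tiers
on the two axes jointly, or into three tiers on ADS alone, at the standard
10%/30% PPDR and 0.15/0.5 ADS cut-offs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .disorder import DisorderProfile
from .io import Proteome

__all__ = [
    "Tier",
    "AdsTier",
    "ClassificationThresholds",
    "DisorderSummary",
    "ads",
    "ppdr",
    "classify_two_axis",
    "classify_ads_only",
    "summarize_protein",
    "proteome_summary",
    "tier_percentages",
]


class Tier(str, enum.Enum):
    """Two-axis disorder tiers."""

    HIGHLY_DISORDERED = "HighlyDisordered"
    HIGHLY_ORDERED = "HighlyOrdered"
    MODERATELY_DISORDERED = "ModeratelyDisordered"
    MODERATELY_ORDERED = "ModeratelyOrderedOrMildlyFlexible"


class AdsTier(str, enum.Enum):
    """ADS-only disorder tiers."""

    HIGHLY_ORDERED = "HighlyOrdered"
    MODERATELY_DISORDERED = "ModeratelyDisordered"
    HIGHLY_DISORDERED = "HighlyDisordered"


TIER_ORDER = [
    Tier.HIGHLY_DISORDERED,
    Tier.HIGHLY_ORDERED,
    Tier.MODERATELY_DISORDERED,
    Tier.MODERATELY_ORDERED,
]


@dataclass(frozen=True)
class ClassificationThresholds:
    """Tier cut-offs.

    ``highly_disordered_rule`` selects how the top tier combines its two
    conditions: ``"or"`` (default; PPDR ≥ high or ADS ≥ high) or ``"and"``.
    The disjunctive form is the one consistent with published tier tables
    where the residual tier can be empty; the conjunctive form matches a
    stricter reading and is kept selectable.
    """

    ppdr_low: float = 10.0
    ppdr_high: float = 30.0
    ads_low: float = 0.15
    ads_high: float = 0.5
    highly_disordered_rule: str = "or"

    def __post_init__(self) -> None:
        if not (self.ppdr_low < self.ppdr_high):
            raise ValueError("require ppdr_low < ppdr_high")
        if not (self.ads_low < self.ads_high):
            raise ValueError("require ads_low < ads_high")
        if self.highly_disordered_rule not in ("or", "and"):
            raise ValueError("highly_disordered_rule must be 'or' or 'and'")


DEFAULT_THRESHOLDS = ClassificationThresholds()


@dataclass(frozen=True)
class DisorderSummary:
    """Per-protein ADS, PPDR, and tier labels."""

    protein_id: str
    ads: float
    ppdr: float
    tier: Tier
    ads_only_tier: AdsTier


def ads(profile: DisorderProfile) -> float:
    """Average disorder score: mean per-residue score."""
    return float(np.mean(profile.scores))


def ppdr(profile: DisorderProfile) -> float:
    """Percent of residues with score strictly above 0.5."""
    return float(100.0 * np.count_nonzero(profile.scores > 0.5) / len(profile))


def classify_two_axis(
    ads_value: float,
    ppdr_value: float,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> Tier:
    """Assign the two-axis tier for one protein.

    Rules are applied in order, so every (ADS, PPDR) pair maps to exactly
    one tier:

    1. HighlyDisordered if PPDR ≥ 30 or ADS ≥ 0.5 (``"and"`` rule: both);
    2. HighlyOrdered if PPDR < 10 and ADS < 0.15;
    3. ModeratelyDisordered if 10 ≤ PPDR < 30 and 0.15 ≤ ADS < 0.5;
    4. otherwise ModeratelyOrderedOrMildlyFlexible (the residual tier for
       discordant axis combinations).
    """
    t = thresholds
    if not (0.0 <= ads_value <= 1.0):
        raise ValueError(f"ADS out of range: {ads_value}")
    if not (0.0 <= ppdr_value <= 100.0):
        raise ValueError(f"PPDR out of range: {ppdr_value}")
    hd_ppdr = ppdr_value >= t.ppdr_high
    hd_ads = ads_value >= t.ads_high
    if (hd_ppdr or hd_ads) if t.highly_disordered_rule == "or" else (hd_ppdr and hd_ads):
        return Tier.HIGHLY_DISORDERED
    if ppdr_value < t.ppdr_low and ads_value < t.ads_low:
        return Tier.HIGHLY_ORDERED
    if t.ppdr_low <= ppdr_value < t.ppdr_high and t.ads_low <= ads_value < t.ads_high:
        return Tier.MODERATELY_DISORDERED
    return Tier.MODERATELY_ORDERED


def classify_ads_only(
    ads_value: float,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> AdsTier:
    """Three-way split on ADS alone: < 0.15 / [0.15, 0.5) / ≥ 0.5."""
    if not (0.0 <= ads_value <= 1.0):
        raise ValueError(f"ADS out of range: {ads_value}")
    if ads_value < thresholds.ads_low:
        return AdsTier.HIGHLY_ORDERED
    if ads_value < thresholds.ads_high:
        return AdsTier.MODERATELY_DISORDERED
    return AdsTier.HIGHLY_DISORDERED


def summarize_protein(
    profile: DisorderProfile,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> DisorderSummary:
    a, p = ads(profile), ppdr(profile)
    return DisorderSummary(
        protein_id=profile.protein_id,
        ads=a,
        ppdr=p,
        tier=classify_two_axis(a, p, thresholds),
        ads_only_tier=classify_ads_only(a, thresholds),
    )


def tier_percentages(counts: Mapping[Tier | str, int]) -> dict[str, float]:
    """Percentages per tier, denominator = sum of the tier counts, 2 decimals."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("tier counts sum to zero")
    return {
        (k.value if isinstance(k, Tier) else str(k)): round(100.0 * v / total, 2)
        for k, v in counts.items()
    }


def proteome_summary(
    proteome: Proteome,
    profiles: Mapping[str, DisorderProfile],
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> dict:
    """Summarize one proteome: per-protein table, tier counts/shares, means.

    Returns a dict with keys ``table`` (per-protein DataFrame with ads, ppdr,
    tier), ``counts`` (tier → n), ``percentages`` (tier → % of summed
    counts, 2 decimals), ``mean_ads`` and ``mean_ppdr`` (means over
    proteins).
    """
    missing = [r.id for r in proteome if r.id not in profiles]
    if missing:
        raise KeyError(f"missing profiles for {len(missing)} proteins, e.g. {missing[:3]}")
    rows = [summarize_protein(profiles[r.id], thresholds) for r in proteome]
    table = pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in rows],
            "ads": [s.ads for s in rows],
            "ppdr": [s.ppdr for s in rows],
            "tier": [s.tier.value for s in rows],
            "ads_only_tier": [s.ads_only_tier.value for s in rows],
        }
    )
    counts = {t: int((table["tier"] == t.value).sum()) for t in TIER_ORDER}
    return {
        "name": proteome.name,
        "n": len(proteome),
        "table": table,
        "counts": counts,
        "percentages": tier_percentages(counts),
        "mean_ads": float(table["ads"].mean()),
        "mean_ppdr": float(table["ppdr"].mean()),
    }
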