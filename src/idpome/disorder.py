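"""Per-residue intrinsic-disorder profiles.

Two sequence-only predictors are built in, both emitting scores in [0, 1]
with the usual 0.5 order/disorder midpoint:

``foldindex``
    A windowed charge–hydropathy discriminant. For the window centred at
    residue i, ``FI_i = 2.785·<H>_i − |<R>|_i − 1.151`` where ``<H>`` is the
    mean min–max-normalized Kyte–Doolittle hydropathy and ``|<R>|`` the
    absolute mean net charge (K, R = +1; D, E = −1; H uncharged at pH 7).
    Negative FI marks the disordered side; the profile maps it to
    ``s_i = clip(0.5 − FI_i/2, 0, 1)`` so that FI = 0 lands exactly on 0.5.

``topidp``
    A windowed mean of the TOP-IDP per-residue disorder propensity scale,
    min–max normalized over the 20 residues.

Windows are centred and truncated at the termini (no virtual residues).
External per-residue score tables plug into the same registry, so any
trained predictor's output can stand in for the built-ins downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "KYTE_DOOLITTLE",
    "TOP_IDP",
    "DisorderProfile",
    "normalized_hydropathy",
    "window_net_charge",
    "foldindex_profile",
    "propensity_profile",
    "consensus_profile",
    "register_predictor",
    "get_predictor",
    "list_predictors",
    "table_predictor",
]

#: Kyte–Doolittle residue hydropathy (raw scale, −4.5 … 4.5).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: TOP-IDP disorder propensity scale (higher = more disorder-prone).
TOP_IDP: dict[str, float] = {
    "A": 0.06, "R": 0.180, "N": 0.007, "D": 0.192, "C": 0.02,
    "Q": 0.318, "E": 0.736, "G": 0.166, "H": 0.303, "I": -0.486,
    "L": -0.326, "K": 0.586, "M": -0.397, "F": -0.697, "P": 0.987,
    "S": 0.341, "T": 0.059, "W": -0.884, "Y": -0.510, "V": -0.121,
}

#: Formal residue charge at pH 7 (histidine treated as uncharged).
RESIDUE_CHARGE: dict[str, float] = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

# CH-plot discriminant constants (slope, intercept) of the boundary line
# separating compact from natively unfolded proteins in (hydropathy, charge)
# space; shared by foldindex_profile and chcdf.ch_score.
CH_SLOPE = 2.785
CH_INTERCEPT = 1.151

_KD_MIN = min(KYTE_DOOLITTLE.values())
_KD_SPAN = max(KYTE_DOOLITTLE.values()) - _KD_MIN
NORMALIZED_KD: dict[str, float] = {
    aa: (v - _KD_MIN) / _KD_SPAN for aa, v in KYTE_DOOLITTLE.items()
}

DEFAULT_WINDOW = 21


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder scores in [0, 1] for one protein, one predictor."""

    protein_id: str
    scores: np.ndarray
    predictor: str

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1 or scores.size == 0:
            raise ValueError("scores must be a non-empty 1-D array")
        if scores.min() < 0.0 or scores.max() > 1.0:
            raise ValueError("disorder scores must lie in [0, 1]")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.scores)


def _check_window(window: int) -> None:
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")


def _residue_values(sequence: str, scale: Mapping[str, float]) -> np.ndarray:
    try:
        return np.array([scale[aa] for aa in sequence], dtype=float)
    except KeyError as err:
        raise ValueError(f"residue {err.args[0]!r} not covered by the scale") from None


def _sliding_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with windows truncated at the termini."""
    n = len(values)
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def normalized_hydropathy(sequence: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Windowed mean of min–max-normalized Kyte–Doolittle hydropathy, in [0, 1]."""
    _check_window(window)
    return _sliding_mean(_residue_values(sequence, NORMALIZED_KD), window)


def window_net_charge(sequence: str, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Windowed absolute mean net charge (K,R = +1; D,E = −1), in [0, 1]."""
    _check_window(window)
    charges = np.array([RESIDUE_CHARGE.get(aa, 0.0) for aa in sequence])
    return np.abs(_sliding_mean(charges, window))


def foldindex_profile(
    sequence: str,
    protein_id: str = "",
    window: int = DEFAULT_WINDOW,
) -> DisorderProfile:
    """Windowed charge–hydropathy disorder profile (see module docstring)."""
    h = normalized_hydropathy(sequence, window)
    r = window_net_charge(sequence, window)
    fi = CH_SLOPE * h - r - CH_INTERCEPT
    scores = np.clip(0.5 - fi / 2.0, 0.0, 1.0)
    return DisorderProfile(protein_id, scores, "foldindex")


def propensity_profile(
    sequence: str,
    protein_id: str = "",
    scale: Mapping[str, float] | None = None,
    window: int = DEFAULT_WINDOW,
) -> DisorderProfile:
    """Windowed, min–max-normalized disorder-propensity profile.

    *scale* maps each residue to a propensity (default: TOP-IDP). The scale
    is normalized over its own range, so the most disorder-prone homopolymer
    scores 1.0 and the least scores 0.0.
    """
    _check_window(window)
    if scale is None:
        scale = TOP_IDP
    lo, hi = min(scale.values()), max(scale.values())
    if hi <= lo:
        raise ValueError("degenerate propensity scale")
    values = (_residue_values(sequence, scale) - lo) / (hi - lo)
    return DisorderProfile(protein_id, _sliding_mean(values, window), "topidp")


def consensus_profile(
    profiles: Sequence[DisorderProfile],
    weights: Sequence[float] | None = None,
) -> DisorderProfile:
    """Per-residue weighted mean of several profiles of the same protein.

    The analogue of running a panel of per-residue predictors and averaging:
    permutation-invariant, identity for a single profile, bounded in [0, 1].
    """
    if not profiles:
        raise ValueError("need at least one profile")
    n = len(profiles[0])
    pid = profiles[0].protein_id
    for p in profiles:
        if len(p) != n:
            raise ValueError("profile length mismatch")
        if p.protein_id != pid:
            raise ValueError("profiles refer to different proteins")
    if weights is None:
        weights = [1.0] * len(profiles)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(profiles) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    stacked = np.stack([p.scores for p in profiles])
    scores = (w[:, None] * stacked).sum(axis=0) / w.sum()
    return DisorderProfile(pid, scores, "consensus")


# ---------------------------------------------------------------------------
# Predictor registry

Predictor = Callable[..., DisorderProfile]

_REGISTRY: dict[str, Predictor] = {
    "foldindex": foldindex_profile,
    "topidp": propensity_profile,
}


def register_predictor(name: str, fn: Predictor) -> None:
    """Register a callable ``fn(sequence, protein_id, **kwargs) -> DisorderProfile``."""
    _REGISTRY[name] = fn


def get_predictor(name: str) -> Predictor:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown predictor {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def list_predictors() -> list[str]:
    return sorted(_REGISTRY)


def table_predictor(
    scores: Mapping[str, np.ndarray], name: str = "external"
) -> Predictor:
    """Wrap a per-residue score table (id → vector) as a registry predictor.

    Lets externally computed predictor outputs (read via
    :func:`idpome.io.read_score_table`) substitute for the built-ins. The
    returned callable checks that the stored vector matches the sequence
    length.
    """

    def predict(sequence: str, protein_id: str = "", **_: object) -> DisorderProfile:
        try:
            vec = scores[protein_id]
        except KeyError:
            raise KeyError(f"no external scores for protein {protein_id!r}") from None
        if len(vec) != len(sequence):
            raise ValueError(
                f"{protein_id}: table has {len(vec)} scores for a "
                f"{len(sequence)}-residue sequence"
            )
        return DisorderProfile(protein_id, np.asarray(vec, float), name)

    return predict
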