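"""Seeded synthetic proteomes with known order/disorder/LLPS composition.

Real comparative studies start from curated FASTA sets; this module
generates stand-ins with controllable structure so every pipeline stage is
testable end to end. Sequences come in four archetypes:

* ``ORDERED`` — hydrophobic-rich i.i.d. composition (I/L/V/F/A-weighted),
  emulating compact globular proteins: high mean hydropathy, low net
  charge, CH on the ordered side.
* ``DISORDERED`` — polar/charged low-hydrophobicity composition
  (P/E/S/K/Q/G-rich), emulating extended IDPs: CH on the disordered side,
  high per-residue disorder scores.
* ``PS_PRONE`` — sticker blocks (RG/SY/FG-style) interleaved with short
  polar spacers, emulating phase-separating low-complexity regions:
  disordered *and* sticker-rich, so sliding-window LLPS detection fires.
* ``MIXED`` — an ordered and a disordered segment concatenated, emulating
  a folded domain with a long IDR tail.

The i.i.d.-plus-blocks design is deliberate: downstream analyses consume
only composition- and window-level signals, so no higher-order sequence
structure is modelled. One integer seed drives a splittable RNG stream per
protein, making any subset reproducible in isolation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import Proteome, ProteinRecord

__all__ = [
    "Archetype",
    "ArchetypeSpec",
    "SyntheticProteomeSpec",
    "generate_sequence",
    "generate_proteome",
    "generate_reference_sets",
]


class Archetype(str, enum.Enum):
    ORDERED = "ORDERED"
    DISORDERED = "DISORDERED"
    PS_PRONE = "PS_PRONE"
    MIXED = "MIXED"


#: Default i.i.d. residue compositions (normalized at use).
COMPOSITIONS: dict[Archetype, dict[str, float]] = {
    Archetype.ORDERED: {
        "I": 0.13, "L": 0.15, "V": 0.12, "F": 0.07, "A": 0.12, "M": 0.04,
        "W": 0.02, "G": 0.05, "T": 0.06, "S": 0.04, "Y": 0.03, "C": 0.03,
        "N": 0.03, "P": 0.02, "D": 0.025, "E": 0.025, "K": 0.02, "R": 0.02,
        "Q": 0.015, "H": 0.015,
    },
    Archetype.DISORDERED: {
        "P": 0.16, "E": 0.20, "S": 0.11, "K": 0.16, "Q": 0.07, "G": 0.09,
        "D": 0.06, "A": 0.06, "T": 0.04, "N": 0.03, "R": 0.02,
    },
}

#: PS_PRONE block compositions: sticker blocks and polar spacers.
_STICKER_BLOCK = {"R": 0.30, "G": 0.25, "Y": 0.15, "S": 0.10, "F": 0.10, "Q": 0.10}
_SPACER_BLOCK = {"G": 0.30, "S": 0.30, "P": 0.20, "N": 0.10, "Q": 0.10}
_STICKER_LEN, _SPACER_LEN = 6, 3


@dataclass(frozen=True)
class ArchetypeSpec:
    """One archetype with a length range and (optional) custom composition."""

    archetype: Archetype
    length_range: tuple[int, int] = (100, 400)
    composition: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 30 or hi < lo:
            raise ValueError("length range must satisfy 30 <= min <= max")
        if self.composition is not None:
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition probabilities sum to {total}, not 1")
            if any(p < 0 for p in self.composition.values()):
                raise ValueError("composition probabilities must be non-negative")


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """A mixture of archetypes, a protein count, and a seed."""

    n: int
    mixture: Mapping[Archetype, float]
    seed: int
    length_range: tuple[int, int] = (100, 400)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {total}, not 1")
        if any(f < 0 for f in self.mixture.values()):
            raise ValueError("mixture fractions must be non-negative")


def _normalized(composition: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    residues = sorted(composition)
    probs = np.array([composition[aa] for aa in residues], float)
    return residues, probs / probs.sum()


def _sample_iid(
    composition: Mapping[str, float], length: int, rng: np.random.Generator
) -> str:
    residues, probs = _normalized(composition)
    return "".join(rng.choice(residues, size=length, p=probs))


def generate_sequence(spec: ArchetypeSpec, rng: np.random.Generator) -> str:
    """Draw one sequence: length uniform over the range, residues per archetype."""
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    if spec.composition is not None:
        return _sample_iid(spec.composition, length, rng)
    arch = spec.archetype
    if arch in (Archetype.ORDERED, Archetype.DISORDERED):
        return _sample_iid(COMPOSITIONS[arch], length, rng)
    if arch is Archetype.PS_PRONE:
        parts: list[str] = []
        total = 0
        while total < length:
            parts.append(_sample_iid(_STICKER_BLOCK, _STICKER_LEN, rng))
            parts.append(_sample_iid(_SPACER_BLOCK, _SPACER_LEN, rng))
            total += _STICKER_LEN + _SPACER_LEN
        return "".join(parts)[:length]
    if arch is Archetype.MIXED:
        half = length // 2
        ordered = _sample_iid(COMPOSITIONS[Archetype.ORDERED], half, rng)
        disordered = _sample_iid(
            COMPOSITIONS[Archetype.DISORDERED], length - half, rng
        )
        return ordered + disordered
    raise ValueError(f"unknown archetype {arch!r}")


def _largest_remainder(n: int, fractions: Mapping[Archetype, float]) -> dict[Archetype, int]:
    """Apportion n among archetypes by largest remainder; ties by enum order."""
    items = sorted(fractions.items(), key=lambda kv: list(Archetype).index(kv[0]))
    exact = [(arch, n * frac) for arch, frac in items]
    counts = {arch: int(np.floor(x)) for arch, x in exact}
    remainder = n - sum(counts.values())
    by_frac = sorted(exact, key=lambda kv: kv[1] - np.floor(kv[1]), reverse=True)
    for arch, _ in by_frac[:remainder]:
        counts[arch] += 1
    return counts


def generate_proteome(
    spec: SyntheticProteomeSpec, name: str = "synthetic"
) -> tuple[Proteome, dict[str, Archetype]]:
    """Generate a proteome and its ground-truth archetype labels.

    Archetype counts follow the mixture exactly after largest-remainder
    rounding; record order is shuffled so ids carry no label information.
    Ids are ``SYN000001``-style; the labels are returned separately.
    """
    counts = _largest_remainder(spec.n, spec.mixture)
    assignment = [arch for arch, c in counts.items() for _ in range(c)]
    root = np.random.SeedSequence(spec.seed)
    shuffle_rng = np.random.default_rng(root.spawn(1)[0])
    shuffle_rng.shuffle(assignment)
    children = root.spawn(spec.n + 1)[1:]
    records, labels = [], {}
    for i, (arch, child) in enumerate(zip(assignment, children)):
        rng = np.random.default_rng(child)
        seq = generate_sequence(ArchetypeSpec(arch, spec.length_range), rng)
        pid = f"SYN{i + 1:06d}"
        records.append(ProteinRecord(pid, seq))
        labels[pid] = arch
    return Proteome(name, records), labels


#: Fixed seed for the shipped calibration reference sets.
REFERENCE_SEED = 271828


def generate_reference_sets(
    n_each: int = 200,
    seed: int = REFERENCE_SEED,
    length_range: tuple[int, int] = (100, 400),
) -> tuple[Proteome, Proteome]:
    """Reproducible ordered/disordered calibration proteomes (default 200 + 200).

    These feed :func:`idpome.chcdf.calibrate_cdf_boundary`; regenerating
    with the same package version yields identical sequences.
    """
    ordered, _ = generate_proteome(
        SyntheticProteomeSpec(n_each, {Archetype.ORDERED: 1.0}, seed, length_range),
        name="reference_ordered",
    )
    disordered, _ = generate_proteome(
        SyntheticProteomeSpec(
            n_each, {Archetype.DISORDERED: 1.0}, seed + 1, length_range
        ),
        name="reference_disordered",
    )
    return ordered, disordered


def write_labels(labels: Mapping[str, Archetype], path) -> None:
    """Write ground-truth labels as a two-column TSV (id, archetype)."""
    with open(path, "w") as fh:
        for pid, arch in labels.items():
            fh.write(f"{pid}\t{arch.value}\n")
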