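"""Proteome FASTA I/O, external score tables, and overlap splits.

A *proteome* here is simply a named, ordered collection of protein records
(accession + amino-acid sequence) — the unit of comparison throughout the
package. Sequences are restricted to the canonical 20-letter alphabet;
records carrying ambiguous or non-standard residues (B, Z, U, O, X, gaps)
are skipped and logged by default, because every downstream score is a
function of residue composition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "Proteome",
    "OverlapResult",
    "RunLog",
    "SequenceError",
    "validate_sequence",
    "read_fasta",
    "write_fasta",
    "read_score_table",
    "overlap_split",
]

#: Canonical 20-letter amino-acid alphabet.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


class SequenceError(ValueError):
    """Raised for empty or non-canonical amino-acid sequences."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession-like id plus a validated uppercase sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """A named, ordered collection of protein records with distinct ids."""

    name: str
    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate protein id {rec.id!r} in proteome {self.name!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        for rec in self.records:
            if rec.id == protein_id:
                return rec
        raise KeyError(protein_id)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def sequences(self) -> dict[str, str]:
        return {rec.id: rec.sequence for rec in self.records}


@dataclass(frozen=True)
class OverlapResult:
    """Partition of a test proteome's ids against a reference proteome."""

    overlap_ids: frozenset[str]
    unique_ids: frozenset[str]

    @property
    def n_overlap(self) -> int:
        return len(self.overlap_ids)

    @property
    def n_unique(self) -> int:
        return len(self.unique_ids)


class RunLog:
    """Plain-text run log: one line per skipped or filtered record."""

    def __init__(self) -> None:
        self.events: list[tuple[str, str]] = []

    def skip(self, record_id: str, reason: str) -> None:
        self.events.append((record_id, reason))

    def __len__(self) -> int:
        return len(self.events)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for record_id, reason in self.events:
                fh.write(f"{record_id}\t{reason}\n")


def validate_sequence(raw: str) -> str:
    """Uppercase and validate an amino-acid sequence.

    Raises :class:`SequenceError` if the sequence is empty or contains any
    character outside the canonical 20-letter alphabet (ambiguity codes,
    selenocysteine/pyrrolysine, gaps, ...). Callers that prefer skip-and-log
    semantics catch the error and record the skip.
    """
    if not raw:
        raise SequenceError("empty sequence")
    seq = raw.upper()
    bad = set(seq) - _AA_SET
    if bad:
        raise SequenceError(f"non-canonical residues {sorted(bad)}")
    return seq


def _header_id(header: str) -> str:
    """First whitespace token of a FASTA header; UniProt 'sp|ACC|NAME' → ACC."""
    token = header.split()[0] if header.split() else header
    m = _UNIPROT_HEADER.match(token)
    return m.group(1) if m else token


def read_fasta(
    path: str | Path,
    name: str | None = None,
    *,
    strict: bool = False,
    log: RunLog | None = None,
) -> Proteome:
    """Read a proteome from a FASTA file.

    Ids are the first whitespace-delimited header token, with UniProt-style
    ``sp|ACC|NAME`` headers reduced to the accession. In the default lenient
    mode, records with non-canonical residues are skipped and recorded in
    *log*; with ``strict=True`` they raise.

    Raises on a missing or empty file and on duplicate ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = _header_id(entry.description or entry.id)
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        try:
            rec = ProteinRecord(pid, str(entry.seq))
        except SequenceError as err:
            if strict:
                raise SequenceError(f"{pid}: {err}") from err
            if log is not None:
                log.skip(pid, f"invalid sequence: {err}")
            continue
        seen.add(pid)
        records.append(rec)
    if not records:
        raise ValueError(f"no valid FASTA records in {path}")
    return Proteome(name or path.stem, records)


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    """Write a proteome as plain FASTA, wrapping sequences at *width*."""
    with open(path, "w") as fh:
        for rec in proteome:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_score_table(
    path: str | Path,
    kind: str,
    *,
    unit_interval: bool = True,
) -> dict[str, float] | dict[str, np.ndarray]:
    """Read an external predictor's scores from a tab-separated table.

    ``kind="per_protein"`` expects columns (id, score) and returns
    ``{id: float}``. ``kind="per_residue"`` expects (id, position, score)
    with 1-based contiguous positions per id and returns ``{id: ndarray}``.
    With ``unit_interval=True`` (the default, appropriate for disorder
    scores) scores outside [0, 1] are rejected.
    """
    if kind not in ("per_protein", "per_residue"):
        raise ValueError(f"unknown score-table kind {kind!r}")
    ncols = 2 if kind == "per_protein" else 3
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != ncols:
        raise ValueError(f"{kind} table must have {ncols} columns, found {df.shape[1]}")
    if kind == "per_protein":
        df.columns = ["id", "score"]
    else:
        df.columns = ["id", "position", "score"]
    scores = pd.to_numeric(df["score"], errors="raise").to_numpy(float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite score in table")
    if unit_interval and (scores.min() < 0.0 or scores.max() > 1.0):
        raise ValueError("disorder scores must lie in [0, 1]")
    if kind == "per_protein":
        if df["id"].duplicated().any():
            raise ValueError("duplicate protein id in per-protein table")
        return dict(zip(df["id"].astype(str), scores))
    out: dict[str, np.ndarray] = {}
    for pid, grp in df.groupby("id", sort=False):
        pos = grp["position"].to_numpy(int)
        expected = np.arange(1, len(pos) + 1)
        if not np.array_equal(np.sort(pos), expected):
            raise ValueError(f"{pid}: positions must be 1-based and contiguous")
        out[str(pid)] = grp.sort_values("position")["score"].to_numpy(float)
    return out


def overlap_split(test: Proteome, reference: Proteome) -> OverlapResult:
    """Split *test* ids into those present in *reference* and those unique.

    The two id sets partition the test proteome exactly:
    ``overlap ∪ unique = test.ids`` and ``overlap ∩ unique = ∅``.
    """
    ref_ids = set(reference.ids)
    test_ids = test.ids
    overlap = frozenset(i for i in test_ids if i in ref_ids)
    unique = frozenset(i for i in test_ids if i not in ref_ids)
    return OverlapResult(overlap, unique)
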