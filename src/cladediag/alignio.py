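"""Alignment and clade-map IO, residue normalisation, coordinate conventions.

Conventions used throughout the package
---------------------------------------
* Internally, alignment columns are 0-based half-open slices; every position
  in a report or on the command line is a 1-based inclusive alignment column.
* The residue alphabet is {A,C,G,T}, the IUPAC ambiguity letters, and the
  gap character ``-``. Input is normalised: lowercase is raised, RNA ``U``
  becomes ``T``, and the alternative gap glyphs ``.`` and ``~`` become ``-``.
* Leading and trailing gap runs in a row are treated as *missing data*
  (an incompletely sequenced molecule), not as indels. Internal gaps are
  real indels. Each row therefore has a coverage span
  ``[first_residue_column, last_residue_column]``; anything outside it does
  not count as evidence for or against a motif.
* Sequence ids absent from the clade map are kept and act as out-clade
  background for every clade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import iupac
from .errors import (
    DuplicateAssignmentError,
    DuplicateIdError,
    IllegalResidueError,
    RaggedAlignmentError,
    UnknownSequenceError,
)

__all__ = [
    "AlignedSequence",
    "Alignment",
    "CladePartition",
    "normalize_residues",
    "read_alignment",
    "write_alignment",
    "read_clade_map",
    "write_clade_map",
]

_NORMALIZE = str.maketrans({"u": "T", "U": "T", ".": "-", "~": "-"})


def normalize_residues(raw: str, context: str = "") -> str:
    """Uppercase, map U->T and ./~ -> '-', and validate the alphabet.

    Raises :class:`IllegalResidueError` (with the 1-based offending
    position) on any character outside the IUPAC DNA alphabet plus gap.
    """
    if not raw:
        raise IllegalResidueError("", 0, context or "empty sequence")
    out = raw.translate(_NORMALIZE).upper()
    for i, ch in enumerate(out):
        if ch not in iupac.ALPHABET:
            raise IllegalResidueError(raw[i], i + 1, context)
    return out


@dataclass(frozen=True)
class AlignedSequence:
    """One row of an alignment: an id and its (gapped) residues."""

    id: str
    residues: str
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


class Alignment:
    """An equal-length, gapped multiple sequence alignment.

    Provides the numeric views the screen works on: a mask matrix
    (rows x columns of 4-bit residue masks, 0 for gap) and per-row
    coverage spans implementing the terminal-missing-data convention.
    """

    def __init__(self, sequences: Iterable[AlignedSequence]):
        seqs = list(sequences)
        if len(seqs) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        lengths = {s.id: len(s.residues) for s in seqs}
        if len(lengths) != len(seqs):
            seen: set[str] = set()
            for s in seqs:
                if s.id in seen:
                    raise DuplicateIdError(f"duplicate sequence id {s.id!r}")
                seen.add(s.id)
        if len(set(lengths.values())) != 1:
            raise RaggedAlignmentError(lengths)
        self.sequences: list[AlignedSequence] = seqs
        self.n_columns: int = len(seqs[0].residues)
        self._index: dict[str, int] = {s.id: i for i, s in enumerate(seqs)}
        self._masks: np.ndarray | None = None
        self._spans: np.ndarray | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[AlignedSequence]:
        return iter(self.sequences)

    def __getitem__(self, seq_id: str) -> AlignedSequence:
        try:
            return self.sequences[self._index[seq_id]]
        except KeyError:
            raise UnknownSequenceError(f"no sequence {seq_id!r} in alignment") from None

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def row_index(self, seq_id: str) -> int:
        try:
            return self._index[seq_id]
        except KeyError:
            raise UnknownSequenceError(f"no sequence {seq_id!r} in alignment") from None

    # -- numeric views -------------------------------------------------------
    @property
    def mask_matrix(self) -> np.ndarray:
        """(n_seq, n_columns) uint8 matrix of IUPAC masks; gap -> 0."""
        if self._masks is None:
            self._masks = np.vstack(
                [iupac.masks_from_string(s.residues) for s in self.sequences]
            )
        return self._masks

    @property
    def coverage_spans(self) -> np.ndarray:
        """(n_seq, 2) int array of [first, last] residue columns (0-based).

        A row that is entirely gaps gets the empty span [n_columns, -1].
        """
        if self._spans is None:
            m = self.mask_matrix
            nz = m != 0
            any_res = nz.any(axis=1)
            first = np.where(any_res, nz.argmax(axis=1), self.n_columns)
            last = np.where(
                any_res, self.n_columns - 1 - nz[:, ::-1].argmax(axis=1), -1
            )
            self._spans = np.stack([first, last], axis=1).astype(np.int64)
        return self._spans

    def covers(self, seq_id: str, start: int, length: int) -> bool:
        """True if the row's coverage span contains [start, start+length)."""
        first, last = self.coverage_spans[self.row_index(seq_id)]
        return bool(first <= start and last >= start + length - 1)


@dataclass
class CladePartition:
    """A map from sequence id to clade label.

    Ids missing from the map are legal: they are out-clade background for
    every clade (the screen never focuses on them).
    """

    assignments: dict[str, str] = field(default_factory=dict)

    @property
    def clades(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.assignments.values():
            seen.setdefault(label)
        return list(seen)

    def members(self, clade: str) -> list[str]:
        if clade not in set(self.assignments.values()):
            raise KeyError(f"unknown clade {clade!r}")
        return [i for i, c in self.assignments.items() if c == clade]

    def validate_against(self, alignment: Alignment) -> None:
        missing = [i for i in self.assignments if i not in alignment]
        if missing:
            raise UnknownSequenceError(
                f"clade map references absent sequence ids: {missing}"
            )


# -- FASTA -------------------------------------------------------------------

def read_alignment(path: str | Path, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA into an :class:`Alignment`.

    The id is the first whitespace token of the header; the remainder is
    kept as ``source_note``. Residues are normalised and validated.
    """
    if fmt != "fasta":
        raise ValueError(f"unsupported alignment format {fmt!r}")
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        note = rec.description[len(rec.id):].strip() if rec.description else ""
        seqs.append(
            AlignedSequence(
                id=rec.id,
                residues=normalize_residues(str(rec.seq), context=rec.id),
                source_note=note,
            )
        )
    return Alignment(seqs)


def write_alignment(alignment: Alignment, path: str | Path, wrap: int = 80) -> None:
    """Write the alignment as FASTA, wrapped at ``wrap`` columns."""
    records = [
        SeqRecord(
            Seq(s.residues),
            id=s.id,
            description=s.source_note,
        )
        for s in alignment
    ]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read unaligned FASTA as an ordered id -> normalised residues map."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r}")
        out[rec.id] = normalize_residues(str(rec.seq), context=rec.id)
    return out


# -- clade map TSV -----------------------------------------------------------

def read_clade_map(path: str | Path) -> CladePartition:
    """Read a two-column TSV ``sequence_id<TAB>clade``.

    A header row naming the two columns is accepted and skipped. Rows with
    an empty clade field leave the sequence unassigned (out-clade
    everywhere). Conflicting duplicate rows raise
    :class:`DuplicateAssignmentError`.
    """
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            seq_id = parts[0].strip()
            clade = parts[1].strip() if len(parts) > 1 else ""
            if lineno == 1 and seq_id.lower() == "sequence_id":
                continue
            if seq_id in assignments:
                if assignments[seq_id] != clade:
                    raise DuplicateAssignmentError(
                        f"{seq_id!r} assigned to both {assignments[seq_id]!r} "
                        f"and {clade!r} (line {lineno})"
                    )
                continue
            if clade:
                assignments[seq_id] = clade
    return CladePartition(assignments)


def write_clade_map(partition: CladePartition, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("sequence_id\tclade\n")
        for seq_id, clade in partition.assignments.items():
            fh.write(f"{seq_id}\t{clade}\n")
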