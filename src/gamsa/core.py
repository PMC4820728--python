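"""Core domain types: protein sequences, sequence sets, and gapped alignments.

An :class:`Alignment` is both the aligner's output and the GA chromosome.
A valid chromosome satisfies three conditions: all rows share one width,
stripping gaps from row *i* reproduces input sequence *i* exactly, and no
column consists solely of gaps.  Alignments read from files relax the
third condition (foreign references may carry all-gap columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .errors import AlphabetError, ContractError, CorruptionError, DuplicateIdError

#: The 20-letter amino-acid alphabet.
ALPHABET = frozenset("EPACGQVMTRKWYDNHSFLI")

#: The gap character.
GAP = "-"


def _check_residues(residues: str, seq_id: str) -> None:
    for pos, ch in enumerate(residues):
        if ch not in ALPHABET:
            raise AlphabetError(
                f"record {seq_id!r}: invalid symbol {ch!r} at position {pos + 1} "
                f"(allowed: 20 standard amino acids)"
            )


@dataclass(frozen=True)
class ProteinSequence:
    """A named, ungapped amino-acid sequence.

    Residues are normalized to uppercase; the gap character and ambiguity
    codes (B, Z, X, U) are rejected.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ContractError("sequence identifier must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ContractError(f"record {self.id!r}: empty sequence")
        _check_residues(self.residues, self.id)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SequenceSet:
    """An ordered collection of protein sequences with unique identifiers."""

    sequences: tuple[ProteinSequence, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        if len(self.sequences) < 2:
            raise ContractError(
                f"alignment needs at least 2 sequences, got {len(self.sequences)}"
            )
        seen: set[str] = set()
        for seq in self.sequences:
            if seq.id in seen:
                raise DuplicateIdError(f"duplicate sequence id {seq.id!r}")
            seen.add(seq.id)
        if len(self.sequences) < 3:
            warnings.warn(
                "only 2 sequences given; a multiple alignment normally has >= 3",
                stacklevel=3,
            )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def n_max(self) -> int:
        """Length of the longest sequence."""
        return max(len(s) for s in self.sequences)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sequences)

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


class Alignment:
    """A matrix of equal-length gapped rows over the amino-acid alphabet.

    Parameters
    ----------
    rows:
        Gapped strings, one per source sequence, in source order.
    source:
        The :class:`SequenceSet` the rows encode.  If omitted it is derived
        by stripping gaps from the rows (used when reading reference
        alignments from files).
    strict:
        When true (the default, and mandatory inside the GA) an all-gap
        column is an invariant violation.  File readers pass ``strict=False``
        because foreign reference alignments may legitimately contain
        all-gap columns; such columns never contribute to any score.
    """

    __slots__ = ("rows", "source", "_fitness")

    def __init__(
        self,
        rows: Sequence[str],
        source: SequenceSet | None = None,
        *,
        strict: bool = True,
    ) -> None:
        rows = tuple(r.upper() for r in rows)
        if not rows:
            raise ContractError("alignment must have at least one row")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise ContractError(
                f"ragged alignment: row lengths {sorted({len(r) for r in rows})}"
            )
        if width == 0:
            raise ContractError("alignment width must be positive")
        if source is None:
            source = SequenceSet(
                tuple(
                    ProteinSequence(f"seq{i + 1}", r.replace(GAP, ""))
                    for i, r in enumerate(rows)
                )
            )
        if len(rows) != source.n:
            raise ContractError(
                f"{len(rows)} rows for {source.n} source sequences"
            )
        for row, seq in zip(rows, source):
            decoded = row.replace(GAP, "")
            if decoded != seq.residues:
                raise CorruptionError(
                    f"row for {seq.id!r} decodes to {decoded!r}, "
                    f"expected {seq.residues!r}"
                )
            for ch in row:
                if ch != GAP and ch not in ALPHABET:
                    raise AlphabetError(
                        f"row for {seq.id!r}: invalid symbol {ch!r}"
                    )
        if strict:
            for c in range(width):
                if all(r[c] == GAP for r in rows):
                    raise ContractError(f"column {c + 1} contains only gaps")
        self.rows = rows
        self.source = source
        self._fitness: int | None = None

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return self.source.ids

    def decode(self) -> SequenceSet:
        """Return the ungapped source sequences (identity by construction)."""
        return self.source

    def copy(self) -> "Alignment":
        aln = Alignment(self.rows, self.source, strict=False)
        aln._fitness = self._fitness
        return aln

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.rows == other.rows and self.ids == other.ids

    def __hash__(self) -> int:
        return hash((self.rows, self.ids))

    def __repr__(self) -> str:
        return f"Alignment(n={self.n}, width={self.width})"
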