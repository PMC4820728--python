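"""Reading and writing FASTA and CLUSTAL files.

Parsing is delegated to Biopython (``Bio.SeqIO`` / ``Bio.AlignIO``); this
module layers the package's validation contracts on top: alphabet checks,
unique identifiers, equal gapped widths, and the distinction between
unaligned input (gaps forbidden) and alignments (gaps expected).

Dots ('.') are accepted as gap characters on input and normalized to '-'
with a warning, since some benchmark files use them interchangeably.
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GAP, Alignment, ProteinSequence, SequenceSet
from .errors import AlphabetError, ContractError, DuplicateIdError, FormatError

_FORMATS = ("fasta", "clustal")


def _normalize_gaps(text: str, seq_id: str) -> str:
    if "." in text:
        warnings.warn(
            f"record {seq_id!r}: '.' gap characters normalized to '-'",
            stacklevel=3,
        )
        text = text.replace(".", GAP)
    return text


def read_fasta(path: str | os.PathLike) -> SequenceSet:
    """Read unaligned protein sequences from a FASTA file.

    Gap characters in the input are an error: this reader is for the
    aligner's *input*, which must be ungapped.  Use :func:`read_alignment`
    for aligned FASTA.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    seqs = []
    for rec in records:
        text = _normalize_gaps(str(rec.seq), rec.id)
        if GAP in text:
            raise AlphabetError(
                f"record {rec.id!r} contains gap characters; "
                f"unaligned input must be gap-free"
            )
        seqs.append(ProteinSequence(rec.id, text))
    return SequenceSet(tuple(seqs))


def read_alignment(path: str | os.PathLike, format: str = "fasta") -> Alignment:
    """Read an alignment from an aligned-FASTA or CLUSTAL file.

    All rows must share one gapped width.  All-gap columns are tolerated
    (``strict=False``): reference alignments produced elsewhere may contain
    them, and they never affect downstream scores.
    """
    if format not in _FORMATS:
        raise FormatError(
            f"unknown alignment format {format!r}; expected one of {_FORMATS}"
        )
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(msa) == 0:
        raise FormatError(f"{path}: empty alignment")
    ids = [rec.id for rec in msa]
    if len(set(ids)) != len(ids):
        raise DuplicateIdError(f"{path}: duplicate record ids")
    rows = [_normalize_gaps(str(rec.seq).upper(), rec.id) for rec in msa]
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(
            f"{path}: ragged alignment, row lengths {sorted(widths)}"
        )
    source = SequenceSet(
        tuple(
            ProteinSequence(rec_id, row.replace(GAP, ""))
            for rec_id, row in zip(ids, rows)
        )
    )
    return Alignment(rows, source, strict=False)


def write_alignment(
    aln: Alignment, path: str | os.PathLike, format: str = "fasta"
) -> None:
    """Write an alignment as aligned FASTA (wrapped at 60 columns) or CLUSTAL.

    Round-trip law: ``read_alignment(write_alignment(a, f), f) == a``.
    """
    if format not in _FORMATS:
        raise FormatError(
            f"unknown alignment format {format!r}; expected one of {_FORMATS}"
        )
    if not isinstance(aln, Alignment):
        raise ContractError("write_alignment expects an Alignment")
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(row), id=seq_id, description="")
        for seq_id, row in zip(aln.ids, aln.rows)
    )
    with open(path, "w") as handle:
        AlignIO.write(msa, handle, format)


def write_fasta(seqs: SequenceSet | Iterable[ProteinSequence], path: str | os.PathLike) -> None:
    """Write ungapped sequences as FASTA (wrapped at 60 columns)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
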