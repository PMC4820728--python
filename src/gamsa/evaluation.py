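"""Reference-based alignment accuracy: SP and TC scores in [0, 1].

Both scores compare a test alignment against a trusted reference over the
same sequences, in the style of the BAliBase ``bali_score`` program.  Each
residue is identified by (sequence id, ordinal within the ungapped
sequence), which makes the scores independent of gap placement and of
all-gap columns in either alignment.

* SP score — the fraction of reference residue *pairs* (two residues
  sharing a reference column) that also share a column in the test
  alignment.
* TC score — the fraction of reference *columns* (those holding at least
  two residues) whose complete residue set is reunited in a single test
  column.

Reference columns with fewer than two residues carry no alignment
information and are excluded from both denominators.  Core-block
annotations are not used: every reference column is scored.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import GAP, Alignment
from .errors import ContractError

__all__ = ["EvalResult", "evaluate", "sp_score", "tc_score"]


@dataclass(frozen=True)
class EvalResult:
    """SP and TC accuracy of a test alignment against a reference."""

    sp_score: float
    tc_score: float
    n_ref_pairs: int
    n_ref_columns: int


def _check_comparable(test: Alignment, ref: Alignment) -> None:
    if set(test.ids) != set(ref.ids):
        raise ContractError(
            f"test and reference align different sequences: "
            f"{sorted(set(test.ids) ^ set(ref.ids))}"
        )
    test_seqs = {s.id: s.residues for s in test.source}
    for seq in ref.source:
        if test_seqs[seq.id] != seq.residues:
            raise ContractError(
                f"sequence {seq.id!r} differs between test and reference"
            )


def _column_map(aln: Alignment) -> dict[tuple[str, int], int]:
    """Map each residue key (sequence id, ordinal) to its column index."""
    where: dict[tuple[str, int], int] = {}
    for seq_id, row in zip(aln.ids, aln.rows):
        ordinal = 0
        for col, ch in enumerate(row):
            if ch != GAP:
                where[(seq_id, ordinal)] = col
                ordinal += 1
    return where


def _reference_columns(ref: Alignment) -> list[list[tuple[str, int]]]:
    """Residue keys per reference column, keeping columns with >= 2 residues."""
    columns: list[list[tuple[str, int]]] = [[] for _ in range(ref.width)]
    for seq_id, row in zip(ref.ids, ref.rows):
        ordinal = 0
        for col, ch in enumerate(row):
            if ch != GAP:
                columns[col].append((seq_id, ordinal))
                ordinal += 1
    return [col for col in columns if len(col) >= 2]


def evaluate(test: Alignment, ref: Alignment) -> EvalResult:
    """Compute SP and TC scores of ``test`` against ``ref`` in one pass."""
    _check_comparable(test, ref)
    test_col = _column_map(test)
    ref_columns = _reference_columns(ref)

    n_pairs = 0
    hit_pairs = 0
    n_columns = len(ref_columns)
    hit_columns = 0
    for keys in ref_columns:
        cols = [test_col[k] for k in keys]
        m = len(keys)
        n_pairs += m * (m - 1) // 2
        for i in range(m - 1):
            for j in range(i + 1, m):
                if cols[i] == cols[j]:
                    hit_pairs += 1
        if len(set(cols)) == 1:
            hit_columns += 1

    return EvalResult(
        sp_score=hit_pairs / n_pairs if n_pairs else 0.0,
        tc_score=hit_columns / n_columns if n_columns else 0.0,
        n_ref_pairs=n_pairs,
        n_ref_columns=n_columns,
    )


def sp_score(test: Alignment, ref: Alignment) -> float:
    """Fraction of reference residue pairs co-columned in the test alignment."""
    return evaluate(test, ref).sp_score


def tc_score(test: Alignment, ref: Alignment) -> float:
    """Fraction of scored reference columns fully recovered by the test."""
    return evaluate(test, ref).tc_score
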