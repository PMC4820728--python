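"""PAM250 pairwise symbol scoring and sum-of-pairs alignment fitness.

The score of a column pair (p, q) is

* ``matrix[p][q]``                    if p and q are both residues,
* ``penalty_sign * 2``                if p is a residue and q a gap,
* ``penalty_sign * 3``                if p is a gap and q a residue,
* ``penalty_sign * 1``                if both are gaps.

The residue/gap cases are deliberately asymmetric, so the pair order
convention matters: the row with the smaller index supplies p, the larger
supplies q.  Gap costs are flat per column (no opening/extension
distinction).  The penalties are magnitudes; with the default
``penalty_sign = -1`` they enter the fitness negatively, which matches the
maximization semantics of the GA (gaps cost, matches pay).

The alignment fitness is the sum of pairs: for every column and every
unordered row pair i < j, add the pair score.  Implemented with a single
(21 x 21) lookup table over numpy-encoded rows; a character-by-character
triple loop over (column, i, j) gives the same number and serves as the
test oracle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .core import ALPHABET, GAP, Alignment
from .errors import AlphabetError, ContractError

#: Canonical residue ordering used for matrix files and numpy encoding.
RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Code assigned to the gap character in numpy-encoded rows.
GAP_CODE = 20

_CODE_OF = {ch: i for i, ch in enumerate(RESIDUE_ORDER)}
_CODE_OF[GAP] = GAP_CODE


def load_matrix(path: str | os.PathLike) -> dict[tuple[str, str], int]:
    """Parse a whitespace-delimited NCBI/EMBOSS-style substitution matrix.

    Lines starting with '#' are comments; the first data line is the column
    header of single-letter residue codes; each further line is a row label
    followed by integer scores.  Only the 20 standard amino acids are kept
    (ambiguity columns such as B, Z, X, * are ignored if present).
    """
    with open(path) as handle:
        lines = [ln for ln in handle if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ContractError(f"{path}: empty matrix file")
    header = lines[0].split()
    matrix: dict[tuple[str, str], int] = {}
    for line in lines[1:]:
        parts = line.split()
        row_letter, values = parts[0].upper(), parts[1:]
        if len(values) != len(header):
            raise ContractError(
                f"{path}: row {row_letter!r} has {len(values)} entries, "
                f"expected {len(header)}"
            )
        if row_letter not in ALPHABET:
            continue
        for col_letter, value in zip(header, values):
            col_letter = col_letter.upper()
            if col_letter in ALPHABET:
                matrix[(row_letter, col_letter)] = int(value)
    missing = [
        (a, b)
        for a in RESIDUE_ORDER
        for b in RESIDUE_ORDER
        if (a, b) not in matrix
    ]
    if missing:
        raise ContractError(
            f"{path}: matrix incomplete, {len(missing)} residue pairs missing"
        )
    return matrix


def _bundled_pam250() -> dict[tuple[str, str], int]:
    with resources.as_file(
        resources.files("gamsa.data").joinpath("PAM250")
    ) as path:
        return load_matrix(path)


@dataclass(frozen=True)
class ScoringScheme:
    """A substitution matrix plus the three flat gap-penalty magnitudes.

    ``gap_residue_first`` prices (residue, gap) pairs, ``gap_residue_second``
    prices (gap, residue) pairs, and ``gap_gap`` prices (gap, gap) pairs.
    All three are non-negative magnitudes multiplied by ``penalty_sign``.
    """

    matrix: dict[tuple[str, str], int] = field(repr=False)
    gap_residue_first: int = 2
    gap_residue_second: int = 3
    gap_gap: int = 1
    penalty_sign: int = -1

    def __post_init__(self) -> None:
        if self.penalty_sign not in (-1, 1):
            raise ContractError("penalty_sign must be -1 or +1")
        if min(self.gap_residue_first, self.gap_residue_second, self.gap_gap) < 0:
            raise ContractError("gap penalty magnitudes must be non-negative")
        for a in RESIDUE_ORDER:
            for b in RESIDUE_ORDER:
                if self.matrix[(a, b)] != self.matrix[(b, a)]:
                    raise ContractError(
                        f"substitution matrix asymmetric at ({a}, {b})"
                    )

    @classmethod
    def default(cls, **kwargs) -> "ScoringScheme":
        """The PAM250 scheme with gap magnitudes 2 / 3 / 1, penalties negative."""
        return cls(matrix=_bundled_pam250(), **kwargs)

    @classmethod
    def from_file(cls, path: str | os.PathLike, **kwargs) -> "ScoringScheme":
        """Load an alternative substitution matrix (e.g. PAM120, BLOSUM62)."""
        return cls(matrix=load_matrix(path), **kwargs)

    def pair_table(self) -> np.ndarray:
        """The full (21 x 21) pair-score table over encoded symbols.

        Index 20 is the gap.  The table is asymmetric in its gap entries:
        ``table[res, gap] != table[gap, res]`` in general.
        """
        cached = getattr(self, "_table", None)
        if cached is None:
            table = np.zeros((21, 21), dtype=np.int64)
            for a, i in _CODE_OF.items():
                for b, j in _CODE_OF.items():
                    if a != GAP and b != GAP:
                        table[i, j] = self.matrix[(a, b)]
            table[:GAP_CODE, GAP_CODE] = self.penalty_sign * self.gap_residue_first
            table[GAP_CODE, :GAP_CODE] = self.penalty_sign * self.gap_residue_second
            table[GAP_CODE, GAP_CODE] = self.penalty_sign * self.gap_gap
            table.setflags(write=False)
            object.__setattr__(self, "_table", table)
            cached = table
        return cached


def pair_score(p: str, q: str, scheme: ScoringScheme) -> int:
    """Score one column pair (p, q); p comes from the lower-indexed row."""
    for sym in (p, q):
        if sym != GAP and sym not in ALPHABET:
            raise AlphabetError(f"invalid symbol {sym!r} in pair score")
    p_gap, q_gap = p == GAP, q == GAP
    if not p_gap and not q_gap:
        return scheme.matrix[(p, q)]
    if not p_gap and q_gap:
        return scheme.penalty_sign * scheme.gap_residue_first
    if p_gap and not q_gap:
        return scheme.penalty_sign * scheme.gap_residue_second
    return scheme.penalty_sign * scheme.gap_gap


def encode(aln: Alignment) -> np.ndarray:
    """Encode alignment rows as an (n, width) uint8 matrix of symbol codes."""
    return np.array(
        [[_CODE_OF[ch] for ch in row] for row in aln.rows], dtype=np.uint8
    )


def sp_fitness(aln: Alignment, scheme: ScoringScheme) -> int:
    """Sum-of-pairs fitness: total pair score over all columns and row pairs.

    The result is cached on the alignment; chromosomes are immutable so the
    cache never goes stale.
    """
    if aln._fitness is not None:
        cached_for, value = aln._fitness
        if cached_for is scheme:
            return value
    if aln.n < 2:
        raise ContractError("sum-of-pairs fitness needs at least 2 rows")
    table = scheme.pair_table()
    codes = encode(aln)
    total = 0
    for i in range(aln.n - 1):
        for j in range(i + 1, aln.n):
            total += int(table[codes[i], codes[j]].sum())
    aln._fitness = (scheme, total)
    return total
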