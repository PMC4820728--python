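"""Shared fixtures and independent oracles for the gamsa test suite.

The oracles here are deliberately naive re-implementations (character
loops, explicit pair enumeration) kept independent of the package's
vectorized / indexed code paths they are used to check.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pytest

from gamsa.core import GAP, Alignment, ProteinSequence, SequenceSet
from gamsa.ga_engine import GAConfig, init_population
from gamsa.scoring import ScoringScheme, pair_score

# 2-row alignments are legal but warn; tests use them freely.
warnings.filterwarnings(
    "ignore", message="only 2 sequences given", category=UserWarning
)

_RESIDUE_POOL = "EPACGQVMTRKWYDNHSFLI"


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    return ScoringScheme.default()


@pytest.fixture()
def toy_seqs() -> SequenceSet:
    return SequenceSet(
        (
            ProteinSequence("s1", "ACDE"),
            ProteinSequence("s2", "ACE"),
            ProteinSequence("s3", "CDE"),
        )
    )


def random_sequence_set(
    rng: np.random.Generator,
    n_range: tuple[int, int] = (2, 6),
    len_range: tuple[int, int] = (5, 30),
) -> SequenceSet:
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    seqs = []
    for i in range(n):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        letters = rng.choice(list(_RESIDUE_POOL), size=length)
        seqs.append(ProteinSequence(f"s{i + 1}", "".join(letters)))
    return SequenceSet(tuple(seqs))


def random_alignment(rng: np.random.Generator, **kwargs) -> Alignment:
    """One random valid chromosome over a random sequence set."""
    seqs = random_sequence_set(rng, **kwargs)
    cfg = GAConfig(population_size=2, generations=0, seed=int(rng.integers(2**31)))
    return init_population(seqs, cfg).members[0]


def brute_force_fitness(rows: list[str], sch: ScoringScheme) -> int:
    """Triple loop over (column, i, j) using the scalar pair score."""
    total = 0
    for c in range(len(rows[0])):
        for i in range(len(rows) - 1):
            for j in range(i + 1, len(rows)):
                total += pair_score(rows[i][c], rows[j][c], sch)
    return total


def brute_force_sp_tc(test: Alignment, ref: Alignment) -> tuple[float, float]:
    """SP/TC by explicit enumeration of reference pairs and columns."""

    def residue_columns(aln: Alignment) -> dict[tuple[str, int], int]:
        out = {}
        for seq_id, row in zip(aln.ids, aln.rows):
            k = 0
            for col, ch in enumerate(row):
                if ch != GAP:
                    out[(seq_id, k)] = col
                    k += 1
        return out

    tcol = residue_columns(test)
    rcol = residue_columns(ref)
    by_ref_column: dict[int, list] = {}
    for key, col in rcol.items():
        by_ref_column.setdefault(col, []).append(key)

    pairs = hits = cols = col_hits = 0
    for keys in by_ref_column.values():
        if len(keys) < 2:
            continue
        cols += 1
        for a, b in itertools.combinations(keys, 2):
            pairs += 1
            if tcol[a] == tcol[b]:
                hits += 1
        if len({tcol[k] for k in keys}) == 1:
            col_hits += 1
    return (
        hits / pairs if pairs else 0.0,
        col_hits / cols if cols else 0.0,
    )
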