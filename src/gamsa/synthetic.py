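"""Synthetic protein families with a known true alignment.

The simulator draws a random root sequence and derives each family member
independently (star topology): per-site substitutions whose replacement
residue is biased toward PAM250-similar residues, plus geometric-length
insertions and deletions.  Because every member descends directly from the
root, the true alignment is unambiguous — homologous columns are the
surviving root positions, and each insertion event contributes fresh
columns in which every other sequence carries a gap.

This gives the aligner and the SP/TC evaluator a self-contained test bed
with a ground-truth reference, standing in for curated benchmark families
at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GAP, Alignment, ProteinSequence, SequenceSet
from .errors import ContractError
from .scoring import RESIDUE_ORDER, ScoringScheme

__all__ = ["SimulatedFamily", "simulate_family"]

#: Softmax temperature for substitution draws; 2 score units per e-fold
#: keeps conservative replacements favored without making them certain.
_SUBSTITUTION_TEMPERATURE = 2.0


@dataclass(frozen=True)
class SimulatedFamily:
    """A simulated protein family: ungapped members plus their true alignment."""

    sequences: SequenceSet
    true_alignment: Alignment
    params: dict

    def __post_init__(self) -> None:
        for row, seq in zip(self.true_alignment.rows, self.sequences):
            assert row.replace(GAP, "") == seq.residues


def _substitution_distributions(scheme: ScoringScheme) -> np.ndarray:
    """Row-stochastic (20, 20) matrix of replacement probabilities.

    Row a gives the distribution of the replacement residue when residue a
    is hit by a substitution; the diagonal is zero (a substitution changes
    the residue) and off-diagonal mass is proportional to
    exp(score(a, b) / T), so PAM250-similar residues are preferred.
    """
    probs = np.zeros((20, 20))
    for i, a in enumerate(RESIDUE_ORDER):
        weights = np.array(
            [
                0.0
                if b == a
                else np.exp(scheme.matrix[(a, b)] / _SUBSTITUTION_TEMPERATURE)
                for b in RESIDUE_ORDER
            ]
        )
        probs[i] = weights / weights.sum()
    return probs


def simulate_family(
    n_seqs: int = 4,
    root_length: int = 30,
    sub_rate: float = 0.1,
    indel_rate: float = 0.02,
    mean_indel_len: float = 2.0,
    seed: int = 0,
) -> SimulatedFamily:
    """Simulate a star-topology protein family with a known true alignment.

    Parameters
    ----------
    n_seqs:
        Number of family members (>= 2).
    root_length:
        Length of the random ancestral sequence.
    sub_rate:
        Per-site probability that a member's copy of a root residue is
        substituted (replacement biased toward PAM250-similar residues).
    indel_rate:
        Per-site probability of an indel event, split evenly between
        insertion (after the site) and deletion (starting at the site).
        An insertion anchor before the first site is included.
    mean_indel_len:
        Mean of the geometric indel-length distribution.
    seed:
        Seeds all randomness; identical seeds give identical families.

    The defaults describe an easy family — closely related members, few
    indels — on which a working aligner should recover most of the truth.
    """
    if n_seqs < 2:
        raise ContractError("n_seqs must be >= 2")
    if root_length < 1:
        raise ContractError("root_length must be >= 1")
    if not 0.0 <= sub_rate <= 1.0 or not 0.0 <= indel_rate <= 1.0:
        raise ContractError("rates must lie in [0, 1]")
    if mean_indel_len < 1.0:
        raise ContractError("mean_indel_len must be >= 1")

    rng = np.random.default_rng(seed)
    scheme = ScoringScheme.default()
    sub_probs = _substitution_distributions(scheme)
    letters = np.array(list(RESIDUE_ORDER))
    root_codes = rng.integers(0, 20, size=root_length)

    def indel_length() -> int:
        return int(rng.geometric(1.0 / mean_indel_len))

    # Per leaf: which root sites survive, what residue each carries, and the
    # inserted runs keyed by anchor (-1 = before the first root site).
    kept_all: list[np.ndarray] = []
    residues_all: list[list[str]] = []
    insertions_all: list[dict[int, str]] = []
    for _ in range(n_seqs):
        codes = root_codes.copy()
        hit = rng.random(root_length) < sub_rate
        for pos in np.flatnonzero(hit):
            codes[pos] = rng.choice(20, p=sub_probs[codes[pos]])

        kept = np.ones(root_length, dtype=bool)
        insertions: dict[int, str] = {}
        for anchor in range(-1, root_length):
            if rng.random() < indel_rate / 2.0:  # insertion after anchor
                length = indel_length()
                insertions[anchor] = "".join(
                    letters[rng.integers(0, 20, size=length)]
                )
            if anchor >= 0 and rng.random() < indel_rate / 2.0:  # deletion
                kept[anchor : anchor + indel_length()] = False
        if not kept.any() and not insertions:
            kept[0] = True  # a member must keep at least one residue
        kept_all.append(kept)
        residues_all.append([letters[c] for c in codes])
        insertions_all.append(insertions)

    # Assemble the true alignment column by column: for each anchor, first
    # the homologous column (skipped if deleted everywhere), then one
    # private column block per member that inserted there.
    rows = [[] for _ in range(n_seqs)]
    for anchor in range(-1, root_length):
        if anchor >= 0 and any(kept[anchor] for kept in kept_all):
            for i in range(n_seqs):
                rows[i].append(
                    residues_all[i][anchor] if kept_all[i][anchor] else GAP
                )
        for i in range(n_seqs):
            run = insertions_all[i].get(anchor)
            if run:
                for j in range(n_seqs):
                    rows[j].append(run if j == i else GAP * len(run))

    gapped = ["".join(parts) for parts in rows]
    sequences = SequenceSet(
        tuple(
            ProteinSequence(f"seq{i + 1}", row.replace(GAP, ""))
            for i, row in enumerate(gapped)
        )
    )
    true_alignment = Alignment(gapped, sequences)
    params = {
        "n_seqs": n_seqs,
        "root_length": root_length,
        "sub_rate": sub_rate,
        "indel_rate": indel_rate,
        "mean_indel_len": mean_indel_len,
        "seed": seed,
    }
    return SimulatedFamily(
        sequences=sequences, true_alignment=true_alignment, params=params
    )
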