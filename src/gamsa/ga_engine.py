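"""The genetic algorithm: chromosome repair, initialization, selection,
crossover, mutation, elitist replacement, the generation loop, and a
hill-climbing baseline.

A chromosome is an :class:`~gamsa.core.Alignment`.  Every operator here
maps valid chromosomes to valid chromosomes: residues are never reordered,
only gaps move.  The mutation operators are classic permutation-style
moves (exchange, segment reverse, three-cycle, two-half inverse) applied
to the row *string*; afterwards the gap/non-gap pattern of the mutated row
is kept and the original residues are rewritten left-to-right into the
non-gap slots.  Mutations therefore shuffle gap geometry while decode
invariance holds by construction.

Replacement is elitist: the next generation is the best 60 % of parents
plus the best 40 % of children, so the best fitness per generation never
decreases.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import GAP, Alignment, SequenceSet
from .errors import ContractError, CorruptionError
from .scoring import ScoringScheme, sp_fitness

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "GAConfig",
    "GAResult",
    "Population",
    "crossover_I",
    "crossover_II",
    "hill_climb",
    "init_population",
    "mutate_best_of_four",
    "mutate_exchange",
    "mutate_inverse",
    "mutate_position",
    "mutate_reverse",
    "next_generation",
    "repair",
    "run_ga",
    "select_parents",
]


@dataclass(frozen=True)
class GAConfig:
    """Run parameters for the genetic algorithm.

    Defaults mirror the method's published setting: 100 chromosomes evolved
    for 50 generations, crossover probability 0.8 per selected pair,
    initial width 1.2 x the longest input sequence, and elitist 60-40
    parent-child replacement.

    ``mutation_prob`` is the per-child probability of applying the
    best-of-four mutation.  It defaults to 1.0 because the algorithm's step
    list applies all four mutation operators to every child and keeps the
    fittest result; a nominal rate like 0.01, read per child, would disable
    the operator family the method's own baseline comparison relies on.
    """

    population_size: int = 100
    generations: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 1.0
    width_factor: float = 1.2
    max_gap_fraction: float = 0.25
    parent_fraction: float = 0.6
    child_fraction: float = 0.4
    patience: int | None = None  # stop after k improvement-free generations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ContractError("population_size must be >= 2")
        if self.generations < 0:
            raise ContractError("generations must be >= 0")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ContractError(f"{name} must lie in [0, 1], got {p}")
        if self.width_factor < 1.0:
            raise ContractError("width_factor must be >= 1")
        if abs(self.parent_fraction + self.child_fraction - 1.0) > 1e-9:
            raise ContractError("parent_fraction + child_fraction must equal 1")

    def width_for(self, seqs: SequenceSet) -> int:
        """Initial chromosome width: ceil(width_factor x n_max)."""
        return math.ceil(self.width_factor * seqs.n_max)


@dataclass
class Population:
    """One GA generation: a list of chromosomes over a shared sequence set."""

    members: list[Alignment]
    generation: int = 0

    @property
    def size(self) -> int:
        return len(self.members)

    def fitnesses(self, scheme: ScoringScheme) -> list[int]:
        return [sp_fitness(m, scheme) for m in self.members]

    def best(self, scheme: ScoringScheme) -> Alignment:
        return max(self.members, key=lambda m: sp_fitness(m, scheme))


@dataclass
class GAResult:
    """Outcome of a search run: the best chromosome found and the trace.

    ``history`` has one row per generation, generation 0 included:
    (generation, best, mean, worst) fitness of the population at that point.
    """

    best: Alignment
    history: list[tuple[int, int, float, int]]
    operator_counts: dict[str, int] = field(default_factory=dict)

    @property
    def best_fitness_trace(self) -> list[int]:
        return [row[1] for row in self.history]


def repair(rows: Sequence[str], source: SequenceSet) -> Alignment:
    """Normalize raw operator output into a valid chromosome.

    Shorter rows are padded with trailing gaps to the longest row, then
    every all-gap column is deleted.  A row whose residues no longer match
    its source sequence raises :class:`CorruptionError` — operator bugs
    surface, they are never silently fixed.
    """
    rows = [r.upper() for r in rows]
    if len(rows) != source.n:
        raise ContractError(f"{len(rows)} rows for {source.n} sequences")
    for row, seq in zip(rows, source):
        if row.replace(GAP, "") != seq.residues:
            raise CorruptionError(
                f"row for {seq.id!r} decodes to {row.replace(GAP, '')!r}, "
                f"expected {seq.residues!r}"
            )
    width = max(len(r) for r in rows)
    rows = [r.ljust(width, GAP) for r in rows]
    keep = [c for c in range(width) if any(r[c] != GAP for r in rows)]
    if len(keep) != width:
        rows = ["".join(r[c] for c in keep) for r in rows]
    return Alignment(rows, source)


def _random_gapped_row(residues: str, width: int, rng: np.random.Generator) -> str:
    """Spread width - len(residues) gaps over uniformly random positions."""
    n_gaps = width - len(residues)
    if n_gaps == 0:
        return residues
    gap_at = set(rng.choice(width, size=n_gaps, replace=False).tolist())
    out = []
    it = iter(residues)
    for c in range(width):
        out.append(GAP if c in gap_at else next(it))
    return "".join(out)


def init_population(seqs: SequenceSet, cfg: GAConfig) -> Population:
    """Random initial population at width ceil(width_factor x n_max).

    Each row of length L receives W - L gaps at uniformly random positions.
    The per-row gap budget of 25 % of the longest sequence always holds for
    the longest row (0.2 <= 0.25); shorter rows may exceed it because the
    width rule fixes their gap count, in which case a debug note is logged
    and the width rule wins.
    """
    rng = np.random.default_rng(cfg.seed)
    width = cfg.width_for(seqs)
    cap = math.floor(cfg.max_gap_fraction * seqs.n_max)
    for seq in seqs:
        if width - len(seq) > cap:
            logger.debug(
                "row %r needs %d gaps, over the 25%% budget of %d; width rule wins",
                seq.id, width - len(seq), cap,
            )
    members = [
        repair([_random_gapped_row(s.residues, width, rng) for s in seqs], seqs)
        for _ in range(cfg.population_size)
    ]
    return Population(members=members, generation=0)


def select_parents(
    pop: Population, scheme: ScoringScheme
) -> tuple[list[tuple[Alignment, Alignment]], list[Alignment]]:
    """Rank by fitness (descending, stable) and pair consecutive members.

    Returns the ordered list of disjoint pairs — (1st, 2nd), (3rd, 4th), …
    — plus any unpaired leftover (odd population), which is carried over
    unchanged to the child pool.
    """
    if pop.size < 2:
        raise ContractError("cannot select parents from fewer than 2 members")
    ranked = sorted(
        pop.members, key=lambda m: sp_fitness(m, scheme), reverse=True
    )
    pairs = [
        (ranked[i], ranked[i + 1]) for i in range(0, pop.size - 1, 2)
    ]
    leftover = [ranked[-1]] if pop.size % 2 else []
    return pairs, leftover


def _residue_prefix_end(row: str, count: int) -> int:
    """Index just past the count-th residue of a gapped row (0 if count==0)."""
    if count == 0:
        return 0
    seen = 0
    for idx, ch in enumerate(row):
        if ch != GAP:
            seen += 1
            if seen == count:
                return idx + 1
    raise ContractError(f"row has fewer than {count} residues")


def _splice_prefix(a: Alignment, b: Alignment, cut: int) -> Alignment:
    """Child = columns [0, cut) of *a* + residue-consistent tail of *b*.

    For each row the tail starts right after *b*'s copy of the last residue
    the prefix contains; junction gaps pad the ragged tails to one width.
    """
    pieces = []
    for row_a, row_b in zip(a.rows, b.rows):
        pre = row_a[:cut]
        n_res = sum(ch != GAP for ch in pre)
        tail = row_b[_residue_prefix_end(row_b, n_res):]
        pieces.append((pre, tail))
    width = max(len(pre) + len(tail) for pre, tail in pieces)
    rows = [
        pre + GAP * (width - len(pre) - len(tail)) + tail
        for pre, tail in pieces
    ]
    return repair(rows, a.source)


def _splice_suffix(a: Alignment, b: Alignment, cut: int) -> Alignment:
    """Child = residue-consistent head of *a* + columns [cut, W) of *b*.

    The head of each row of *a* is cut right after the residue that precedes
    *b*'s suffix block; junction gaps are inserted before the suffix so the
    right blocks stay column-aligned.
    """
    pieces = []
    for row_a, row_b, seq in zip(a.rows, b.rows, a.source):
        suf = row_b[cut:]
        n_suf = sum(ch != GAP for ch in suf)
        head = row_a[: _residue_prefix_end(row_a, len(seq) - n_suf)]
        pieces.append((head, suf))
    width = max(len(head) + len(suf) for head, suf in pieces)
    rows = [
        head + GAP * (width - len(head) - len(suf)) + suf
        for head, suf in pieces
    ]
    return repair(rows, a.source)


def crossover_I(
    p1: Alignment, p2: Alignment, rng: np.random.Generator
) -> tuple[Alignment, Alignment]:
    """One-point crossover anchored on a column of the first parent.

    A cut column c of p1 is drawn uniformly from {0, …, width}.  Child 1
    keeps p1's columns left of c and continues with p2's arrangement of the
    remaining residues; child 2 is the mirror.  Gap padding is added at the
    junction where the exchanged blocks disagree in length.
    """
    _check_same_source(p1, p2)
    cut = int(rng.integers(0, p1.width + 1))
    child1 = _splice_prefix(p1, p2, cut)
    child2 = _splice_prefix(p2, p1, min(cut, p2.width))
    return child1, child2


def crossover_II(
    p1: Alignment, p2: Alignment, rng: np.random.Generator
) -> tuple[Alignment, Alignment]:
    """One-point crossover anchored on a column of the second parent.

    The cut column is drawn in p2 and the exchanged blocks are aligned on
    the right: gaps are inserted before the suffix block rather than after
    the prefix block.  Together with :func:`crossover_I` this gives two
    distinct cut geometries, both residue-safe.
    """
    _check_same_source(p1, p2)
    cut = int(rng.integers(0, p2.width + 1))
    child1 = _splice_suffix(p1, p2, cut)
    child2 = _splice_suffix(p2, p1, min(cut, p1.width))
    return child1, child2


def _check_same_source(p1: Alignment, p2: Alignment) -> None:
    if p1.ids != p2.ids or any(
        s1.residues != s2.residues for s1, s2 in zip(p1.source, p2.source)
    ):
        raise ContractError("crossover parents must encode the same sequences")


def _refit_residues(original: str, mutated: str) -> str:
    """Keep the mutated gap pattern; refill the original residues in order."""
    residues = iter(original.replace(GAP, ""))
    return "".join(GAP if ch == GAP else next(residues) for ch in mutated)


def _mutate_row(
    aln: Alignment,
    rng: np.random.Generator,
    row_op: Callable[[str, np.random.Generator], str],
) -> Alignment:
    idx = int(rng.integers(0, aln.n))
    row = aln.rows[idx]
    mutated = _refit_residues(row, row_op(row, rng))
    rows = list(aln.rows)
    rows[idx] = mutated
    return repair(rows, aln.source)


def mutate_exchange(aln: Alignment, rng: np.random.Generator) -> Alignment:
    """Swap the symbols at two random positions of one random row."""

    def op(row: str, rng: np.random.Generator) -> str:
        i, j = (int(x) for x in rng.integers(0, len(row), size=2))
        chars = list(row)
        chars[i], chars[j] = chars[j], chars[i]
        return "".join(chars)

    return _mutate_row(aln, rng, op)


def mutate_reverse(aln: Alignment, rng: np.random.Generator) -> Alignment:
    """Reverse the segment between two random positions of one random row."""

    def op(row: str, rng: np.random.Generator) -> str:
        a, b = sorted(int(x) for x in rng.integers(0, len(row), size=2))
        return row[:a] + row[a : b + 1][::-1] + row[b + 1 :]

    return _mutate_row(aln, rng, op)


def mutate_position(aln: Alignment, rng: np.random.Generator) -> Alignment:
    """Three-cycle the symbols at three random positions a < b < c.

    The symbol at a moves to b, b's to c, and c's to a.  Rows shorter than
    three symbols are returned unchanged.
    """

    def op(row: str, rng: np.random.Generator) -> str:
        if len(row) < 3:
            return row
        a, b, c = sorted(
            int(x) for x in rng.choice(len(row), size=3, replace=False)
        )
        chars = list(row)
        chars[b], chars[c], chars[a] = row[a], row[b], row[c]
        return "".join(chars)

    return _mutate_row(aln, rng, op)


def mutate_inverse(aln: Alignment, rng: np.random.Generator) -> Alignment:
    """Split one row at a random point and reverse each half in place."""

    def op(row: str, rng: np.random.Generator) -> str:
        s = int(rng.integers(0, len(row) + 1))
        return row[:s][::-1] + row[s:][::-1]

    return _mutate_row(aln, rng, op)


_MUTATION_OPS: tuple[tuple[str, Callable], ...] = (
    ("exchange", mutate_exchange),
    ("reverse", mutate_reverse),
    ("position", mutate_position),
    ("inverse", mutate_inverse),
)


def mutate_best_of_four(
    aln: Alignment,
    scheme: ScoringScheme,
    rng: np.random.Generator,
    counts: dict[str, int] | None = None,
) -> Alignment:
    """Apply all four mutation operators to copies; keep the fittest result.

    Each operator draws its own random sites from the shared stream in the
    fixed order exchange, reverse, position, inverse; ties go to the earlier
    operator in that order.
    """
    best_name, best_candidate, best_fit = None, None, None
    for name, op in _MUTATION_OPS:
        candidate = op(aln, rng)
        fit = sp_fitness(candidate, scheme)
        if best_fit is None or fit > best_fit:
            best_name, best_candidate, best_fit = name, candidate, fit
    if counts is not None:
        counts[best_name] = counts.get(best_name, 0) + 1
    return best_candidate


def next_generation(
    pop: Population,
    children: list[Alignment],
    cfg: GAConfig,
    scheme: ScoringScheme,
) -> Population:
    """Elitist replacement: best 60 % of parents + best 40 % of children.

    If fewer children than the 40 % quota are available the remainder is
    filled with the next-best parents (with a warning).  Population size is
    preserved and the generation index advances.
    """
    size = pop.size
    n_parents = round(cfg.parent_fraction * size)
    n_children = size - n_parents
    ranked_parents = sorted(
        pop.members, key=lambda m: sp_fitness(m, scheme), reverse=True
    )
    ranked_children = sorted(
        children, key=lambda m: sp_fitness(m, scheme), reverse=True
    )
    taken_children = ranked_children[:n_children]
    shortfall = n_children - len(taken_children)
    if shortfall > 0:
        warnings.warn(
            f"only {len(taken_children)} children for a quota of "
            f"{n_children}; filling {shortfall} slots with parents",
            stacklevel=2,
        )
    members = ranked_parents[: n_parents + shortfall] + taken_children
    return Population(members=members, generation=pop.generation + 1)


def _history_row(
    pop: Population, scheme: ScoringScheme
) -> tuple[int, int, float, int]:
    fits = pop.fitnesses(scheme)
    return (pop.generation, max(fits), float(np.mean(fits)), min(fits))


def run_ga(
    seqs: SequenceSet,
    cfg: GAConfig | None = None,
    scheme: ScoringScheme | None = None,
) -> GAResult:
    """Evolve alignments of ``seqs`` for ``cfg.generations`` generations.

    Each generation: members are ranked and paired best-with-next-best;
    each pair recombines with probability ``crossover_prob`` through one of
    the two crossover operators (chosen 50/50), otherwise the parents are
    copied; each child is mutated with probability ``mutation_prob`` by the
    best-of-four mutation; the next population keeps the best 60 % of
    parents and the best 40 % of children.  Fully reproducible from
    ``cfg.seed``.
    """
    cfg = cfg or GAConfig()
    scheme = scheme or ScoringScheme.default()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    pop = init_population(seqs, cfg)
    history = [_history_row(pop, scheme)]
    best_ever = pop.best(scheme)
    counts: dict[str, int] = {"crossover_I": 0, "crossover_II": 0}
    stale = 0
    for _ in range(cfg.generations):
        pairs, leftover = select_parents(pop, scheme)
        children: list[Alignment] = []
        for mother, father in pairs:
            if rng.random() < cfg.crossover_prob:
                if rng.random() < 0.5:
                    op_name, op = "crossover_I", crossover_I
                else:
                    op_name, op = "crossover_II", crossover_II
                c1, c2 = op(mother, father, rng)
                counts[op_name] += 1
            else:
                c1, c2 = mother.copy(), father.copy()
            children.extend((c1, c2))
        children.extend(m.copy() for m in leftover)
        children = [
            mutate_best_of_four(ch, scheme, rng, counts)
            if rng.random() < cfg.mutation_prob
            else ch
            for ch in children
        ]
        pop = next_generation(pop, children, cfg, scheme)
        history.append(_history_row(pop, scheme))
        gen_best = pop.best(scheme)
        if sp_fitness(gen_best, scheme) > sp_fitness(best_ever, scheme):
            best_ever, stale = gen_best, 0
        else:
            stale += 1
            if cfg.patience is not None and stale >= cfg.patience:
                break
    return GAResult(best=best_ever, history=history, operator_counts=counts)


def hill_climb(
    seqs: SequenceSet,
    cfg: GAConfig | None = None,
    scheme: ScoringScheme | None = None,
    budget: int | None = None,
) -> GAResult:
    """First-ascent hill climbing from the best member of the same random
    initial population the GA starts from.

    The budget is counted in candidate fitness evaluations and defaults to
    the GA's ``generations x population_size``.  Each proposal is one
    best-of-four mutation (four evaluations); only strict improvements are
    accepted.  ``history`` records (proposal index, current best, current
    best, current best) so its first column is a step counter rather than a
    generation index.
    """
    cfg = cfg or GAConfig()
    scheme = scheme or ScoringScheme.default()
    if budget is None:
        budget = cfg.generations * cfg.population_size
    if budget < 0:
        raise ContractError("budget must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    pop = init_population(seqs, cfg)
    current = pop.best(scheme)
    fit = sp_fitness(current, scheme)
    history = [(0, fit, float(fit), fit)]
    used = 0
    step = 0
    n_ops = len(_MUTATION_OPS)
    while used + n_ops <= budget:
        candidate = mutate_best_of_four(current, scheme, rng)
        used += n_ops
        step += 1
        cand_fit = sp_fitness(candidate, scheme)
        if cand_fit > fit:
            current, fit = candidate, cand_fit
        history.append((step, fit, float(fit), fit))
    return GAResult(best=current, history=history)
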