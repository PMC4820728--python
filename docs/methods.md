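# Methods

## Alignment model

An alignment of sequences N₁ … Nₙ is a set of equal-length rows M₁ … Mₙ over
the 20-letter amino-acid alphabet plus the gap character `-`, subject to
three invariants: (1) all rows share one width, (2) removing the gaps from
Mᵢ reproduces Nᵢ exactly, and (3) no column consists only of gaps. Every
operator in the package maps valid alignments to valid alignments; condition
(2) is enforced as a hard error (`CorruptionError`) rather than repaired,
because a violation can only be an operator bug. Alignments read from files
relax condition (3): foreign reference alignments sometimes carry all-gap
columns, and such columns never contribute to any score computed here.

## Objective function

The fitness of an alignment is the sum over columns and unordered row pairs
(i < j) of a pairwise symbol score: the PAM250 log-odds entry for two
residues, otherwise a flat gap penalty of magnitude 2 for (residue, gap),
3 for (gap, residue) and 1 for (gap, gap). Design choices behind this:

* **Sign.** The magnitudes are "penalties" in a maximized objective, so they
  enter negatively by default (`penalty_sign = -1`); a positive sign would
  reward gap columns. The sign is configurable for experimentation.
* **Pair order.** The gap cases are asymmetric, so the score is only
  well-defined with a fixed convention: the row with the smaller index
  supplies the first symbol. This makes fitness reproducible across runs
  and platforms.
* **Flat gap costs.** Gap costs are per column with no opening/extension
  distinction. An affine gap model is out of scope.
* **Matrix.** The standard published Dayhoff PAM250 table ships as a
  plain-text NCBI-style matrix file (`gamsa/data/PAM250`); alternative
  matrices (PAM120, BLOSUM62) can be loaded from files in the same
  whitespace-delimited format via `ScoringScheme.from_file`. The bundled
  table is cross-checked entry-for-entry against Biopython's canonical
  PAM250 in the test suite.

The fitness implementation encodes rows over a 21-symbol code (20 residues +
gap) and sums a precomputed 21×21 pair table over all row pairs; the test
suite checks it exhaustively against a character-by-character triple loop on
small instances (every alignment shape with n·width ≤ 8 over a 3-letter
sub-alphabet) and on random larger ones. The match-column ("TC-style") term
sometimes combined with sum-of-pairs objectives is deliberately not part of
the fitness; column recovery is measured separately by the evaluator.

## Genetic algorithm

**Encoding and initialization.** The chromosome is the alignment itself. The
initial width is `ceil(width_factor × n_max)` with `width_factor = 1.2`,
where `n_max` is the longest input sequence; each row of length L receives
its W − L gaps at uniformly random positions. A nominal per-row gap budget
of 25 % of `n_max` always holds for the longest row (0.2 ≤ 0.25); for
shorter rows the width rule fixes the gap count and wins over the budget
(the conflict is logged at debug level, not enforced — both rules cannot
hold simultaneously for short rows).

**Selection.** Members are sorted by fitness (stable, descending) and paired
consecutively — (1st, 2nd), (3rd, 4th), … — so the best individuals
recombine with each other. An unpaired leftover in an odd population carries
over to the child pool unchanged.

**Crossover.** Two one-point, residue-consistent cut operators, chosen 50/50
per pair, applied with probability 0.8 per pair (otherwise the parents are
copied). Operator I draws a cut column c in the first parent; each child row
is the first parent's columns left of c followed by the second parent's
arrangement of the remaining residues, with junction gaps padding the ragged
tails. Operator II mirrors the geometry: the cut column is drawn in the
second parent and the exchanged suffix blocks stay right-aligned, gaps being
inserted before the suffix block. Both constructions count residues across
the cut, so decode invariance holds by construction; `repair` then pads
ragged rows and deletes any all-gap columns.

**Mutation.** Four classic permutation-style operators act on one random row:
exchange (swap two positions), reverse (reverse a segment), position
(three-cycle three positions), inverse (reverse each half around a split
point). Applied literally to the row string these would reorder residues, so
each operator is followed by a pattern refit: the gap/non-gap pattern of the
mutated row is kept and the original residues are rewritten left-to-right
into the non-gap slots. Mutations therefore move gaps while preserving each
operator's distinct shuffling geometry. All four operators are applied to
copies of each child (drawing from the shared random stream in the fixed
order exchange, reverse, position, inverse) and the fittest of the four
candidates is kept, ties going to the earlier operator.

`mutation_prob`, the per-child probability of applying this best-of-four
step, defaults to 1.0: the algorithm's step list applies all four mutation
operators to every child and keeps the best, and the method's advantage
over a mutation-only hill climber (below) depends on the mutation family
being active. A nominal rate like 0.01, read as a per-child application
probability, would make the GA a crossover-only search — measured on the
easy synthetic suite this drops mean best fitness from ≈711 to ≈252
(population 30, 30 generations, 8 seeds) and inverts the GA-vs-baseline
comparison. The knob remains configurable for ablations.

**Replacement and termination.** Elitist 60-40: the next generation is the
best 60 % of parents plus the best 40 % of children (quota shortfalls are
filled with next-best parents, with a warning). Best fitness per generation
is therefore non-decreasing. The run lasts a fixed 50 generations by
default; an optional `patience` flag stops after k improvement-free
generations (off by default). Alternative 50-50 and 40-60 replacement
splits are exposed through the ablation runner.

**Determinism.** All randomness flows from `GAConfig.seed` through numpy
Generators (the search stream is derived from the seed with a fixed salt so
it is independent of the initialization stream). Identical inputs and seed
give byte-identical output alignments and histories.

## Hill-climbing baseline

The baseline starts from the best member of the *same* random initial
population the GA would use (same seed) and repeatedly proposes best-of-four
mutations, accepting only strict fitness improvements. Its budget is counted
in candidate fitness evaluations and defaults to `generations ×
population_size`, the GA's nominal child count; each best-of-four proposal
consumes four evaluations. One caveat measured honestly: because the GA's
unconditional mutation step also evaluates four mutants per child, the GA
actually consumes about four times more fitness evaluations than this
nominal budget. At the nominal budget the GA outperforms the climber on the
easy synthetic suite (mean best fitness ≈711 vs ≈669; mean truth-recovery
SP ≈0.87 vs ≈0.82 over 8 seeds); when the climber is granted the GA's full
evaluation count it becomes the stronger searcher on these small families
(≈798). The package reports the comparison at the nominal budget and
exposes `budget` as an explicit parameter.

## Accuracy evaluation

SP and TC scores compare a test alignment with a reference over the same
sequences, identifying each residue by (sequence id, ordinal within the
ungapped sequence). SP is the fraction of reference residue pairs (two
residues sharing a reference column) that also share a test column; TC is
the fraction of reference columns whose complete residue set is reunited in
one test column. Reference columns with fewer than two residues carry no
information and are excluded from both denominators; an empty denominator
yields 0. Both scores are invariant to all-gap columns in either alignment.
Core-block annotations of curated benchmarks are not parsed — every
reference column is scored — which is a deliberate simplification relative
to annotation-aware scorers.

## Synthetic families

The simulator draws a root sequence uniformly over the alphabet and derives
each member independently (star topology): every site is substituted with
probability `sub_rate`, the replacement drawn over the 19 other residues
with probability ∝ exp(PAM250 score / 2) so conservative replacements are
favored, and indel events occur per anchor with probability `indel_rate`,
split evenly between insertions (geometric length, mean `mean_indel_len`,
random residues) and deletions (geometric run of root sites). The true
alignment is assembled by construction: homologous columns are surviving
root positions; each insertion event contributes private columns in which
all other members carry gaps. A star topology keeps this construction
unambiguous — independent insertions are never merged into shared columns —
at the cost of realism (no nested phylogenetic structure, no rate
heterogeneity, no conserved motif blocks). Passing recovery tests on these
families shows the search machinery works end to end, not that the aligner
matches curated-benchmark accuracy on real protein families.

Defaults (4 sequences, root length 30, `sub_rate` 0.1, `indel_rate` 0.02,
`mean_indel_len` 2.0) describe an easy family: ~85 % expected identity to
the root and roughly one indel per pair of members, the regime where truth
recovery is realistic for a stochastic aligner at desk scale. With balanced
insertion and deletion rates the expected member length stays near the root
length.

## Problem sizes used in the test suite

Full-size GA properties (elitist monotonicity, determinism) run at the
default population 100 × 50 generations over 20 seeds. The recovery and
baseline comparisons run at population 30 × 30 generations over 20 seeds,
a scaled-down setting chosen so the whole suite stays a few-minute desk run
while leaving the directional comparisons unambiguous. Exhaustive oracle
checks cover every alignment shape with n·width ≤ 8 over a 3-letter
sub-alphabet (~10⁵ instances after validity filtering); full enumeration at
the larger shapes the oracle also samples randomly would be astronomically
large (4²⁴ states at n = 4, width = 6).

## Known limitations

* Flat (non-affine) gap costs; no terminal-gap special-casing.
* The fitness has no column-match term; highly gappy optima can score well
  under sum-of-pairs while breaking columns a curated reference keeps.
* Guide-tree-based initialization is not implemented.
* The evaluator scores all reference columns; it is not a drop-in
  replacement for annotation-aware benchmark scorers on files with
  core-block annotations.
* The simulator's star topology and uniform root make its families easier
  than real divergent protein families; absolute scores on it do not
  transfer to curated benchmarks.
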