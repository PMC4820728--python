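"""Chromosome repair, initialization, selection, crossover, mutation,
replacement, and the search loops."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_alignment, random_sequence_set

from gamsa.core import GAP, Alignment, ProteinSequence, SequenceSet
from gamsa.errors import ContractError, CorruptionError
from gamsa.ga_engine import (
    GAConfig,
    Population,
    crossover_I,
    crossover_II,
    hill_climb,
    init_population,
    mutate_best_of_four,
    mutate_exchange,
    mutate_inverse,
    mutate_position,
    mutate_reverse,
    next_generation,
    repair,
    run_ga,
    select_parents,
)
from gamsa.scoring import sp_fitness


class ScriptedRng:
    """Plays back a fixed list of draws; lets tests pin random sites."""

    def __init__(self, values):
        self.queue = list(values)

    def integers(self, low, high=None, size=None):
        if size is None:
            return self.queue.pop(0)
        return np.array([self.queue.pop(0) for _ in range(size)])

    def choice(self, n, size=None, replace=True, p=None):
        return np.array([self.queue.pop(0) for _ in range(size)])

    def random(self):
        return self.queue.pop(0)


def assert_valid(aln: Alignment) -> None:
    """The three chromosome invariants, checked from the raw rows."""
    width = aln.width
    assert all(len(r) == width for r in aln.rows)
    for row, seq in zip(aln.rows, aln.source):
        assert row.replace(GAP, "") == seq.residues
    for c in range(width):
        assert any(r[c] != GAP for r in aln.rows)


def two_seqs(*residues):
    return SequenceSet(
        tuple(ProteinSequence(f"s{i + 1}", r) for i, r in enumerate(residues))
    )


class TestRepair:
    def test_pads_ragged_rows_with_trailing_gaps(self):
        aln = repair(["AC", "ACDE"], two_seqs("AC", "ACDE"))
        assert aln.rows == ("AC--", "ACDE")

    def test_drops_all_gap_columns(self):
        aln = repair(["A--C", "AG-C"], two_seqs("AC", "AGC"))
        assert aln.rows == ("A-C", "AGC")

    def test_residue_mismatch_is_a_corruption_error(self):
        with pytest.raises(CorruptionError):
            repair(["A-C", "AGC"], two_seqs("AC", "AC"))


class TestInitPopulation:
    def test_width_is_ceil_of_factor_times_longest(self, toy_seqs):
        seqs = two_seqs("ACDEFGHIKL", "ACDEF")  # n_max = 10
        cfg = GAConfig(population_size=4, seed=1)
        assert cfg.width_for(seqs) == 12
        pop = init_population(seqs, cfg)
        assert all(m.width <= 12 for m in pop.members)
        assert all(m.width >= seqs.n_max for m in pop.members)

    def test_full_length_row_gets_no_gaps(self):
        seqs = two_seqs("ACDEFGHIKLMN", "ACDEF")
        cfg = GAConfig(population_size=4, width_factor=1.0, seed=2)
        pop = init_population(seqs, cfg)
        for member in pop.members:
            assert member.rows[0] == "ACDEFGHIKLMN"

    def test_same_seed_reproduces_population(self, toy_seqs):
        cfg = GAConfig(population_size=6, seed=9)
        a = init_population(toy_seqs, cfg)
        b = init_population(toy_seqs, cfg)
        assert [m.rows for m in a.members] == [m.rows for m in b.members]

    def test_members_are_valid_and_size_respected(self, toy_seqs):
        cfg = GAConfig(population_size=7, seed=3)
        pop = init_population(toy_seqs, cfg)
        assert pop.size == 7
        for member in pop.members:
            assert_valid(member)


class TestSelectParents:
    @staticmethod
    def _pop_with_fitnesses(scheme, fits):
        members = []
        for k, f in enumerate(fits):
            aln = Alignment(["AC", "AC"])
            aln._fitness = (scheme, f)
            members.append(aln)
        return Population(members=members)

    def test_pairs_ranked_best_with_next_best(self, scheme):
        pop = self._pop_with_fitnesses(scheme, [5, 9, 1, 7])
        pairs, leftover = select_parents(pop, scheme)
        got = [
            (sp_fitness(a, scheme), sp_fitness(b, scheme)) for a, b in pairs
        ]
        assert got == [(9, 7), (5, 1)]
        assert leftover == []

    def test_stable_order_on_ties(self, scheme):
        pop = self._pop_with_fitnesses(scheme, [3, 3, 3, 3])
        pairs, _ = select_parents(pop, scheme)
        assert pairs[0][0] is pop.members[0]
        assert pairs[0][1] is pop.members[1]

    def test_odd_population_leaves_worst_unpaired(self, scheme):
        pop = self._pop_with_fitnesses(scheme, [5, 9, 1])
        pairs, leftover = select_parents(pop, scheme)
        assert len(pairs) == 1
        assert sp_fitness(leftover[0], scheme) == 1

    def test_too_small_population_rejected(self, scheme):
        pop = Population(members=[Alignment(["AC", "AC"])])
        with pytest.raises(ContractError):
            select_parents(pop, scheme)


class TestCrossover:
    def parents(self, seed=0):
        rng = np.random.default_rng(seed)
        seqs = random_sequence_set(rng, n_range=(3, 4), len_range=(8, 15))
        cfg1 = GAConfig(population_size=2, seed=seed)
        cfg2 = GAConfig(population_size=2, seed=seed + 1000)
        return (
            init_population(seqs, cfg1).members[0],
            init_population(seqs, cfg2).members[1],
        )

    def test_cut_at_zero_swaps_parents(self):
        p1, p2 = self.parents()
        c1, c2 = crossover_I(p1, p2, ScriptedRng([0]))
        assert c1 == p2
        assert c2 == p1

    def test_cut_at_width_returns_first_parent(self):
        p1, p2 = self.parents()
        c1, _ = crossover_I(p1, p2, ScriptedRng([p1.width, 0]))
        assert c1 == p1

    def test_crossover_ii_cut_at_zero(self):
        p1, p2 = self.parents()
        c1, c2 = crossover_II(p1, p2, ScriptedRng([0]))
        assert c1 == p2
        assert c2 == p1

    def test_spec_toy_cut_preserves_decode(self):
        seqs = two_seqs("ACD", "ACD")
        p1 = Alignment(["AC-D", "A-CD"], seqs)
        p2 = Alignment(["ACD-", "AC-D"], seqs)
        c1, c2 = crossover_I(p1, p2, ScriptedRng([2]))
        for child in (c1, c2):
            assert_valid(child)
            assert child.source is seqs

    def test_identical_parents_children_decode_equal(self):
        p1, _ = self.parents(seed=5)
        p2 = p1.copy()
        for op in (crossover_I, crossover_II):
            c1, c2 = op(p1, p2, np.random.default_rng(3))
            for child in (c1, c2):
                assert_valid(child)
                assert child.decode() == p1.decode()

    def test_mismatched_parents_rejected(self):
        p1, _ = self.parents(seed=1)
        q1, _ = self.parents(seed=2)
        with pytest.raises(ContractError):
            crossover_I(p1, q1, np.random.default_rng(0))

    @pytest.mark.parametrize("op", [crossover_I, crossover_II])
    @pytest.mark.parametrize("trial", range(25))
    def test_children_always_valid(self, op, trial):
        rng = np.random.default_rng(3000 + trial)
        seqs = random_sequence_set(rng)
        pop = init_population(seqs, GAConfig(population_size=2, seed=trial))
        c1, c2 = op(pop.members[0], pop.members[1], rng)
        assert_valid(c1)
        assert_valid(c2)


class TestMutations:
    """Frozen examples derived by hand from the gap-pattern repair rule:
    the operator rearranges the row string, then the original residues are
    rewritten left-to-right into the resulting non-gap slots."""

    def aln(self, row, other="ACDEF"):
        other = other[: len(row)].ljust(len(row), "G")
        return Alignment(
            [row, other], two_seqs(row.replace(GAP, ""), other)
        )

    def test_exchange_moves_gap(self):
        # swap positions 3 and 5 (1-based) of "AC-DE": gap moves to the end
        out = mutate_exchange(self.aln("AC-DE"), ScriptedRng([0, 2, 4]))
        assert out.rows[0] == "ACDE-"

    def test_exchange_of_two_residues_is_identity(self):
        out = mutate_exchange(self.aln("AC-DE"), ScriptedRng([0, 0, 1]))
        assert out.rows[0] == "AC-DE"

    def test_exchange_of_two_gaps_is_identity(self):
        out = mutate_exchange(self.aln("A--DE"), ScriptedRng([0, 1, 2]))
        assert out.rows[0] == "A--DE"

    def test_reverse_span_moves_gaps_right(self):
        # reverse span 3..6 (1-based) of "AC--DE"
        out = mutate_reverse(self.aln("AC--DE"), ScriptedRng([0, 2, 5]))
        assert out.rows[0] == "ACDE--"

    def test_reverse_palindromic_gap_pattern_is_identity(self):
        # span "-CD-" has a symmetric gap pattern
        out = mutate_reverse(self.aln("A-CD-E"), ScriptedRng([0, 1, 4]))
        assert out.rows[0] == "A-CD-E"

    def test_reverse_degenerate_span_is_identity(self):
        out = mutate_reverse(self.aln("AC--DE"), ScriptedRng([0, 3, 3]))
        assert out.rows[0] == "AC--DE"

    def test_position_cycles_gap_forward(self):
        # positions (2,4,5) 1-based on "A-CDE": the gap lands at position 4
        out = mutate_position(self.aln("A-CDE"), ScriptedRng([0, 1, 3, 4]))
        assert out.rows[0] == "ACD-E"

    def test_position_on_three_residues_is_identity(self):
        out = mutate_position(self.aln("A-CDE"), ScriptedRng([0, 0, 2, 3]))
        assert out.rows[0] == "A-CDE"

    def test_inverse_split_reverses_halves(self):
        # split "AF-C--" after position 3: halves "AF-" and "C--" reverse to
        # "-FA" and "--C"; pattern "-RR--R" refilled with AFC gives "-AF--C"
        seqs = two_seqs("AFC", "ACDEFG")
        aln = Alignment(["AF-C--", "ACDEFG"], seqs)
        out = mutate_inverse(aln, ScriptedRng([0, 3]))
        assert out.rows[0] == "-AF--C"

    def test_inverse_symmetric_pattern_is_identity(self):
        # halves "A--F" and "C-D" have palindromic gap patterns
        seqs = two_seqs("AFCD", "ACDEFGH")
        aln = Alignment(["A--FC-D", "ACDEFGH"], seqs)
        out = mutate_inverse(aln, ScriptedRng([0, 4]))
        assert out.rows[0] == "A--FC-D"

    def test_inverse_split_at_zero_reverses_whole_row(self):
        aln = self.aln("AC--DE")
        out = mutate_inverse(aln, ScriptedRng([0, 0]))
        rev = mutate_reverse(self.aln("AC--DE"), ScriptedRng([0, 0, 5]))
        assert out.rows[0] == rev.rows[0]

    @pytest.mark.parametrize(
        "op", [mutate_exchange, mutate_reverse, mutate_position, mutate_inverse]
    )
    @pytest.mark.parametrize("trial", range(10))
    def test_mutants_always_valid(self, op, trial):
        rng = np.random.default_rng(4000 + trial)
        aln = random_alignment(rng)
        assert_valid(op(aln, rng))


class TestBestOfFour:
    def test_returns_max_of_four_candidates(self, scheme):
        for seed in range(10):
            aln = random_alignment(np.random.default_rng(6000 + seed))
            ops = [mutate_exchange, mutate_reverse, mutate_position, mutate_inverse]
            oracle_rng = np.random.default_rng(seed)
            candidates = [op(aln, oracle_rng) for op in ops]
            expected = max(sp_fitness(c, scheme) for c in candidates)
            result = mutate_best_of_four(aln, scheme, np.random.default_rng(seed))
            assert sp_fitness(result, scheme) == expected

    def test_tie_broken_by_operator_order(self, scheme):
        aln = random_alignment(np.random.default_rng(42))
        ops = [mutate_exchange, mutate_reverse, mutate_position, mutate_inverse]
        oracle_rng = np.random.default_rng(42)
        candidates = [op(aln, oracle_rng) for op in ops]
        fits = [sp_fitness(c, scheme) for c in candidates]
        first_best = candidates[int(np.argmax(fits))]
        result = mutate_best_of_four(aln, scheme, np.random.default_rng(42))
        assert result == first_best


class TestNextGeneration:
    def _pop(self, scheme, seqs, size, seed):
        return init_population(seqs, GAConfig(population_size=size, seed=seed))

    def test_sixty_forty_split(self, scheme, toy_seqs):
        pop = self._pop(scheme, toy_seqs, 10, 1)
        children = self._pop(scheme, toy_seqs, 10, 2).members
        cfg = GAConfig(population_size=10, seed=1)
        new = next_generation(pop, children, cfg, scheme)
        assert new.size == 10
        assert new.generation == 1
        parent_set = {id(m) for m in pop.members}
        n_parents = sum(1 for m in new.members if id(m) in parent_set)
        assert n_parents == 6

    def test_best_parent_always_survives(self, scheme, toy_seqs):
        pop = self._pop(scheme, toy_seqs, 8, 3)
        children = self._pop(scheme, toy_seqs, 8, 4).members
        cfg = GAConfig(population_size=8, seed=3)
        best_before = max(pop.fitnesses(scheme))
        new = next_generation(pop, children, cfg, scheme)
        assert max(new.fitnesses(scheme)) >= best_before

    def test_child_shortfall_filled_with_parents(self, scheme, toy_seqs):
        pop = self._pop(scheme, toy_seqs, 10, 5)
        only_child = self._pop(scheme, toy_seqs, 2, 6).members[:1]
        cfg = GAConfig(population_size=10, seed=5)
        with pytest.warns(UserWarning, match="quota"):
            new = next_generation(pop, only_child, cfg, scheme)
        assert new.size == 10


class TestRunGA:
    def test_zero_generations_returns_initial_best(self, scheme, toy_seqs):
        cfg = GAConfig(population_size=6, generations=0, seed=7)
        result = run_ga(toy_seqs, cfg, scheme)
        pop = init_population(toy_seqs, cfg)
        assert sp_fitness(result.best, scheme) == max(pop.fitnesses(scheme))
        assert len(result.history) == 1

    def test_determinism_same_seed_identical_output(self, scheme, toy_seqs):
        cfg = GAConfig(population_size=10, generations=8, seed=11)
        a = run_ga(toy_seqs, cfg, scheme)
        b = run_ga(toy_seqs, cfg, scheme)
        assert a.best.rows == b.best.rows
        assert a.history == b.history

    def test_history_length_and_monotone_best(self, scheme, toy_seqs):
        cfg = GAConfig(population_size=10, generations=12, seed=13)
        result = run_ga(toy_seqs, cfg, scheme)
        assert len(result.history) == 13
        trace = result.best_fitness_trace
        assert all(a <= b for a, b in zip(trace, trace[1:]))

    def test_every_generation_decodes_to_input(self, scheme, toy_seqs):
        cfg = GAConfig(population_size=8, generations=5, seed=17)
        result = run_ga(toy_seqs, cfg, scheme)
        assert_valid(result.best)
        assert result.best.decode().ids == toy_seqs.ids

    def test_patience_stops_early(self, scheme, toy_seqs):
        cfg = GAConfig(population_size=6, generations=50, patience=2, seed=19)
        result = run_ga(toy_seqs, cfg, scheme)
        assert len(result.history) <= 51


class TestHillClimb:
    def test_zero_budget_returns_initial_best(self, scheme, toy_seqs):
        cfg = GAConfig(population_size=6, generations=10, seed=23)
        result = hill_climb(toy_seqs, cfg, scheme, budget=0)
        pop = init_population(toy_seqs, cfg)
        assert sp_fitness(result.best, scheme) == max(pop.fitnesses(scheme))

    def test_history_is_non_decreasing(self, scheme, toy_seqs):
        cfg = GAConfig(population_size=6, generations=5, seed=29)
        result = hill_climb(toy_seqs, cfg, scheme)
        trace = result.best_fitness_trace
        assert all(a <= b for a, b in zip(trace, trace[1:]))


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    op_index=st.integers(0, 5),
)
def test_operator_closure_property(seed, op_index):
    """Any operator applied to any valid chromosome yields a valid one."""
    rng = np.random.default_rng(seed)
    aln = random_alignment(rng)
    if op_index < 4:
        op = [mutate_exchange, mutate_reverse, mutate_position, mutate_inverse][
            op_index
        ]
        out = op(aln, rng)
        assert_valid(out)
    else:
        other = init_population(
            aln.source, GAConfig(population_size=2, seed=seed % 997)
        ).members[1]
        op = [crossover_I, crossover_II][op_index - 4]
        c1, c2 = op(aln, other, rng)
        assert_valid(c1)
        assert_valid(c2)
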