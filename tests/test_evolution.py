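import random

import pytest

from erd.constraints import CANONICAL_PAIRS, ConstraintConflictError, ConstraintSet
from erd.evolution import (
    Candidate,
    build_initial_sequence,
    design,
    evaluate_and_select,
    make_population,
)
from erd.pools import Fragment, FragmentPool
from erd.randstruct import random_compatible_sequence, random_stem_loop
from erd.struct_model import (
    ComponentKind,
    GeometryKey,
    decompose,
    parse_dotbracket,
)


def single_assembly_pool():
    pool = FragmentPool()
    pool.add(GeometryKey(ComponentKind.STEM, (2,)), Fragment(("GC", "GC")))
    pool.add(GeometryKey(ComponentKind.HAIRPIN, (3,)), Fragment(("AAA",)))
    return pool


def pairing_compatible(seq, target):
    return all(
        seq[i - 1] + seq[j - 1] in CANONICAL_PAIRS for i, j in target.pair_list()
    )


class TestBuildInitialSequence:
    def test_single_possible_assembly(self, toy_engine):
        target = parse_dotbracket("((...))")
        cand, seq_ok, energy_ok = build_initial_sequence(
            target, single_assembly_pool(), ConstraintSet(), toy_engine, random.Random(0)
        )
        assert cand.seq == "GCAAAGC"
        assert seq_ok and energy_ok

    def test_mask_checked_per_position(self, toy_engine):
        target = parse_dotbracket("((...))")
        cand, seq_ok, _ = build_initial_sequence(
            target,
            single_assembly_pool(),
            ConstraintSet(mask="GNNNNNC"),
            toy_engine,
            random.Random(0),
        )
        assert cand.seq == "GCAAAGC" and seq_ok

    def test_conflicting_mask_raises_before_sampling(self, toy_engine):
        target = parse_dotbracket("((...))")
        with pytest.raises(ConstraintConflictError):
            build_initial_sequence(
                target,
                single_assembly_pool(),
                ConstraintSet(mask="ANNNNNC"),
                toy_engine,
                random.Random(0),
            )

    def test_unreachable_energy_interval_flagged(self, toy_engine):
        target = parse_dotbracket("((...))")
        cand, seq_ok, energy_ok = build_initial_sequence(
            target,
            single_assembly_pool(),
            ConstraintSet(energy_min=-100.0, energy_max=-50.0),
            toy_engine,
            random.Random(0),
        )
        assert seq_ok and not energy_ok
        assert cand.seq == "GCAAAGC"  # best-so-far still returned


class TestMakePopulation:
    def test_distance_zero_parent_breeds_nothing(self, toy_engine, toy_pool):
        target = parse_dotbracket("((...))")
        parent = Candidate(seq="GCAAAGC")
        parent.mfe_structure, _ = toy_engine.fold(parent.seq)
        assert parent.mfe_structure.dotbracket == target.dotbracket
        pop = make_population(
            parent, target, decompose(target), toy_pool, ConstraintSet(), random.Random(0)
        )
        assert pop == [parent]

    def test_one_mismatched_component_one_variant(self, toy_engine, toy_pool):
        target = parse_dotbracket("((((...)))).")
        parent = Candidate(seq=random_compatible_sequence(target, random.Random(3)))
        # predicted structure disagreeing only inside the hairpin loop
        parent.mfe_structure = parse_dotbracket("(((((.))))).", min_hairpin=0)
        pop = make_population(
            parent, target, decompose(target), toy_pool, ConstraintSet(), random.Random(0)
        )
        # mismatches at loop positions only -> hairpin component -> parent + 1
        assert len(pop) == 2

    def test_offspring_stay_mask_and_pairing_compliant(self, toy_engine, toy_pool):
        rng = random.Random(5)
        for _ in range(30):
            target = random_stem_loop(rng)
            seq = random_compatible_sequence(target, rng)
            mask = "".join(b if rng.random() < 0.2 else "N" for b in seq)
            cs = ConstraintSet(mask=mask)
            parent = Candidate(seq=seq)
            parent.mfe_structure, _ = toy_engine.fold(seq)
            for child in make_population(
                parent, target, decompose(target), toy_pool, cs, rng
            ):
                assert pairing_compatible(child.seq, target)
                assert all(
                    m == "N" or b == m for b, m in zip(child.seq, mask)
                )


class FakeEngine:
    """Records fold order; energy_of returns canned values by sequence."""

    name = "fake"

    def __init__(self, energies):
        self.energies = energies
        self.folded = []

    def fold(self, seq):
        self.folded.append(seq)
        return parse_dotbracket("." * len(seq)), 0.0

    def energy_of(self, seq, s):
        return self.energies[seq]


class TestEvaluateAndSelect:
    def test_population_of_one(self, toy_engine):
        target = parse_dotbracket("((...))")
        c = Candidate(seq="GCAAAGC")
        survivors, best = evaluate_and_select([c], target, None, ConstraintSet(), toy_engine)
        assert survivors == [c] and best is c

    def test_fold_order_without_interval(self):
        target = parse_dotbracket("....")
        seqs = ["AAAA", "CCCC", "GGGG", "UUUU"]
        energies = dict(zip(seqs, [-5.0, -3.0, -9.0, -1.0]))
        eng = FakeEngine(energies)
        pop = [Candidate(seq=s) for s in seqs]
        evaluate_and_select(pop, target, None, ConstraintSet(), eng)
        assert eng.folded == ["GGGG", "AAAA", "CCCC"]

    def test_fold_order_with_interval_uses_center_distance(self):
        # interval [-6,-2], center -4: distances |e-c| = 5,1,1,3, so the
        # candidates at -5 and -3 (tie broken by input order) then -1 fold
        target = parse_dotbracket("....")
        seqs = ["AAAA", "CCCC", "GGGG", "UUUU"]
        energies = dict(zip(seqs, [-9.0, -5.0, -3.0, -1.0]))
        eng = FakeEngine(energies)
        pop = [Candidate(seq=s) for s in seqs]
        evaluate_and_select(
            pop, target, None, ConstraintSet(energy_min=-6, energy_max=-2), eng
        )
        assert eng.folded == ["CCCC", "GGGG", "UUUU"]


class TestDesign:
    def test_fully_masked_target_returns_that_sequence(self, toy_engine, toy_pool):
        seq = "GGGGGAAACCCCC"
        target, _ = toy_engine.fold(seq)
        res = design(target, ConstraintSet(mask=seq), toy_pool, toy_engine, seed=1)
        assert res.seq == seq
        assert res.success and res.distance == 0
        assert res.iterations_used <= 2

    def test_success_refolds_to_target(self, toy_engine, toy_pool):
        target = parse_dotbracket("((((...))))")
        res = design(target, ConstraintSet(), toy_pool, toy_engine, seed=0)
        if res.success:
            s, _ = toy_engine.fold(res.seq)
            assert s.dotbracket == target.dotbracket

    def test_infeasible_interval_surfaces_as_flags(self, toy_engine, toy_pool):
        target = parse_dotbracket("((((((((...))))))))")
        res = design(
            target,
            ConstraintSet(energy_min=-0.5, energy_max=-0.4),
            toy_pool,
            toy_engine,
            seed=2,
            max_iter=5,
        )
        assert not res.success and not res.energy_constraint_met

    def test_deterministic_under_seed(self, toy_engine, toy_pool):
        target = parse_dotbracket("((((...)))).((...))")
        r1 = design(target, ConstraintSet(), toy_pool, toy_engine, seed=11, max_iter=20)
        r2 = design(target, ConstraintSet(), toy_pool, toy_engine, seed=11, max_iter=20)
        assert r1 == r2

    def test_returned_sequences_always_compatible_and_masked(self, toy_engine, toy_pool):
        rng = random.Random(31)
        for k in range(60):
            target = random_stem_loop(rng, max_len=40)
            base = random_compatible_sequence(target, rng)
            mask = "".join(b if rng.random() < 0.25 else "N" for b in base)
            cs = ConstraintSet(mask=mask)
            res = design(target, cs, toy_pool, toy_engine, seed=k, max_iter=10)
            assert pairing_compatible(res.seq, target)
            assert all(m == "N" or b == m for b, m in zip(res.seq, mask))
            assert res.sequence_constraints_met
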