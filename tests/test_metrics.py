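import itertools
import math
import random

import pytest

from erd.metrics import (
    expected_energy_distance,
    expected_similarity_to_natural,
    expected_similarity_within,
    expected_time,
    nucleotide_distribution,
    similarity,
)
from erd.pools import NATURAL_TOTAL, generate_synthetic_corpus
from erd.struct_model import parse_dotbracket

MATCH, MISMATCH, OPEN, EXTEND = 5.0, -4.0, 10.0, 0.5


def nw_oracle(a: str, b: str):
    """Independent exhaustive global aligner (affine gaps, free end gaps).

    Enumerates every alignment as a monotone path of match/insert/delete
    moves, scores it with needle's defaults, and returns the best score with
    the set of identity percentages among all optimal alignments.
    """
    best_score = -math.inf
    best_idents = set()

    def gap_cost(length, at_end):
        if length == 0:
            return 0.0
        return 0.0 if at_end else OPEN + EXTEND * (length - 1)

    n, m = len(a), len(b)

    def rec(i, j, score, columns, ident, state):
        nonlocal best_score, best_idents
        if i == n and j == m:
            if score > best_score:
                best_score, best_idents = score, set()
            if score == best_score:
                best_idents.add(100.0 * ident / columns if columns else 0.0)
            return
        if i < n and j < m:
            s = MATCH if a[i] == b[j] else MISMATCH
            rec(i + 1, j + 1, score + s, columns + 1,
                ident + (a[i] == b[j]), "m")
        if i < n:
            at_end = j == m or j == 0
            cost = 0.0 if at_end else (OPEN if state != "d" else EXTEND)
            rec(i + 1, j, score - cost, columns + 1, ident, "d")
        if j < m:
            at_end = i == n or i == 0
            cost = 0.0 if at_end else (OPEN if state != "i" else EXTEND)
            rec(i, j + 1, score - cost, columns + 1, ident, "i")

    rec(0, 0, 0.0, 0, 0, "start")
    return best_score, best_idents


class TestExpectedTime:
    def test_division(self):
        assert expected_time(100.0, 50) == 2.0
        assert expected_time(7.5, 1) == 7.5

    def test_no_success_is_infinite(self):
        assert expected_time(100.0, 0) == math.inf


class TestExpectedEnergyDistance:
    def test_hand_example(self):
        assert expected_energy_distance([-10, -12], [-11, -11]) == 1.0
        assert expected_energy_distance([-10, -12], [-10, -12]) == 0.0

    def test_empty_is_infinite(self):
        assert expected_energy_distance([], []) == math.inf

    def test_brute_force_oracle(self):
        rng = random.Random(1)
        for _ in range(50):
            n = rng.randint(1, 20)
            d = [rng.uniform(-150, 0) for _ in range(n)]
            e = [rng.uniform(-150, 0) for _ in range(n)]
            brute = sum(abs(x - y) for x, y in zip(d, e)) / n
            assert expected_energy_distance(d, e) == pytest.approx(brute, rel=1e-9)


class TestSimilarity:
    def test_identical_sequences(self):
        assert similarity("ACGUACGU", "ACGUACGU") == 100.0

    def test_symmetry(self):
        rng = random.Random(2)
        for _ in range(20):
            a = "".join(rng.choice("ACGU") for _ in range(rng.randint(1, 15)))
            b = "".join(rng.choice("ACGU") for _ in range(rng.randint(1, 15)))
            assert similarity(a, b) == similarity(b, a)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            similarity("", "ACGU")

    def test_matches_exhaustive_dynamic_program(self):
        rng = random.Random(3)
        cases = [("ACGU", "UGCA"), ("ACGU", "ACGU"), ("A", "G")]
        for _ in range(15):
            cases.append(
                (
                    "".join(rng.choice("ACGU") for _ in range(rng.randint(1, 8))),
                    "".join(rng.choice("ACGU") for _ in range(rng.randint(1, 8))),
                )
            )
        for a, b in cases:
            _, idents = nw_oracle(a, b)
            got = similarity(a, b)
            assert any(got == pytest.approx(v) for v in idents), (a, b, got, idents)


class TestExpectedSimilarityWithin:
    def test_two_identical_sequences(self):
        assert expected_similarity_within([["ACGU", "ACGU"]]) == 100.0

    def test_pair_enumeration(self):
        s, t = "ACGUACGU", "ACGUAAAA"
        expected = (100.0 + 2 * similarity(s, t)) / 3
        assert expected_similarity_within([[s, s, t]]) == pytest.approx(expected)

    def test_brute_force_double_loop(self):
        rng = random.Random(4)
        groups = [
            ["".join(rng.choice("ACGU") for _ in range(12)) for _ in range(rng.randint(1, 4))]
            for _ in range(5)
        ]
        per = []
        for g in groups:
            if len(g) < 2:
                continue
            sims = [similarity(x, y) for x, y in itertools.combinations(g, 2)]
            per.append(sum(sims) / len(sims))
        assert expected_similarity_within(groups) == pytest.approx(
            sum(per) / len(per), rel=1e-9
        )

    def test_all_groups_too_small(self):
        with pytest.raises(ValueError):
            expected_similarity_within([["ACGU"], []])


class TestExpectedSimilarityToNatural:
    def test_identical_lists(self):
        assert expected_similarity_to_natural(["ACGU", "GGGG"], ["ACGU", "GGGG"]) == 100.0

    def test_single_pair(self):
        a, b = "ACGUACGU", "ACGAACGA"
        assert expected_similarity_to_natural([a], [b]) == similarity(a, b)

    def test_brute_force_mean(self):
        rng = random.Random(5)
        d = ["".join(rng.choice("ACGU") for _ in range(10)) for _ in range(6)]
        n = ["".join(rng.choice("ACGU") for _ in range(10)) for _ in range(6)]
        brute = sum(similarity(x, y) for x, y in zip(d, n)) / 6
        assert expected_similarity_to_natural(d, n) == pytest.approx(brute, rel=1e-9)


class TestNucleotideDistribution:
    def test_hand_example(self):
        table = nucleotide_distribution(["GCAAAGC"], [parse_dotbracket("((...))")])
        assert table.paired == {"AU": 0.0, "GC": 1.0, "GU": 0.0}
        assert table.unpaired["A"] == 1.0

    def test_all_unpaired(self):
        table = nucleotide_distribution(["ACGU"], [parse_dotbracket("....")])
        assert table.paired == {}
        assert table.total == {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}

    def test_group_sums_to_one(self):
        rng = random.Random(6)
        from erd.randstruct import random_compatible_sequence, random_structure

        seqs, structs = [], []
        for _ in range(20):
            s = random_structure(rng, 20, 80)
            structs.append(s)
            seqs.append(random_compatible_sequence(s, rng))
        table = nucleotide_distribution(seqs, structs)
        for group in (table.paired, table.unpaired, table.total):
            if group:
                assert sum(group.values()) == pytest.approx(1.0, abs=1e-9)
        assert table.other_pairs == 0

    def test_corpus_totals_approach_generator_targets(self):
        seqs = generate_synthetic_corpus(1000, (100, 100), random.Random(8))
        structs = [parse_dotbracket("." * 100)] * len(seqs)
        table = nucleotide_distribution(seqs, structs)
        for base, target in NATURAL_TOTAL.items():
            assert table.total[base] == pytest.approx(target, abs=0.02)
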