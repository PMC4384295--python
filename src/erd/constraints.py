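"""Sequence (IUPAC) and free-energy interval constraints.

A design run may fix positions of the output sequence to a nucleotide or a
subset of nucleotides via a mask of IUPAC one-letter codes, and may require
the free energy of the designed sequence evaluated on the target structure to
lie inside ``[energy_min, energy_max]`` kcal/mol.  The default interval is
``(-inf, 0]``: any stabilising sequence is acceptable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .struct_model import SecondaryStructure

#: IUPAC nucleotide ambiguity codes over the RNA alphabet.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

#: Watson-Crick plus wobble pairs, as ordered 5'+3' strings.
CANONICAL_PAIRS: frozenset[str] = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})


class ConstraintConflictError(ValueError):
    """A mask is internally infeasible against the target pairing."""

    def __init__(self, conflicts: list[tuple[int, int, str, str]]):
        self.conflicts = conflicts
        detail = "; ".join(
            f"pair {i}.{j} constrained to {ci}/{cj}" for i, j, ci, cj in conflicts
        )
        super().__init__(f"infeasible sequence constraints: {detail}")


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert DNA-style T to U (FASTA corpora mix alphabets)."""
    return seq.upper().replace("T", "U")


def normalize_mask(mask: str) -> str:
    mask = normalize_sequence(mask)
    for pos, ch in enumerate(mask, start=1):
        if ch not in IUPAC:
            raise ValueError(f"unknown IUPAC symbol {ch!r} at position {pos}")
    return mask


@dataclass(frozen=True)
class ConstraintSet:
    """IUPAC mask (or None) plus an inclusive free-energy interval in kcal/mol."""

    mask: str | None = None
    energy_min: float = -math.inf
    energy_max: float = 0.0

    def __post_init__(self):
        if self.mask is not None:
            object.__setattr__(self, "mask", normalize_mask(self.mask))
        if self.energy_min > self.energy_max:
            raise ValueError(
                f"energy_min {self.energy_min} exceeds energy_max {self.energy_max}"
            )

    @property
    def has_finite_interval(self) -> bool:
        return math.isfinite(self.energy_min) and math.isfinite(self.energy_max)

    @property
    def interval_center(self) -> float:
        return (self.energy_min + self.energy_max) / 2.0


def matches(code: str, base: str) -> bool:
    """Standard IUPAC semantics: does ``base`` belong to the set ``code`` denotes?"""
    try:
        allowed = IUPAC[code]
    except KeyError:
        raise ValueError(f"unknown IUPAC symbol {code!r}") from None
    if base not in IUPAC or len(IUPAC[base]) != 1:
        raise ValueError(f"not a nucleotide: {base!r}")
    return base in allowed


def sequence_satisfies(seq: str, cs: ConstraintSet) -> bool:
    """True iff every position of ``seq`` matches its mask symbol."""
    if cs.mask is None:
        return True
    if len(seq) != len(cs.mask):
        raise ValueError(f"length mismatch: sequence {len(seq)} vs mask {len(cs.mask)}")
    return all(b in IUPAC[c] for b, c in zip(seq, cs.mask))


def pair_choices(code5: str, code3: str) -> list[str]:
    """All canonical pairs (as 5'+3' strings) admitted by two mask symbols."""
    return [
        p
        for p in sorted(CANONICAL_PAIRS)
        if p[0] in IUPAC[code5] and p[1] in IUPAC[code3]
    ]


def detect_conflicts(
    structure: SecondaryStructure, mask: str | None
) -> list[tuple[int, int, str, str]]:
    """Pairs ``i.j`` whose mask symbols admit no complementary combination.

    An empty list means the mask is feasible against the pairing.
    """
    if mask is None:
        return []
    mask = normalize_mask(mask)
    if len(mask) != structure.length:
        raise ValueError(
            f"length mismatch: structure {structure.length} vs mask {len(mask)}"
        )
    conflicts = []
    for i, j in structure.pair_list():
        if not pair_choices(mask[i - 1], mask[j - 1]):
            conflicts.append((i, j, mask[i - 1], mask[j - 1]))
    return conflicts


def energy_in_range(e: float, cs: ConstraintSet) -> bool:
    """Inclusive membership of ``e`` in the constraint interval."""
    return cs.energy_min <= e <= cs.energy_max


def interval_distance(e: float, cs: ConstraintSet) -> float:
    """How far ``e`` sits from the acceptable energies (0 when inside).

    With a finite interval this is the distance to the interval center, the
    quantity the search minimises when an energy band is requested.
    """
    if cs.has_finite_interval:
        return abs(e - cs.interval_center)
    if e < cs.energy_min:
        return cs.energy_min - e
    if e > cs.energy_max:
        return e - cs.energy_max
    return 0.0
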