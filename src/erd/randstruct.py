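"""Random valid secondary-structure generators.

Synthetic targets for benchmarking and property testing: structures are
grown recursively from helices and loops, so every output respects the
minimum-hairpin rule and helix nesting by construction.  All generators are
deterministic given the ``random.Random`` passed in.
"""

from __future__ import annotations

import random

from .struct_model import (
    MIN_HAIRPIN,
    SecondaryStructure,
    has_multiloop,
    parse_dotbracket,
)


def _grow(n: int, rng: random.Random, depth: int = 0) -> str:
    """A random structure over exactly ``n`` positions."""
    if n < MIN_HAIRPIN + 2 + 2:  # too short for a helix of 2 + hairpin
        return "." * n
    if depth > 0 and rng.random() < 0.25:
        return "." * n
    # helix of k pairs enclosing an interior, with optional flanks
    k = rng.randint(2, max(2, min(8, (n - MIN_HAIRPIN) // 2)))
    interior_max = n - 2 * k
    if interior_max < MIN_HAIRPIN:
        return "." * n
    interior = rng.randint(MIN_HAIRPIN, interior_max)
    flank = n - 2 * k - interior
    left = rng.randint(0, flank)
    right = flank - left
    # interior: hairpin, single branch with loop strands, or multiple branches
    inner = _interior(interior, rng, depth + 1)
    return "." * left + "(" * k + inner + ")" * k + "." * right


def _interior(n: int, rng: random.Random, depth: int) -> str:
    min_branch = MIN_HAIRPIN + 4  # smallest closed stem-loop: ((...))
    n_branches_max = n // min_branch
    if n_branches_max == 0 or depth > 6:
        return "." * n
    choices = [0]
    if n_branches_max >= 1:
        choices.append(1)
    if n_branches_max >= 2:
        choices.append(2)
    if n_branches_max >= 3:
        choices.append(3)
    b = rng.choice(choices)
    if b == 0:
        return "." * n
    branch_total = rng.randint(b * min_branch, n)
    sizes = _random_partition(branch_total, b, min_branch, rng)
    gaps = _random_partition(n - branch_total, b + 1, 0, rng)
    out = "." * gaps[0]
    for t in range(b):
        out += _grow_closed(sizes[t], rng, depth)
        out += "." * gaps[t + 1]
    return out


def _random_partition(total: int, parts: int, minimum: int, rng: random.Random) -> list[int]:
    extra = total - parts * minimum
    cuts = sorted(rng.randint(0, extra) for _ in range(parts - 1))
    sizes = []
    prev = 0
    for c in cuts:
        sizes.append(minimum + c - prev)
        prev = c
    sizes.append(minimum + extra - prev)
    return sizes


def _grow_closed(n: int, rng: random.Random, depth: int) -> str:
    """A structure whose outermost positions form a pair (a closed branch)."""
    k = rng.randint(1, max(1, min(6, (n - MIN_HAIRPIN) // 2)))
    interior = n - 2 * k
    if interior < MIN_HAIRPIN:
        k = (n - MIN_HAIRPIN) // 2
        interior = n - 2 * k
    return "(" * k + _interior(interior, rng, depth + 1) + ")" * k


def random_structure(
    rng: random.Random, min_len: int = 20, max_len: int = 300
) -> SecondaryStructure:
    """A random valid structure of length uniform in ``[min_len, max_len]``."""
    n = rng.randint(min_len, max_len)
    return parse_dotbracket(_grow(n, rng))


def random_multiloop_structure(
    rng: random.Random, min_len: int = 30, max_len: int = 200, max_tries: int = 200
) -> SecondaryStructure:
    """A random valid structure guaranteed to contain at least one multi-loop."""
    for _ in range(max_tries):
        s = random_structure(rng, min_len, max_len)
        if has_multiloop(s):
            return s
    # construct one directly: two branches under a closing helix
    inner = "((...))" * 2
    n = max(min_len, len(inner) + 4)
    pad = n - len(inner) - 4
    return parse_dotbracket("((" + inner + "." * pad + "))")


def random_stem_loop(
    rng: random.Random, max_len: int = 50
) -> SecondaryStructure:
    """A random hairpin target: one or two helices with a hairpin loop and
    optionally an internal/bulge loop and unpaired flanks."""
    while True:
        k1 = rng.randint(3, 8)
        two_helix = rng.random() < 0.5
        k2 = rng.randint(2, 5) if two_helix else 0
        loop = rng.randint(3, 8)
        il_left = rng.randint(0, 3) if two_helix else 0
        il_right = rng.randint(0, 3) if two_helix else 0
        if two_helix and il_left == 0 and il_right == 0:
            il_left = 1  # avoid stacking the two helices into one
        flank5 = rng.randint(0, 3)
        flank3 = rng.randint(0, 3)
        db = (
            "." * flank5
            + "(" * k1
            + "." * il_left
            + "(" * k2
            + "." * loop
            + ")" * k2
            + "." * il_right
            + ")" * k1
            + "." * flank3
        )
        if len(db) <= max_len:
            return parse_dotbracket(db)


def random_compatible_sequence(
    s: SecondaryStructure, rng: random.Random
) -> str:
    """A uniform pairing-compatible sequence for ``s`` (pairs drawn from the
    six canonical combinations, unpaired bases uniform)."""
    pairs = s.pair_list()
    seq = [""] * s.length
    canonical = ["AU", "UA", "GC", "CG", "GU", "UG"]
    for i, j in pairs:
        p = rng.choice(canonical)
        seq[i - 1], seq[j - 1] = p[0], p[1]
    for t in range(s.length):
        if not seq[t]:
            seq[t] = rng.choice("ACGU")
    return "".join(seq)
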