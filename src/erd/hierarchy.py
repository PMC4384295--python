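"""Hierarchical decomposition of a target structure at its multi-loops.

Folding cost grows at least cubically with length, so long targets are split
into sub-structures that can be optimised independently.  Splits happen only
where multi-loops occur: for each multi-loop, its order-minimum closing pair
(ordered by 5' index) is the *tag base pair*, the stem containing it the
*tag stem*, and the order-minimum pair of that stem the *breaking base
pair*.  When several multi-loops offer breaking pairs at one level, the one
that splits the string into the most nearly equal halves is chosen (ties to
the lowest 5' index).

A split at breaking pair ``i.j`` yields the closed sub-structure ``i..j`` as
one child and the remainder as the other; the pair ``i.j`` is duplicated
into the remainder as a zero-loop boundary stub ``()`` so both children stay
balanced, and is counted once (the closed child's copy wins) on reassembly.
Reassembling the leaves reproduces the parent string character-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .struct_model import (
    Component,
    ComponentKind,
    SecondaryStructure,
    decompose,
    iter_multiloops,
    parse_dotbracket,
)

#: sub-structures shorter than this are never split further
DEFAULT_MIN_SPLIT_LEN = 40


@dataclass
class DecompositionNode:
    """Node of the hierarchical decomposition tree.

    ``global_positions[t]`` maps local position ``t+1`` to the position in
    the original (root) structure; duplicated boundary-stub copies in a
    remainder child map to the same global position as the closed child's
    copy.  ``stub_pairs`` are the boundary stubs present in this node's
    string, in local coordinates.
    """

    structure: SecondaryStructure
    sequence: str
    offset: int  # 1-based start in parent coordinates (closed child) or 1
    global_positions: tuple[int, ...]
    breaking_pair: tuple[int, int] | None = None  # parent coords of the split
    stub_pairs: tuple[tuple[int, int], ...] = ()
    children: list["DecompositionNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["DecompositionNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def dump(self, indent: int = 0) -> str:
        """Debug rendering: indented dot-bracket lines."""
        lines = [" " * indent + self.structure.dotbracket]
        for c in self.children:
            lines.append(c.dump(indent + 2))
        return "\n".join(lines)


def closing_pair_order(p1: tuple[int, int], p2: tuple[int, int]) -> int:
    """-1, 0 or 1: pairs from one closing set are ordered by their 5' index."""
    if p1[0] < p2[0]:
        return -1
    if p1[0] > p2[0]:
        return 1
    return 0


def _stem_of(comps: list[Component], pair: tuple[int, int]) -> Component:
    for c in comps:
        if c.kind is ComponentKind.STEM and pair in c.closing_pairs:
            return c
    raise ValueError(f"pair {pair} not in any stem")


def find_breaking_pairs(s: SecondaryStructure) -> list[tuple[int, int]]:
    """One breaking base pair per multi-loop (empty when there are none).

    The tag pair is the closing pair with minimum 5' index, the tag stem the
    stem containing it, and the breaking pair the minimum pair of that stem
    — its outermost pair.
    """
    comps = decompose(s)
    out = []
    for closing, branches in iter_multiloops(s):
        tag = min([closing, *branches], key=lambda p: p[0])
        stem = _stem_of(comps, tag)
        breaking = min(stem.closing_pairs, key=lambda p: p[0])
        out.append(breaking)
    return sorted(set(out))


def _split(
    node: DecompositionNode, bp: tuple[int, int]
) -> tuple[DecompositionNode, DecompositionNode]:
    i, j = bp
    s, seq, gp = node.structure.dotbracket, node.sequence, node.global_positions
    inner_db = s[i - 1 : j]
    inner_seq = seq[i - 1 : j]
    inner = DecompositionNode(
        structure=parse_dotbracket(inner_db, min_hairpin=0),
        sequence=inner_seq,
        offset=i,
        global_positions=gp[i - 1 : j],
        breaking_pair=bp,
        stub_pairs=tuple(
            (a - i + 1, b - i + 1)
            for a, b in node.stub_pairs
            if i <= a and b <= j
        ),
    )
    outer_db = s[: i - 1] + "()" + s[j:]
    outer_seq = seq[: i - 1] + seq[i - 1] + seq[j - 1] + seq[j:]
    shift = j - i - 1  # positions after j move left by this much
    outer_stubs = [(i, i + 1)]
    for a, b in node.stub_pairs:
        if b < i:
            outer_stubs.append((a, b))
        elif a > j:
            outer_stubs.append((a - shift, b - shift))
    outer = DecompositionNode(
        structure=parse_dotbracket(outer_db, min_hairpin=0),
        sequence=outer_seq,
        offset=1,
        global_positions=gp[: i - 1] + (gp[i - 1], gp[j - 1]) + gp[j:],
        breaking_pair=bp,
        stub_pairs=tuple(sorted(outer_stubs)),
    )
    return inner, outer


def _choose_breaking_pair(
    s: SecondaryStructure, candidates: list[tuple[int, int]]
) -> tuple[int, int]:
    """Most balanced split wins; ties go to the lowest 5' index."""
    n = s.length

    def imbalance(bp):
        left = bp[1] - bp[0] + 1       # closed child
        right = n - left + 2           # remainder incl. duplicated pair
        return abs(left - right)

    return min(candidates, key=lambda bp: (imbalance(bp), bp[0]))


def decompose_hierarchically(
    s: SecondaryStructure,
    seq: str,
    *,
    min_split_len: int = DEFAULT_MIN_SPLIT_LEN,
) -> DecompositionNode:
    """Recursively split structure and compatible sequence at breaking pairs.

    Recursion stops when a part has no multi-loop or is shorter than
    ``min_split_len``.  The sequence is sliced at exactly the same positions
    as the structure.
    """
    if len(seq) != s.length:
        raise ValueError(f"length mismatch: sequence {len(seq)} vs structure {s.length}")
    root = DecompositionNode(
        structure=s,
        sequence=seq,
        offset=1,
        global_positions=tuple(range(1, s.length + 1)),
    )
    _recurse(root, min_split_len)
    return root


def _recurse(node: DecompositionNode, min_split_len: int) -> None:
    if node.structure.length < min_split_len:
        return
    stubs = set(node.stub_pairs)
    n = node.structure.length
    # a stub is never re-split, and a pair spanning the whole part would
    # leave a bare "()" remainder — both splits are degenerate
    candidates = [
        bp
        for bp in find_breaking_pairs(node.structure)
        if bp not in stubs and not (bp[0] == 1 and bp[1] == n)
    ]
    if not candidates:
        return
    bp = _choose_breaking_pair(node.structure, candidates)
    inner, outer = _split(node, bp)
    node.children = [inner, outer]
    for child in node.children:
        _recurse(child, min_split_len)


def reassemble(node: DecompositionNode) -> tuple[str, str]:
    """Rebuild ``(dotbracket, sequence)`` from the leaves of a tree.

    The duplicated boundary pair is taken from the closed child.
    """
    if node.is_leaf:
        return node.structure.dotbracket, node.sequence
    inner_db, inner_seq = reassemble(node.children[0])
    outer_db, outer_seq = reassemble(node.children[1])
    i = node.children[0].offset
    db = outer_db[: i - 1] + inner_db + outer_db[i + 1 :]
    seq = outer_seq[: i - 1] + inner_seq + outer_seq[i + 1 :]
    return db, seq
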