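"""RNA secondary structures in dot-bracket notation and their loop decomposition.

All coordinates are 1-based and inclusive, matching the ``i.j`` base-pair
notation standard in the RNA literature.  A structure is pseudoknot-free by
construction: pairs are produced by stack matching of ``(`` and ``)``, so no
two pairs can cross.

The central operation is :func:`decompose`, which partitions the positions of
a structure into its structural components — stems (maximal helices of
stacked pairs), hairpin loops, internal loops, bulge loops, multi-loops and
the external loop.  Every position ``1..n`` belongs to exactly one component;
paired positions belong to the stem that contains their pair, unpaired
positions to the loop they lie in.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator

MIN_HAIRPIN = 3  # folding-engine convention: at least 3 unpaired bases in a hairpin


class StructureError(ValueError):
    """Invalid dot-bracket input; ``position`` is the offending 1-based index."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)


@dataclass(frozen=True)
class SecondaryStructure:
    """A parsed pseudoknot-free secondary structure.

    ``pairs`` maps each paired position to its partner in both directions
    (``pairs[i] == j`` and ``pairs[j] == i``).
    """

    dotbracket: str
    pairs: dict[int, int] = field(repr=False)

    @property
    def length(self) -> int:
        return len(self.dotbracket)

    def pair_list(self) -> list[tuple[int, int]]:
        """All pairs ``(i, j)`` with ``i < j``, sorted by ``i``."""
        return sorted((i, j) for i, j in self.pairs.items() if i < j)

    def partner(self, i: int) -> int | None:
        return self.pairs.get(i)

    def __len__(self) -> int:
        return len(self.dotbracket)


class ComponentKind(enum.Enum):
    STEM = "stem"
    HAIRPIN = "hairpin"
    INTERNAL = "internal"
    BULGE = "bulge"
    MULTI = "multi"
    EXTERNAL = "external"


@dataclass(frozen=True)
class GeometryKey:
    """Component kind plus the integer signature that fixes its geometry.

    Signatures: STEM ``(k,)`` stacked pairs; HAIRPIN ``(loop length,)``;
    BULGE ``(strand length,)``; INTERNAL ``(left, right)``; MULTI
    ``(branch count, seg0, seg1, ...)`` with unpaired segment lengths listed
    5'→3' starting after the closing pair; EXTERNAL ``(seg0, seg1, ...)``.
    """

    kind: ComponentKind
    signature: tuple[int, ...]


@dataclass(frozen=True)
class Component:
    """One structural element of a decomposed structure.

    ``spans`` are the ordered, disjoint 1-based inclusive position ranges the
    component owns; a zero-length loop segment is recorded as ``(start,
    start - 1)`` so that geometry is preserved even when no position is owned.
    ``closing_pairs`` are the base pairs bounding the component (for a stem,
    its own pairs outermost-first).
    """

    kind: ComponentKind
    spans: tuple[tuple[int, int], ...]
    closing_pairs: tuple[tuple[int, int], ...]
    key: GeometryKey

    @property
    def positions(self) -> tuple[int, ...]:
        out: list[int] = []
        for a, b in self.spans:
            out.extend(range(a, b + 1))
        return tuple(out)


def parse_dotbracket(text: str, *, min_hairpin: int = MIN_HAIRPIN) -> SecondaryStructure:
    """Parse a dot-bracket string via stack matching.

    Raises :class:`StructureError` naming the offending position for
    unbalanced input, foreign characters, or a hairpin loop shorter than
    ``min_hairpin`` (pass ``min_hairpin=0`` to accept boundary stubs produced
    by hierarchical splitting).
    """
    if not text:
        raise StructureError("empty structure")
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for pos, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError("unmatched ')'", pos)
            i = stack.pop()
            pairs[i] = pos
            pairs[pos] = i
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r}", pos)
    if stack:
        raise StructureError("unclosed '('", stack[0])
    if min_hairpin:
        for i, j in pairs.items():
            if i < j and j - i - 1 < min_hairpin:
                # innermost pairs close hairpins; an inner pair would sit between
                if not any(i < k < j for k in pairs):
                    raise StructureError(
                        f"hairpin loop shorter than {min_hairpin}", i
                    )
    return SecondaryStructure(dotbracket=text, pairs=pairs)


def hamming_distance(a: SecondaryStructure | str, b: SecondaryStructure | str) -> int:
    """Number of positions at which two equal-length dot-bracket strings differ."""
    sa = a.dotbracket if isinstance(a, SecondaryStructure) else a
    sb = b.dotbracket if isinstance(b, SecondaryStructure) else b
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    return sum(x != y for x, y in zip(sa, sb))


def _helices(s: SecondaryStructure) -> list[list[tuple[int, int]]]:
    """Maximal runs of stacked pairs, outermost pair first, sorted by 5' start."""
    plist = s.pair_list()
    pairset = set(plist)
    helices = []
    for i, j in plist:
        if (i - 1, j + 1) in pairset:
            continue  # not the outermost pair of its helix
        run = [(i, j)]
        while (run[-1][0] + 1, run[-1][1] - 1) in pairset:
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        helices.append(run)
    return helices


def _segments_between(s: SecondaryStructure, start: int, stop: int) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Scan positions ``start..stop`` at one nesting level.

    Returns ``(branches, segments)`` where branches are the outer pairs of
    child helices encountered and segments the (possibly zero-length)
    unpaired runs before, between and after them.
    """
    branches: list[tuple[int, int]] = []
    segments: list[tuple[int, int]] = []
    pos = start
    seg_start = start
    while pos <= stop:
        j = s.partner(pos)
        if j is None:
            pos += 1
        else:
            segments.append((seg_start, pos - 1))
            branches.append((pos, j))
            pos = j + 1
            seg_start = pos
    segments.append((seg_start, stop))
    return branches, segments


def decompose(s: SecondaryStructure) -> list[Component]:
    """Unique decomposition into stems and loops.

    Stems own their paired positions; each loop owns its unpaired positions.
    The external component is emitted only when unpaired exterior positions
    exist.  Components are returned sorted by their first position.
    """
    comps: list[Component] = []

    for run in _helices(s):
        k = len(run)
        i0, j0 = run[0]
        spans = ((i0, i0 + k - 1), (j0 - k + 1, j0))
        comps.append(
            Component(
                kind=ComponentKind.STEM,
                spans=spans,
                closing_pairs=tuple(run),
                key=GeometryKey(ComponentKind.STEM, (k,)),
            )
        )
        # the loop closed by this helix's innermost pair
        ci, cj = run[-1]
        branches, segments = _segments_between(s, ci + 1, cj - 1)
        seg_lens = tuple(b - a + 1 for a, b in segments)
        if not branches:
            comps.append(
                Component(
                    kind=ComponentKind.HAIRPIN,
                    spans=tuple(segments),
                    closing_pairs=((ci, cj),),
                    key=GeometryKey(ComponentKind.HAIRPIN, (seg_lens[0],)),
                )
            )
        elif len(branches) == 1:
            left, right = seg_lens
            if left and right:
                kind, sig = ComponentKind.INTERNAL, (left, right)
                spans = tuple(segments)
            else:
                # exactly one strand is non-empty (both empty would stack)
                kind, sig = ComponentKind.BULGE, (max(left, right),)
                spans = (segments[0] if left else segments[1],)
            comps.append(
                Component(
                    kind=kind,
                    spans=spans,
                    closing_pairs=((ci, cj), branches[0]),
                    key=GeometryKey(kind, sig),
                )
            )
        else:
            comps.append(
                Component(
                    kind=ComponentKind.MULTI,
                    spans=tuple(segments),
                    closing_pairs=((ci, cj), *branches),
                    key=GeometryKey(
                        ComponentKind.MULTI, (len(branches), *seg_lens)
                    ),
                )
            )

    # exterior: unpaired positions outside every helix
    branches, segments = _segments_between(s, 1, s.length)
    if any(b - a + 1 > 0 for a, b in segments):
        seg_lens = tuple(b - a + 1 for a, b in segments)
        comps.append(
            Component(
                kind=ComponentKind.EXTERNAL,
                spans=tuple(segments),
                closing_pairs=tuple(branches),
                key=GeometryKey(ComponentKind.EXTERNAL, seg_lens),
            )
        )

    comps.sort(key=lambda c: (min(c.positions) if c.positions else s.length + 1))
    return comps


def position_component_map(comps: list[Component]) -> dict[int, Component]:
    """Map every owned position to its component."""
    out: dict[int, Component] = {}
    for c in comps:
        for p in c.positions:
            out[p] = c
    return out


def iter_multiloops(s: SecondaryStructure) -> Iterator[tuple[tuple[int, int], list[tuple[int, int]]]]:
    """Yield ``(exterior closing pair, branch pairs)`` for each multi-loop."""
    pairset = set(s.pair_list())
    for i, j in sorted(pairset):
        branches, _ = _segments_between(s, i + 1, j - 1)
        if len(branches) >= 2:
            yield (i, j), branches


def has_multiloop(s: SecondaryStructure) -> bool:
    return next(iter_multiloops(s), None) is not None
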