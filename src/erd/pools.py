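"""Pools of natural sub-sequence fragments keyed by component geometry.

The design algorithm assembles candidate sequences from sub-sequences that
real RNAs use for the same structural element: every sequence of a corpus is
folded to its MFE structure, decomposed, and each component's sub-sequence is
filed under the component's geometry key (kind + size signature).  Sampling a
pool therefore reproduces, fragment by fragment, the base usage of natural
RNA rather than a uniform alphabet.

When a geometry has never been observed (or no stored fragment is compatible
with the active IUPAC mask), a fragment is generated de novo from the natural
base-pair and unpaired-base frequencies, so the naturalistic composition is
preserved even off-corpus.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

from .constraints import (
    IUPAC,
    ConstraintConflictError,
    normalize_sequence,
    pair_choices,
)
from .fold_engine import FoldEngine
from .struct_model import Component, ComponentKind, GeometryKey, decompose

logger = logging.getLogger(__name__)

#: Frequencies of canonical pair classes in natural paired regions.
NATURAL_PAIRED = {"AU": 0.39, "GC": 0.49, "GU": 0.12}
#: Base frequencies in natural unpaired regions.
NATURAL_UNPAIRED = {"A": 0.38, "C": 0.19, "G": 0.17, "U": 0.26}
#: Overall base frequencies in natural sequences.
NATURAL_TOTAL = {"A": 0.27, "C": 0.22, "G": 0.25, "U": 0.26}


@dataclass(frozen=True)
class Fragment:
    """Sub-sequence(s) filling one component.

    STEM fragments carry two strands of equal length ``k``, both written
    5'→3' (the 3' strand as it appears in the parent sequence), so strand
    position ``t`` of the first pairs with position ``k−1−t`` of the second.
    Loop fragments carry one (possibly empty) string per unpaired segment.
    """

    strands: tuple[str, ...]


@dataclass
class FragmentPool:
    """Multiset of fragments per geometry key (duplicates weight sampling)."""

    table: dict[GeometryKey, list[Fragment]] = field(default_factory=dict)
    source: str = "synthetic"

    def add(self, key: GeometryKey, frag: Fragment) -> None:
        self.table.setdefault(key, []).append(frag)

    def __len__(self) -> int:
        return sum(len(v) for v in self.table.values())


def extract_fragment(seq: str, comp: Component) -> Fragment:
    """Slice the component's strands out of its parent sequence."""
    return Fragment(tuple(seq[a - 1 : b] for a, b in comp.spans))


def build_pools(corpus: list[str], engine: FoldEngine) -> FragmentPool:
    """Fold every corpus sequence, decompose, and bin sub-sequences by geometry.

    Sequences the engine cannot fold are skipped with a warning.  Identical
    sequences contribute their fragments once per occurrence (multiset
    semantics — sampling is frequency weighted).
    """
    if not corpus:
        raise ValueError("empty corpus")
    pool = FragmentPool(source="corpus")
    for idx, raw in enumerate(corpus):
        seq = normalize_sequence(raw)
        try:
            structure, _ = engine.fold(seq)
        except Exception as exc:  # pragma: no cover - engine failures are rare
            logger.warning("skipping corpus sequence %d: fold failed (%s)", idx, exc)
            continue
        for comp in decompose(structure):
            pool.add(comp.key, extract_fragment(seq, comp))
    return pool


def generate_synthetic_corpus(
    n_sequences: int,
    length_range: tuple[int, int],
    rng: random.Random,
) -> list[str]:
    """Random RNA sequences with naturalistic overall base composition.

    Bases are drawn i.i.d. from the natural total distribution
    (A 0.27, C 0.22, G 0.25, U 0.26); lengths uniformly from
    ``length_range`` (inclusive).  Deterministic for a fixed ``rng`` state.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range {length_range}")
    bases = list(NATURAL_TOTAL)
    weights = [NATURAL_TOTAL[b] for b in bases]
    out = []
    for _ in range(n_sequences):
        length = rng.randint(lo, hi)
        out.append("".join(rng.choices(bases, weights=weights, k=length)))
    return out


def _fragment_matches_mask(frag: Fragment, mask: tuple[str, ...] | None) -> bool:
    if mask is None:
        return True
    for strand, mstrand in zip(frag.strands, mask):
        if any(b not in IUPAC[m] for b, m in zip(strand, mstrand)):
            return False
    return True


def _weighted_pair(choices: list[str], rng: random.Random) -> str:
    # each unordered class splits its weight evenly over its two orientations
    weights = [
        NATURAL_PAIRED[p if p in NATURAL_PAIRED else p[::-1]] / 2.0 for p in choices
    ]
    return rng.choices(choices, weights=weights, k=1)[0]


def _weighted_base(allowed: frozenset[str], rng: random.Random) -> str:
    bases = sorted(allowed)
    weights = [NATURAL_UNPAIRED[b] for b in bases]
    return rng.choices(bases, weights=weights, k=1)[0]


def denovo_fragment(
    key: GeometryKey, rng: random.Random, mask: tuple[str, ...] | None = None
) -> Fragment:
    """Generate a fragment matching ``key`` and ``mask`` from natural frequencies.

    Paired bases follow the natural pair-class distribution (AU 0.39,
    GC 0.49, GU 0.12, orientations equiprobable within a class); unpaired
    bases the natural unpaired distribution, both renormalised over whatever
    the mask allows.
    """
    if key.kind is ComponentKind.STEM:
        (k,) = key.signature
        m5 = mask[0] if mask else "N" * k
        m3 = mask[1] if mask else "N" * k
        s5, s3 = [""] * k, [""] * k
        for t in range(k):
            choices = pair_choices(m5[t], m3[k - 1 - t])
            if not choices:
                raise ConstraintConflictError(
                    [(t + 1, k - t, m5[t], m3[k - 1 - t])]
                )
            pair = _weighted_pair(choices, rng)
            s5[t] = pair[0]
            s3[k - 1 - t] = pair[1]
        return Fragment(("".join(s5), "".join(s3)))

    # loop signatures are the segment lengths; MULTI prepends its branch count
    seg_lens = key.signature[1:] if key.kind is ComponentKind.MULTI else key.signature
    strands = []
    for si, ln in enumerate(seg_lens):
        mstrand = mask[si] if mask else "N" * ln
        chars = []
        for t in range(ln):
            allowed = IUPAC[mstrand[t]]
            chars.append(_weighted_base(allowed, rng))
        strands.append("".join(chars))
    return Fragment(tuple(strands))


def _relaxed_multi_candidates(
    pool: FragmentPool, key: GeometryKey
) -> list[Fragment]:
    """Multi-loop fallback: same branch count and total unpaired length,
    re-cut to the requested segment lengths."""
    branch_count = key.signature[0]
    seg_lens = key.signature[1:]
    total = sum(seg_lens)
    out = []
    for other, frags in pool.table.items():
        if other.kind is not ComponentKind.MULTI:
            continue
        if other.signature[0] != branch_count or sum(other.signature[1:]) != total:
            continue
        for f in frags:
            joined = "".join(f.strands)
            cut, pos = [], 0
            for ln in seg_lens:
                cut.append(joined[pos : pos + ln])
                pos += ln
            out.append(Fragment(tuple(cut)))
    return out


def sample_fragment(
    pool: FragmentPool,
    key: GeometryKey,
    rng: random.Random,
    mask: tuple[str, ...] | None = None,
) -> Fragment:
    """Uniform draw among stored fragments compatible with ``key`` and ``mask``.

    Falls back (multi-loops: first to a relaxed key with equal branch count
    and total unpaired length) to de-novo generation when nothing stored is
    compatible; the returned fragment always matches key and mask.
    """
    candidates = [
        f for f in pool.table.get(key, []) if _fragment_matches_mask(f, mask)
    ]
    if not candidates and key.kind is ComponentKind.MULTI:
        candidates = [
            f
            for f in _relaxed_multi_candidates(pool, key)
            if _fragment_matches_mask(f, mask)
        ]
    if candidates:
        return rng.choice(candidates)
    return denovo_fragment(key, rng, mask)


# ---------------------------------------------------------------------------
# on-disk pool cache: a small tab-separated dialect, one fragment per row
# ---------------------------------------------------------------------------

POOL_FORMAT_VERSION = "1"


def save_pool(pool: FragmentPool, path) -> None:
    """Write ``kind<TAB>signature-csv<TAB>strands-csv`` rows with a # header."""
    with open(path, "w") as fh:
        fh.write(f"# erd-pool-cache v{POOL_FORMAT_VERSION} source={pool.source}\n")
        for key in sorted(pool.table, key=lambda k: (k.kind.value, k.signature)):
            for frag in pool.table[key]:
                sig = ",".join(map(str, key.signature))
                strands = ",".join(frag.strands)
                fh.write(f"{key.kind.value}\t{sig}\t{strands}\n")


def load_pool(path) -> FragmentPool:
    pool = FragmentPool(source=str(path))
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            kind_s, sig_s, strands_s = line.split("\t")
            key = GeometryKey(
                ComponentKind(kind_s),
                tuple(int(x) for x in sig_s.split(",") if x != ""),
            )
            strands = tuple(strands_s.split(","))
            pool.add(key, Fragment(strands))
    return pool
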