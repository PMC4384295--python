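"""Evaluation statistics for design benchmarks.

Implements the standard figures of merit for inverse-folding methods: the
success count SC and expected time per success E_T; the expected energy
distance E_ED between designed and natural sequences; the expected pairwise
similarity E_SA among the designs for one structure (a diversity measure —
lower is more diverse); the expected similarity E_SN of designs to their
natural counterparts; and the distribution of nucleotides over paired and
unpaired regions.

Similarity is the percent identity of an optimal global Needleman–Wunsch
alignment under the EMBOSS ``needle`` default scheme: EDNAFULL-equivalent
nucleotide scoring (match +5, mismatch −4), gap open 10, gap extend 0.5,
end gaps free; identity = matches / alignment length (gap columns included)
× 100.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

from .struct_model import SecondaryStructure

INF = math.inf


def expected_time(total_time: float, sc: int) -> float:
    """E_T = total execution time / success count; infinity when SC = 0."""
    if sc == 0:
        return INF
    return total_time / sc


def expected_energy_distance(designed: list[float], natural: list[float]) -> float:
    """E_ED = mean |E_designed − E_natural| over successful designs."""
    if len(designed) != len(natural):
        raise ValueError("designed and natural energy lists must be matched")
    if not designed:
        return INF
    return sum(abs(d - n) for d, n in zip(designed, natural)) / len(designed)


@lru_cache(maxsize=1)
def _aligner():
    from Bio.Align import PairwiseAligner

    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 5.0
    a.mismatch_score = -4.0
    a.open_gap_score = -10.0
    a.extend_gap_score = -0.5
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # needle's default endweight=false: terminal gaps are free
        a.target_end_gap_score = 0.0
        a.query_end_gap_score = 0.0
    return a


def similarity(a: str, b: str, *, metric: str = "identity") -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Deterministic and symmetric: the pair is aligned in a canonical order
    and the first optimal alignment reported.  ``metric="similar"`` counts
    positively-scoring aligned columns instead of exact matches (for the
    plain A/C/G/U alphabet the two coincide).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    x, y = (a, b) if a <= b else (b, a)
    aln = _aligner().align(x, y)[0]
    counts = aln.counts()
    identities, mismatches, gaps = counts.identities, counts.mismatches, counts.gaps
    length = identities + mismatches + gaps
    if metric == "identity":
        hits = identities
    elif metric == "similar":
        hits = sum(
            1
            for ca, cb in zip(str(aln[0]), str(aln[1]))
            if ca != "-" and cb != "-" and (5.0 if ca == cb else -4.0) > 0
        )
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return 100.0 * hits / length


def expected_similarity_within(groups: list[list[str]]) -> float:
    """E_SA: mean over structures of the mean pairwise similarity among that
    structure's designs (all SC·(SC−1)/2 pairs); groups of fewer than two
    designs are skipped."""
    per_structure = []
    for group in groups:
        m = len(group)
        if m < 2:
            continue
        total = 0.0
        for i in range(m):
            for j in range(i + 1, m):
                total += similarity(group[i], group[j])
        per_structure.append(total / (m * (m - 1) / 2))
    if not per_structure:
        raise ValueError("no group has at least two sequences")
    return sum(per_structure) / len(per_structure)


def expected_similarity_to_natural(designed: list[str], natural: list[str]) -> float:
    """E_SN: mean similarity of each design to its natural counterpart."""
    if len(designed) != len(natural):
        raise ValueError("designed and natural lists must be matched")
    if not designed:
        raise ValueError("empty input")
    return sum(similarity(d, n) for d, n in zip(designed, natural)) / len(designed)


@dataclass
class DistributionTable:
    """Fractions of pair classes and bases; each group sums to 1 when its
    denominator is nonzero.  Non-canonical pairs land in ``other_pairs``
    (a count, excluded from the paired normalisation)."""

    paired: dict[str, float]
    unpaired: dict[str, float]
    total: dict[str, float]
    other_pairs: int = 0


def nucleotide_distribution(
    seqs: list[str], structures: list[SecondaryStructure]
) -> DistributionTable:
    """Tabulate pair-class and base usage over matched sequences/structures."""
    if len(seqs) != len(structures):
        raise ValueError("sequence and structure lists must be matched")
    pair_counts = {"AU": 0, "GC": 0, "GU": 0}
    unpaired_counts = {b: 0 for b in "ACGU"}
    total_counts = {b: 0 for b in "ACGU"}
    other = 0
    for seq, s in zip(seqs, structures):
        if len(seq) != s.length:
            raise ValueError(f"length mismatch: {len(seq)} vs {s.length}")
        paired_pos = set(s.pairs)
        for p, base in enumerate(seq, start=1):
            total_counts[base] += 1
            if p not in paired_pos:
                unpaired_counts[base] += 1
        for i, j in s.pair_list():
            cls = "".join(sorted((seq[i - 1], seq[j - 1])))
            cls = {"AU": "AU", "CG": "GC", "GU": "GU"}.get(cls)
            if cls is None:
                other += 1
            else:
                pair_counts[cls] += 1

    def norm(d: dict) -> dict:
        tot = sum(d.values())
        return {k: v / tot for k, v in d.items()} if tot else {}

    return DistributionTable(
        paired=norm(pair_counts),
        unpaired=norm(unpaired_counts),
        total=norm(total_counts),
        other_pairs=other,
    )
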