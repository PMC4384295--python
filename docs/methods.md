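# Methods

## Model and scope

`erd` performs RNA inverse folding: search for sequences whose MFE structure
under a nearest-neighbor thermodynamic model equals a given pseudoknot-free
target, optionally under per-position IUPAC constraints and a free-energy
interval evaluated *on the target structure*. Structures are dot-bracket
strings; coordinates are 1-based inclusive throughout, pairs written `i.j`
with i < j. Pseudoknots, tertiary contacts and base triples are out of
scope, as are ensemble objectives (partition-function defect); the fitness
is purely the Hamming distance between dot-bracket strings plus the energy
criterion.

## Structure decomposition

`decompose` partitions positions 1..n into components. A stem is a *maximal*
helix of strictly stacked pairs (i+t).(j−t); by maximality an interior loop
of size (0,0) cannot occur. The loop closed by a helix's innermost pair is
classified by its enclosed branches: 0 → hairpin, 1 → internal (both strands
non-empty) or bulge (one strand), ≥2 → multi-loop. Geometry keys are
(kind, integer signature): stem `(k)`, hairpin `(loop)`, bulge `(strand)`,
internal `(left, right)`, multi `(branch count, unpaired segment lengths
5'→3' starting after the closing pair)`, external `(segment lengths)`.
Unpaired exterior bases are keyed as one component by their segment lengths
(segments between exterior helices, including zero-length gaps); the
external component is omitted when no exterior base is unpaired. The minimum
hairpin loop is 3 nt, the folding-engine convention; input violating it is
rejected at parse time, but internally constructed sub-structures (see
boundary stubs below) may relax the check.

## Fragment pools

Every corpus sequence is folded to its MFE structure — corpus structures are
re-predicted rather than taken from any annotation, matching how the pools
are meant to mirror the folding engine's own preferences — then decomposed,
and each component's sub-sequence stored under its geometry key. Pools are
multisets: repeated fragments weight sampling by frequency. Stem fragments
store both strands 5'→3' and are complementary (Watson-Crick + GU wobble) by
construction.

Sampling is uniform among stored fragments compatible with the active mask
slice. When nothing compatible is stored, fallbacks preserve naturalistic
composition: multi-loop keys first relax to (same branch count, same total
unpaired length, re-cut); otherwise a fragment is generated de novo with
paired bases drawn from the natural pair-class distribution (AU 0.39,
GC 0.49, GU 0.12; orientations equiprobable) and unpaired bases from the
natural unpaired distribution (A 0.38, C 0.19, G 0.17, U 0.26), each
renormalised over what the mask admits. A mask admitting no canonical pair
at some paired position raises a constraint-conflict error listing the
offending pairs.

The synthetic corpus generator replaces an external natural-sequence
database: i.i.d. bases at the natural *total* composition (A 0.27, C 0.22,
G 0.25, U 0.26), lengths uniform in a range (defaults 300 sequences of
50–150 nt — enough that common geometries up to `STEM(~8)` and typical loop
sizes are populated, while pools build in about a second). What it does not
emulate: real corpora have covariation, motif reuse and family structure, so
pool fragments here are "natural" only in composition, not in phylogenetic
signal. Success rates and distribution statistics transfer to real corpora
only to the extent that composition, not homology, drives them.

## Hierarchical decomposition

For each multi-loop the closing pairs (exterior + branch pairs) are ordered
by 5' index; the minimum is the tag base pair — necessarily the multi-loop's
exterior closing pair — the stem containing it the tag stem, and that stem's
minimum (outermost) pair the breaking base pair. When several multi-loops
offer breaking pairs at one recursion level, the pair minimising
|len(closed part) − len(remainder)| is chosen, ties to the lowest 5' index.
We read "several breaking pairs" as several *multi-loops'* candidates at one
level; the alternative reading (several candidates within one stem) never
arises because a stem contributes exactly one minimum pair.

A split at i.j yields the closed sub-structure i..j as one child and the
remainder with i.j retained as a zero-loop boundary stub `()` as the other,
so both children are balanced; on reassembly the stub is dropped and the
closed child's copy of the pair (structure and sequence) is kept, making
reassembly character-exact. Recursion stops below 40 nt (configurable) or
when no non-degenerate candidate remains (stub pairs and a pair spanning the
entire part are excluded). During leaf optimisation the stub positions are
excluded from the Hamming distance and from mutation: an isolated `()`
cannot fold in isolation, and those positions are judged in their real
context by the final full-length polish.

## The evolutionary search

The initial sequence is assembled component-by-component from the pools
(mask enforced at sampling). Assembly is retried up to 1000 times for the
sequence constraints, then up to 1000 further times for the energy interval;
on exhaustion the attempt closest to the acceptable energies is kept and
flagged. Each generation: every candidate's energy on the target is
computed; candidates are sorted ascending by energy — or by |E − center|
when a finite interval is set — the top three are folded; among them plus
the incumbent best, the three with smallest Hamming distance survive (ties
by the energy criterion, then stable input order), and each survivor breeds
the next generation by component mutation. Population growth is bounded at
30 variants per parent (uniform subsample of mismatched components when more
exist). The iteration cap (default 250) applies per optimisation loop — per
leaf and once more for the final polish — and is exposed as configuration.
One seeded `random.Random` is threaded through everything; identical
(target, pools, seed, engine) give bitwise-identical results.

Degenerate regime worth knowing: when a mask leaves exactly one compatible
fragment for a component, mutation cannot vary that component (de-novo
fallback triggers only when *no* stored fragment is compatible), and when
the MFE structure already matches the target but the energy misses the
interval, no mismatched components exist to mutate, so the search can
stagnate at its iteration cap. Both surface honestly as `success=False`
with the energy flag unset. Larger corpora dilute the first effect.

## Energies and engines

The reference engine is the ViennaRNA scripting interface (`fold` /
`eval_structure`), Turner parameters, 37 °C default; engine name and version
are recorded in every result, and energies are never comparable across
engine versions. The toy engine is a deterministic Nussinov-style
maximum-pairing folder (−1 per canonical pair, minimum hairpin 3, ties
resolved by pairing each position with its smallest admissible partner that
preserves optimality, scanning 5'→3'), used to keep unit tests hermetic and
fast; it satisfies the same contract (`energy_of(seq, fold(seq)) ==
fold(seq).energy`).

Interval endpoints are inclusive (default (−∞, 0]); input `T` is normalised
to `U`.

## Evaluation metrics

SC is the number of successful designs; E_T = total time / SC (∞ at SC = 0);
E_ED the mean |E_designed − E_natural|; E_SA the mean over structures of the
mean pairwise similarity among that structure's designs; E_SN the mean
similarity of designs to their natural counterparts. Similarity is the
percent identity of a global Needleman–Wunsch alignment under the EMBOSS
`needle` defaults: match +5 / mismatch −4 (EDNAFULL on A/C/G/U), gap open
10, gap extend 0.5, terminal gaps free, identity = matches / alignment
length including gap columns × 100. We report needle's *Identity* (an
alternative positive-score "similar" count is available behind a flag; on
the plain RNA alphabet the two coincide). When several alignments are
co-optimal the first reported by the aligner is used, with the input pair
canonically ordered so the measure is symmetric. The nucleotide-distribution
table counts pairs as unordered classes {AU, GC, GU} (non-canonical pairs go
to a logged bucket excluded from normalisation) and unpaired/total bases per
letter; each group is normalised to sum to 1 when its denominator is
non-zero.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` size their simulations to run
comfortably on one CPU: 1000 random structures (20–300 nt) for the
partition/round-trip invariants, 200 multi-loop structures against the
brute-force breaking-pair oracle, 50 stem-loop targets (≤ 50 nt) for the
success floor, 200 constrained runs (10–30 % fixed positions, mixed
intervals, iteration cap 60 — a soundness check, not a success benchmark),
and a natural-like benchmark of 10 folded-sequence targets × 5 designs for
the E_ED/E_SA/E_SN statistics. Exhaustive checks (IUPAC table, toy-folder
optimality) are exhaustive up to the sizes enumeration permits (all
sequences ≤ 6 nt, random thereafter).

## Known limitations

Lonely (isolated) base pairs in random targets are valid input but are
frequently unrepresentable as MFE structures under the thermodynamic
engine's defaults, so arbitrary random targets plateau below 100 % success —
the success floor is therefore stated for stem-loop targets. The energy
interval applies to the full-length sequence only; leaves run under the
default interval and the polish loop enforces the real one. Hamming distance
on dot-bracket strings under-weights pair identity (a shifted helix scores
few mismatches); this is the classic trade-off of the fitness and is kept
for fidelity to the method.
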