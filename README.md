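# erd — evolutionary RNA design under sequence and energy constraints

`erd` solves the RNA inverse-folding problem: given a target secondary
structure in dot-bracket notation, find RNA sequences whose predicted
minimum-free-energy (MFE) structure equals the target. It is aimed at
anyone who needs designed RNAs that *look like natural RNAs* — ribozyme and
riboswitch engineering, artificial miRNA design, RNA nanotechnology — and
who may additionally need to fix positions of the sequence (as IUPAC codes,
e.g. to preserve a protein-binding motif) or to demand a specific stability,
as a free-energy interval [E_min, E_max] in kcal/mol over the target
structure.

## The algorithm

Any pseudoknot-free secondary structure decomposes uniquely into structural
components: stems (helices of stacked pairs), hairpin loops, internal loops,
bulges, multi-loops and the external loop. `erd` exploits this three ways:

1. **Fragment pools.** A corpus of RNA sequences is folded (ViennaRNA,
   Turner parameters at 37 °C); each predicted structure is decomposed, and
   every component's sub-sequence is filed under the component's geometry
   key (kind + sizes, e.g. `STEM(6)` or `INTERNAL(2,3)`). Candidate
   sequences are assembled from these pools, so designs inherit the base and
   base-pair usage of real RNA instead of drifting to the all-GC designs
   many optimisers produce.

2. **Hierarchical decomposition.** Folding costs O(n³), so long targets are
   split where multi-loops occur. For each multi-loop, closing pairs are
   ordered by 5′ index i (i.j < k.l ⟺ i < k); the minimum closing pair is
   the *tag base pair*, the stem containing it the *tag stem*, and the tag
   stem's minimum pair the *breaking base pair*, at which structure and
   sequence are split (most-balanced split first). Leaves are optimised
   independently, reassembled, and polished full-length.

3. **Component-level evolution.** Each generation, positions where a
   parent's MFE structure disagrees with the target select the components to
   mutate; one offspring per component gets that component's fragment
   resampled (mask-compatibly — constraints can never be violated, only
   enforced at sampling time). Candidates are ranked by their energy *on the
   target* (or by |E − center| when a finite energy interval is given), the
   three most promising are folded, and the three smallest-Hamming-distance
   candidates survive. The loop stops at Hamming distance 0 with all
   constraints met, or after 250 generations (best found is returned, with
   per-constraint flags). There is no crossover, and no nucleotide-level
   mutation.

Because no corpus of natural sequences is bundled, the package ships a
synthetic-corpus generator whose base composition matches
natural totals (A 0.27, C 0.22, G 0.25, U 0.26); de-novo fragment fallback
likewise draws pairs from the natural pair-class distribution (AU 0.39,
GC 0.49, GU 0.12).

## Worked example

Design two sequences for a 16-nt stem-loop, fixing positions 3–4 to `GG`
and demanding a free energy between −8 and −4 kcal/mol on the target:

```
$ printf '((((((....))))))\nNNGGNNNNNNNNNNNN\n' > target.db
$ erd design --structure target.db -n 2 --seed 7 --emin -8 --emax -4
# erd v1.0.0 engine=ViennaRNA-2.7.2@37C seed=7 structure=target.db emin=-8 emax=-4 max_iter=250
design	length	distance	energy	iterations	seed	success	sequence
design_000	16	0	-7.40	1	700021	1	GGGGUCAACCGACCUC
design_001	16	0	-5.50	1	700022	1	GUGGCUACGCAGCUAC
```

`distance` is the Hamming distance between the design's MFE structure and
the target (0 = exact fold); `energy` its free energy on the target in
kcal/mol (both inside the requested interval); `iterations` the generations
used; `success` requires distance 0 plus both constraints. Both designs
carry `GG` at positions 3–4. Exit status is 0 when at least one design
succeeds, 2 for infeasible input (e.g. a mask fixing a base pair to
non-complementary nucleotides — reported with the offending positions).

Other subcommands: `erd synth-corpus` (naturalistic random corpus),
`erd build-pools` (fold a FASTA corpus into a reusable pool cache),
`erd metrics` (SC, E_T, E_ED, E_SA, E_SN summaries of a design table).
The same functionality is available as a library:

```python
from erd import ConstraintSet, ViennaEngine, build_pools, design, parse_dotbracket
from erd.pools import generate_synthetic_corpus
import random

engine = ViennaEngine()
pool = build_pools(generate_synthetic_corpus(300, (50, 150), random.Random(0)), engine)
res = design(parse_dotbracket("((((((....))))))"), ConstraintSet(), pool, engine, seed=1)
print(res.seq, res.distance, res.energy_on_target)
```

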