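"""The evolutionary search: component-level mutation toward a target structure.

The search keeps a sequence always *compatible* with the target (every paired
position complementary, including GU wobble) and always mask-compliant —
constraints are enforced at fragment-sampling time, never repaired after the
fact.  Fitness is the Hamming distance between the candidate's MFE structure
and the target; mutation replaces the sub-sequence of a whole structural
component (never a single nucleotide) whose positions disagree, drawing the
replacement from the fragment pools.  There is no crossover.

Selection per generation: all candidates are scored by their free energy on
the *target* structure (cheap), the three most promising are folded
(expensive), and of those plus the incumbent best the three with smallest
Hamming distance survive.  "Most promising" means lowest energy — or, when a
finite energy interval is requested, smallest distance to the interval
center.

Long targets are first split at multi-loops (see :mod:`erd.hierarchy`), each
leaf optimised independently, and the reassembled sequence polished by the
same loop on the full structure.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .constraints import (
    ConstraintConflictError,
    ConstraintSet,
    detect_conflicts,
    energy_in_range,
    interval_distance,
    sequence_satisfies,
)
from .fold_engine import FoldEngine
from .hierarchy import DecompositionNode, decompose_hierarchically, reassemble
from .pools import FragmentPool, sample_fragment
from .struct_model import (
    Component,
    ComponentKind,
    SecondaryStructure,
    decompose,
    hamming_distance,
    position_component_map,
)

DEFAULT_MAX_ITER = 250
DEFAULT_VARIANT_CAP = 30
MAX_INITIAL_TRIES = 1000


@dataclass
class Candidate:
    """A sequence under evaluation against a fixed target structure."""

    seq: str
    energy_on_target: float | None = None
    mfe_structure: SecondaryStructure | None = None
    distance: int | None = None


@dataclass
class DesignResult:
    """Outcome of one design run; ``success`` iff the sequence refolds to the
    target and meets both constraint kinds."""

    seq: str
    distance: int
    energy_on_target: float
    iterations_used: int
    sequence_constraints_met: bool
    energy_constraint_met: bool
    success: bool
    seed: int | None = None
    engine: str = ""
    mfe_structure: str = ""


def _mask_slices(comp: Component, mask: str | None) -> tuple[str, ...] | None:
    if mask is None:
        return None
    return tuple(mask[a - 1 : b] for a, b in comp.spans)


def _write_fragment(seq: list[str], comp: Component, frag) -> None:
    for (a, b), strand in zip(comp.spans, frag.strands):
        seq[a - 1 : b] = strand


def assemble(
    target: SecondaryStructure,
    comps: list[Component],
    pools: FragmentPool,
    cs: ConstraintSet,
    rng: random.Random,
) -> str:
    """Fill every component of the target with a sampled fragment."""
    seq = [""] * target.length
    for comp in comps:
        frag = sample_fragment(pools, comp.key, rng, _mask_slices(comp, cs.mask))
        _write_fragment(seq, comp, frag)
    return "".join(seq)


def build_initial_sequence(
    target: SecondaryStructure,
    pools: FragmentPool,
    cs: ConstraintSet,
    engine: FoldEngine,
    rng: random.Random,
) -> tuple[Candidate, bool, bool]:
    """Assemble a compatible starting sequence honouring the constraints.

    Sequence constraints are retried up to 1000 times, then the free energy
    on the target is checked against the interval with up to 1000 further
    assemblies; on exhaustion the best attempt (closest to the acceptable
    energies) is returned with its constraint flags.
    """
    conflicts = detect_conflicts(target, cs.mask)
    if conflicts:
        raise ConstraintConflictError(conflicts)
    comps = decompose(target)

    seq = None
    seq_ok = False
    for _ in range(MAX_INITIAL_TRIES):
        seq = assemble(target, comps, pools, cs, rng)
        if sequence_satisfies(seq, cs):
            seq_ok = True
            break

    best_seq, best_e, best_gap = None, None, float("inf")
    energy_ok = False
    for _ in range(MAX_INITIAL_TRIES):
        e = engine.energy_of(seq, target)
        gap = interval_distance(e, cs)
        if gap < best_gap:
            best_seq, best_e, best_gap = seq, e, gap
        if energy_in_range(e, cs):
            energy_ok = True
            break
        seq = assemble(target, comps, pools, cs, rng)
    return Candidate(seq=best_seq, energy_on_target=best_e), seq_ok, energy_ok


def make_population(
    parent: Candidate,
    target: SecondaryStructure,
    comps: list[Component],
    pools: FragmentPool,
    cs: ConstraintSet,
    rng: random.Random,
    *,
    variant_cap: int = DEFAULT_VARIANT_CAP,
    ignore_positions: frozenset[int] = frozenset(),
) -> list[Candidate]:
    """Parent plus one offspring per component covering a mismatched position.

    Mutation is strictly component-level: each offspring equals the parent
    except that one component's fragment is resampled (mask-compatibly).
    When more than ``variant_cap`` components mismatch, a uniform subset is
    mutated.
    """
    if parent.mfe_structure is None:
        raise ValueError("parent must be folded before breeding")
    pos_map = position_component_map(comps)
    mismatched: list[Component] = []
    seen: set[int] = set()
    for p in range(1, target.length + 1):
        if p in ignore_positions:
            continue
        if parent.mfe_structure.dotbracket[p - 1] != target.dotbracket[p - 1]:
            comp = pos_map[p]
            if id(comp) not in seen:
                seen.add(id(comp))
                mismatched.append(comp)
    if len(mismatched) > variant_cap:
        mismatched = rng.sample(mismatched, variant_cap)
    population = [parent]
    for comp in mismatched:
        frag = sample_fragment(pools, comp.key, rng, _mask_slices(comp, cs.mask))
        child = list(parent.seq)
        _write_fragment(child, comp, frag)
        population.append(Candidate(seq="".join(child)))
    return population


def evaluate_and_select(
    pop: list[Candidate],
    target: SecondaryStructure,
    best_so_far: Candidate | None,
    cs: ConstraintSet,
    engine: FoldEngine,
    *,
    ignore_positions: frozenset[int] = frozenset(),
) -> tuple[list[Candidate], Candidate]:
    """Energy-sort the population, fold the three most promising, keep the
    three smallest-distance candidates (incumbent best included)."""
    if not pop:
        raise ValueError("empty population")
    for c in pop:
        if c.energy_on_target is None:
            c.energy_on_target = engine.energy_of(c.seq, target)

    def energy_rank(c: Candidate) -> float:
        if cs.has_finite_interval:
            return abs(c.energy_on_target - cs.interval_center)
        return c.energy_on_target

    ordered = sorted(pop, key=energy_rank)  # stable: ties keep input order
    finalists = ordered[:3]
    for c in finalists:
        if c.mfe_structure is None:
            c.mfe_structure, _ = engine.fold(c.seq)
        if c.distance is None:
            c.distance = _masked_distance(
                c.mfe_structure, target, ignore_positions
            )
    if best_so_far is not None and all(b is not best_so_far for b in finalists):
        finalists = finalists + [best_so_far]
    finalists.sort(key=lambda c: (c.distance, energy_rank(c)))
    survivors = finalists[:3]
    return survivors, survivors[0]


def _masked_distance(
    mfe: SecondaryStructure,
    target: SecondaryStructure,
    ignore_positions: frozenset[int],
) -> int:
    if not ignore_positions:
        return hamming_distance(mfe, target)
    return sum(
        1
        for p in range(1, target.length + 1)
        if p not in ignore_positions
        and mfe.dotbracket[p - 1] != target.dotbracket[p - 1]
    )


def optimize(
    target: SecondaryStructure,
    start: Candidate,
    pools: FragmentPool,
    cs: ConstraintSet,
    engine: FoldEngine,
    rng: random.Random,
    *,
    max_iter: int = DEFAULT_MAX_ITER,
    variant_cap: int = DEFAULT_VARIANT_CAP,
    ignore_positions: frozenset[int] = frozenset(),
) -> tuple[Candidate, int]:
    """Run the generation loop until distance 0 (with the energy constraint
    met) or ``max_iter`` generations; returns (best candidate, iterations)."""
    comps = decompose(target)
    if start.mfe_structure is None:
        start.mfe_structure, _ = engine.fold(start.seq)
    if start.energy_on_target is None:
        start.energy_on_target = engine.energy_of(start.seq, target)
    start.distance = _masked_distance(start.mfe_structure, target, ignore_positions)

    def done(c: Candidate) -> bool:
        return c.distance == 0 and energy_in_range(c.energy_on_target, cs)

    best = start
    survivors = [start]
    iterations = 0
    while iterations < max_iter and not done(best):
        pop: list[Candidate] = []
        seen_seqs: set[str] = set()
        for s in survivors:
            for c in make_population(
                s, target, comps, pools, cs, rng,
                variant_cap=variant_cap, ignore_positions=ignore_positions,
            ):
                if c.seq not in seen_seqs:
                    seen_seqs.add(c.seq)
                    pop.append(c)
        survivors, best = evaluate_and_select(
            pop, target, best, cs, engine, ignore_positions=ignore_positions
        )
        iterations += 1
    return best, iterations


def _leaf_constraints(node: DecompositionNode, cs: ConstraintSet) -> ConstraintSet:
    # the energy interval constrains the full-length sequence only; leaves
    # run under the default interval, the final polish under the real one
    mask = None
    if cs.mask is not None:
        mask = "".join(cs.mask[g - 1] for g in node.global_positions)
    return ConstraintSet(mask=mask)


def design(
    target: SecondaryStructure,
    cs: ConstraintSet,
    pools: FragmentPool,
    engine: FoldEngine,
    *,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
    hierarchical: bool = True,
    min_split_len: int = 40,
    variant_cap: int = DEFAULT_VARIANT_CAP,
) -> DesignResult:
    """Design one sequence folding into ``target`` under the constraints.

    With ``hierarchical`` on (the default) the target is split at
    multi-loops, each leaf optimised independently, the parts reassembled,
    and the full sequence polished by the same loop.  Fully deterministic
    for a fixed (target, pools, seed, engine).
    """
    rng = random.Random(seed)
    start, seq_ok, energy_ok = build_initial_sequence(target, pools, cs, engine, rng)
    total_iters = 0

    if hierarchical:
        tree = decompose_hierarchically(target, start.seq, min_split_len=min_split_len)
        leaves = tree.leaves()
        if len(leaves) > 1:
            for leaf in leaves:
                # boundary-stub copies cannot fold in isolation; their
                # positions are judged only during the final polish
                ignore = frozenset(
                    p for a, b in leaf.stub_pairs for p in (a, b)
                )
                leaf_cs = _leaf_constraints(leaf, cs)
                best, used = optimize(
                    leaf.structure,
                    Candidate(seq=leaf.sequence),
                    pools,
                    leaf_cs,
                    engine,
                    rng,
                    max_iter=max_iter,
                    variant_cap=variant_cap,
                    ignore_positions=ignore,
                )
                leaf.sequence = best.seq
                total_iters += used
            _, start_seq = reassemble(tree)
            start = Candidate(seq=start_seq)

    best, used = optimize(
        target, start, pools, cs, engine, rng,
        max_iter=max_iter, variant_cap=variant_cap,
    )
    total_iters += used

    mfe = best.mfe_structure
    distance = hamming_distance(mfe, target)
    energy = best.energy_on_target
    seq_ok = sequence_satisfies(best.seq, cs)
    energy_ok = energy_in_range(energy, cs)
    return DesignResult(
        seq=best.seq,
        distance=distance,
        energy_on_target=energy,
        iterations_used=total_iters,
        sequence_constraints_met=seq_ok,
        energy_constraint_met=energy_ok,
        success=(distance == 0 and seq_ok and energy_ok),
        seed=seed,
        engine=engine.name,
        mfe_structure=mfe.dotbracket,
    )
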