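"""Folding-engine contract plus two implementations.

``ViennaEngine`` adapts the ViennaRNA scripting bindings (Turner
nearest-neighbor parameters at 37 °C, the model under which all energies in
this package are interpreted).  ``ToyEngine`` is a deterministic
maximum-pairing folder — Nussinov-style dynamic programming scoring −1 per
canonical pair with a minimum hairpin of 3 — so the unit-test suite never
needs the thermodynamic engine.  Energies from the two engines live on
different scales and must never be mixed.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from functools import lru_cache

from .constraints import CANONICAL_PAIRS, normalize_sequence
from .struct_model import MIN_HAIRPIN, SecondaryStructure, parse_dotbracket

_VALID = set("ACGU")


def _check_seq(seq: str) -> str:
    seq = normalize_sequence(seq)
    bad = set(seq) - _VALID
    if not seq or bad:
        raise ValueError(f"invalid RNA sequence (offending characters: {sorted(bad)})")
    return seq


class FoldEngine(ABC):
    """Contract: ``fold`` returns the MFE structure and energy of a sequence;
    ``energy_of`` evaluates a sequence on a fixed structure.  Both are
    deterministic for a fixed engine version, and
    ``energy_of(seq, fold(seq).structure) == fold(seq).energy`` to 1e-2."""

    #: engine name/version, logged into every result for provenance
    name: str = "abstract"

    @abstractmethod
    def fold(self, seq: str) -> tuple[SecondaryStructure, float]: ...

    @abstractmethod
    def energy_of(self, seq: str, s: SecondaryStructure) -> float: ...


class ViennaEngine(FoldEngine):
    """Adapter to the ViennaRNA package's ``fold`` / ``energy_of_structure``."""

    def __init__(self, temperature: float = 37.0):
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "the ViennaRNA scripting bindings (module 'RNA') are required "
                "for the thermodynamic engine; use ToyEngine otherwise"
            ) from exc
        self._RNA = RNA
        self.temperature = temperature
        version = getattr(RNA, "__version__", "?")
        self.name = f"ViennaRNA-{version}@{temperature:g}C"

    def _md(self):
        md = self._RNA.md()
        md.temperature = self.temperature
        return md

    def fold(self, seq: str) -> tuple[SecondaryStructure, float]:
        seq = _check_seq(seq)
        fc = self._RNA.fold_compound(seq, self._md())
        db, mfe = fc.mfe()
        return parse_dotbracket(db, min_hairpin=0), float(mfe)

    def energy_of(self, seq: str, s: SecondaryStructure) -> float:
        seq = _check_seq(seq)
        if len(seq) != s.length:
            raise ValueError(f"length mismatch: {len(seq)} vs {s.length}")
        fc = self._RNA.fold_compound(seq, self._md())
        return float(fc.eval_structure(s.dotbracket))


class ToyEngine(FoldEngine):
    """Hermetic maximum-pairing folder: −1 per canonical pair, hairpin ≥ 3.

    Ties are broken toward 5'-most pairing: scanning left to right, a
    position pairs with the smallest admissible partner that still achieves
    the optimal pair count.
    """

    name = "toy-maxpair-1.0"

    @staticmethod
    def _can_pair(a: str, b: str) -> bool:
        return a + b in CANONICAL_PAIRS

    def fold(self, seq: str) -> tuple[SecondaryStructure, float]:
        seq = _check_seq(seq)
        n = len(seq)
        # N[i][j]: max pairs on seq[i..j], 0-based inclusive
        N = [[0] * n for _ in range(n)]
        for span in range(MIN_HAIRPIN + 1, n):
            for i in range(n - span):
                j = i + span
                best = N[i + 1][j]  # i unpaired
                for k in range(i + MIN_HAIRPIN + 1, j + 1):
                    if self._can_pair(seq[i], seq[k]):
                        inner = N[i + 1][k - 1] if k - 1 > i else 0
                        rest = N[k + 1][j] if k + 1 <= j else 0
                        best = max(best, 1 + inner + rest)
                N[i][j] = best
        db = ["."] * n
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j or N[i][j] == 0:
                continue
            paired = False
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                if self._can_pair(seq[i], seq[k]):
                    inner = N[i + 1][k - 1] if k - 1 > i else 0
                    rest = N[k + 1][j] if k + 1 <= j else 0
                    if 1 + inner + rest == N[i][j]:
                        db[i], db[k] = "(", ")"
                        stack.append((i + 1, k - 1))
                        stack.append((k + 1, j))
                        paired = True
                        break
            if not paired:
                stack.append((i + 1, j))
        structure = parse_dotbracket("".join(db), min_hairpin=0)
        return structure, -float(N[0][n - 1])

    def energy_of(self, seq: str, s: SecondaryStructure) -> float:
        seq = _check_seq(seq)
        if len(seq) != s.length:
            raise ValueError(f"length mismatch: {len(seq)} vs {s.length}")
        score = sum(
            1 for i, j in s.pair_list() if self._can_pair(seq[i - 1], seq[j - 1])
        )
        return -float(score)


@lru_cache(maxsize=2)
def get_engine(name: str = "vienna") -> FoldEngine:
    """Engine registry for the CLI: ``vienna`` (default) or ``toy``."""
    if name == "vienna":
        return ViennaEngine()
    if name == "toy":
        return ToyEngine()
    raise ValueError(f"unknown engine {name!r} (choose 'vienna' or 'toy')")
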