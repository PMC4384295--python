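"""Readers and writers for the tool's standard formats.

Dot-bracket structure files (structure line plus optional IUPAC mask line),
FASTA sequence files (via Biopython), the 6-column CT connectivity table,
and tab-separated result tables.  Sequences read from disk are normalised
to uppercase RNA (T→U).
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constraints import normalize_mask, normalize_sequence
from .struct_model import SecondaryStructure, parse_dotbracket


def read_structure_file(path) -> tuple[SecondaryStructure, str | None]:
    """First non-comment line: dot-bracket; optional second line: IUPAC mask."""
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith(("#", ">", ";"))
    ]
    if not lines:
        raise ValueError(f"{path}: no structure line found")
    structure = parse_dotbracket(lines[0])
    mask = None
    if len(lines) > 1:
        mask = normalize_mask(lines[1])
        if len(mask) != structure.length:
            raise ValueError(
                f"{path}: mask length {len(mask)} does not match "
                f"structure length {structure.length}"
            )
    return structure, mask


def read_fasta(path) -> list[tuple[str, str]]:
    """``(id, sequence)`` records, normalised to uppercase RNA."""
    records = [
        (rec.id, normalize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: list[tuple[str, str]], path, *, header: str = "") -> None:
    """Write records; ``header`` (provenance) goes into each description."""
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description=header) for name, seq in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def write_ct(seq: str, structure: SecondaryStructure, path, *, title: str = "") -> None:
    """Standard 6-column CT: index, base, index−1, index+1 (0 at the ends),
    pairing partner (0 if unpaired), index."""
    n = len(seq)
    if n != structure.length:
        raise ValueError(f"length mismatch: {n} vs {structure.length}")
    with open(path, "w") as fh:
        fh.write(f"{n} {title}\n")
        for i, base in enumerate(seq, start=1):
            partner = structure.partner(i) or 0
            prev_i = i - 1
            next_i = i + 1 if i < n else 0
            fh.write(f"{i} {base} {prev_i} {next_i} {partner} {i}\n")


def read_ct(path) -> tuple[str, SecondaryStructure]:
    """Inverse of :func:`write_ct`."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split()
    n = int(header[0])
    bases = [""] * n
    db = ["."] * n
    for ln in lines[1 : n + 1]:
        f = ln.split()
        i, base, partner = int(f[0]), f[1], int(f[4])
        bases[i - 1] = base
        if partner:
            db[i - 1] = "(" if i < partner else ")"
    return "".join(bases), parse_dotbracket("".join(db), min_hairpin=0)
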