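"""Shared nucleotide/protein sequence helpers."""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

IUPAC_NT: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: codons per amino acid (standard table), sorted for determinism
CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    CODONS_BY_AA.setdefault(_aa, [])
    CODONS_BY_AA[_aa].append(_codon)
CODONS_BY_AA = {aa: tuple(sorted(cs)) for aa, cs in CODONS_BY_AA.items()}


class IUPACError(ValueError):
    """A pattern contains a character outside the IUPAC nucleotide alphabet."""


def validate_iupac(pattern: str) -> None:
    bad = sorted(set(pattern) - set(IUPAC_NT))
    if bad:
        raise IUPACError(f"invalid IUPAC nucleotide character(s): {bad!r}")


def revcomp(seq: str) -> str:
    """Reverse complement; degenerate IUPAC codes are complemented too."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:  # pragma: no cover - defensive
        raise IUPACError(f"cannot complement {exc.args[0]!r}") from exc


def translate(nt: str) -> str:
    """Translate the forward frame, dropping any trailing partial codon."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


def six_frame_translations(nt: str) -> list[tuple[int, str]]:
    """All six reading frames as (frame, protein).

    Frames 0-2 are forward offsets, 3-5 the same offsets on the reverse
    complement. Stops are rendered as ``*``.
    """
    frames = []
    rc = revcomp(nt)
    for off in range(3):
        frames.append((off, translate(nt[off:])))
    for off in range(3):
        frames.append((3 + off, translate(rc[off:])))
    return frames
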