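"""Substrate-binding-pocket code extraction and substrate prediction.

The 10 pocket residues of an adenylation (A) domain are read out at fixed
coordinates (235, 236, 239, 278, 299, 301, 322, 330, 331, 517) expressed in
the numbering of a shipped anchor A-domain. Queries are mapped into that
frame by pairwise alignment, so insertions/deletions relative to the anchor
do not shift the coordinates.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from ._seq import AMINO_ACIDS

STACHELHAUS_POSITIONS: tuple[int, ...] = (235, 236, 239, 278, 299, 301, 322, 330, 331, 517)

#: index of the coordinate-299 slot in the sorted 10-tuple (the pocket
#: position known to vary most between otherwise-identical codes)
POS299_SLOT = STACHELHAUS_POSITIONS.index(299)

ANCHOR_ID = "anchorA_phe"

#: pocket code of the shipped anchor (a Phe-activating stand-in)
ANCHOR_CODE = "DAWTIAAICK"

_ANCHOR_LEN = 525
_ANCHOR_HEAD = "AYLMYTSG"   # encoded by the forward-primer site
_ANCHOR_TAIL = "YRTGDV"     # encoded by the reverse-primer site

#: (name, motif, 1-based anchor start); motifs are the primer-design cores
A3_MOTIF = ("A3", "MYTSG", 4)
A7_MOTIF = ("A7", "YRTGD", 520)
DEFAULT_MOTIFS = (A3_MOTIF, A7_MOTIF)


def _build_anchor() -> str:
    rng = random.Random(20210917)
    seq = [rng.choice(AMINO_ACIDS) for _ in range(_ANCHOR_LEN)]
    seq[: len(_ANCHOR_HEAD)] = _ANCHOR_HEAD
    seq[_ANCHOR_LEN - len(_ANCHOR_TAIL):] = _ANCHOR_TAIL
    for pos, res in zip(STACHELHAUS_POSITIONS, ANCHOR_CODE):
        seq[pos - 1] = res
    return "".join(seq)


ANCHOR_PROTEIN = _build_anchor()


@dataclass(frozen=True)
class CodePositionMap:
    """Pocket coordinates interpreted in an anchor sequence's numbering."""

    positions: tuple[int, ...] = STACHELHAUS_POSITIONS
    reference_id: str = ANCHOR_ID
    anchor_alignment: str = ANCHOR_PROTEIN

    def __post_init__(self) -> None:
        if len(self.positions) != 10:
            raise ValueError("exactly 10 pocket positions required")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")


DEFAULT_POSITION_MAP = CodePositionMap()


@dataclass
class SpecificityCode:
    residues: str
    source_id: str = ""
    coverage: int = 10

    def __post_init__(self) -> None:
        if len(self.residues) != 10:
            raise ValueError("specificity code must have length 10")


@dataclass
class SubstrateCall:
    substrate: str
    distance: int
    ties: list[str]
    paba_type: bool
    variable_pos_mismatch: bool


@dataclass
class ActivityCall:
    active: bool
    missing_motifs: list[str]


class NotAnADomainError(ValueError):
    """Query does not align to the anchor well enough to be an A-domain."""


class UncallableCodeError(ValueError):
    """All pocket positions are gaps; no substrate call possible."""


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    # free end gaps: queries may be partial (e.g. A3-A7 amplicon region)
    aligner.end_gap_score = 0
    return aligner


_PROT_ALIGNER = _protein_aligner()


def align_to_anchor(
    query: str, anchor: str = ANCHOR_PROTEIN
) -> tuple[dict[int, int], float, int]:
    """Map 1-based anchor coordinates to 0-based query indices.

    Returns ``(coordinate_map, identity, aligned_columns)`` where identity
    is computed over columns in which both sequences have a residue.
    """
    aln = _PROT_ALIGNER.align(anchor, query)[0]
    coord: dict[int, int] = {}
    matches = 0
    columns = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            ai, qi = t0 + k, q0 + k
            coord[ai + 1] = qi
            columns += 1
            if anchor[ai] == query[qi]:
                matches += 1
    identity = matches / columns if columns else 0.0
    return coord, identity, columns


def extract_code(
    protein_seq: str,
    position_map: CodePositionMap = DEFAULT_POSITION_MAP,
    source_id: str = "",
    min_identity: float = 0.40,
    min_columns: int = 200,
) -> SpecificityCode:
    """Read the 10 pocket residues of ``protein_seq`` in the anchor frame.

    A position falling in a gap yields ``'-'`` and decrements coverage.
    Raises :class:`NotAnADomainError` below the identity/coverage floor.
    """
    coord, identity, columns = align_to_anchor(protein_seq, position_map.anchor_alignment)
    if identity < min_identity or columns < min_columns:
        raise NotAnADomainError(
            f"query aligns at {identity:.2f} identity over {columns} columns "
            f"(need >= {min_identity:.2f} over >= {min_columns})"
        )
    residues = []
    for pos in position_map.positions:
        qi = coord.get(pos)
        residues.append(protein_seq[qi] if qi is not None else "-")
    code = "".join(residues)
    return SpecificityCode(code, source_id=source_id, coverage=10 - code.count("-"))


def predict_substrate(code: SpecificityCode, table) -> SubstrateCall:
    """Nearest-neighbour substrate call by Hamming distance over the code.

    ``table`` entries need ``.code`` and ``.substrate`` attributes (the
    bundled reference panel qualifies). Gap positions in the query are
    excluded from the distance. All minimal-distance substrates are listed
    in ``ties`` (sorted); ``variable_pos_mismatch`` is true when every
    mismatch against the best entry sits in the coordinate-299 slot.
    """
    if not table:
        raise ValueError("reference table must be non-empty")
    covered = [i for i, c in enumerate(code.residues) if c != "-"]
    if not covered:
        raise UncallableCodeError("all pocket positions are gaps")
    scored = []
    for entry in table:
        if len(entry.code) != 10:
            raise ValueError(f"reference {entry.id!r} code not length 10")
        mism = [i for i in covered if code.residues[i] != entry.code[i]]
        scored.append((len(mism), entry.substrate, entry, mism))
    scored.sort(key=lambda t: (t[0], t[1], t[2].id))
    best_d = scored[0][0]
    ties = sorted({s for d, s, _, _ in scored if d == best_d})
    _, substrate, _, best_mism = scored[0]
    return SubstrateCall(
        substrate=substrate,
        distance=best_d,
        ties=ties,
        paba_type=code.residues[0] == "A",
        variable_pos_mismatch=bool(best_mism) and set(best_mism) <= {POS299_SLOT},
    )


def _motif_present(segment: str, motif: str) -> bool:
    m = len(motif)
    for off in range(len(segment) - m + 1):
        if all(mc in ("x", "X") or segment[off + i] == mc for i, mc in enumerate(motif)):
            return True
    return False


def call_activity(
    protein_seq: str,
    motif_set=DEFAULT_MOTIFS,
    window: int = 10,
    anchor: str = ANCHOR_PROTEIN,
) -> ActivityCall:
    """Check the A3/A7 core motifs at their anchor-frame windows.

    A domain is called active iff every motif matches within +-``window``
    columns of its expected anchor coordinate; ``x`` in a motif is a
    wildcard.
    """
    if not motif_set:
        raise ValueError("motif_set must be non-empty")
    coord, _, _ = align_to_anchor(protein_seq, anchor)
    missing: list[str] = []
    for name, motif, start in motif_set:
        lo_a = max(1, start - window)
        hi_a = min(len(anchor), start + len(motif) - 1 + window)
        mapped = [coord[p] for p in range(lo_a, hi_a + 1) if p in coord]
        if not mapped:
            missing.append(name)
            continue
        segment = protein_seq[min(mapped): max(mapped) + 1]
        if not _motif_present(segment, motif):
            missing.append(name)
    return ActivityCall(active=not missing, missing_motifs=missing)
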