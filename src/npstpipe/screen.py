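"""Two-step PABA-specific NPST screen.

Step 1 compares each NPST (translated, best frame) against characterized
PABA-specific A-domain proteins by Smith-Waterman alignment and keeps
primary hits below an E-value threshold. Step 2 requires an exact match of
a degenerate nucleotide signature unique to PABA-specific A-domains.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from ._seq import IUPAC_NT, revcomp, six_frame_translations, validate_iupac
from .amplicon import NPST, match_degenerate

#: printed degenerate signature: three fixed blocks at exact spacings
DEFAULT_SIGNATURE = "ARAARA (N11) TTYGCNRT (N7) AARGAR"

_SPACER_RE = re.compile(r"^\(N(\d+)\)$")


@dataclass(frozen=True)
class SignaturePattern:
    """Alternating fixed IUPAC blocks and exact-length spacers."""

    blocks: tuple = ()  # str (fixed block) | int (spacer length)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("empty signature pattern")
        if not isinstance(self.blocks[0], str) or not isinstance(self.blocks[-1], str):
            raise ValueError("signature must start and end with a fixed block")
        for b in self.blocks:
            if isinstance(b, int):
                if b <= 0:
                    raise ValueError("spacer lengths must be > 0")
            else:
                validate_iupac(b)

    @property
    def fixed_blocks(self) -> list[str]:
        return [b for b in self.blocks if isinstance(b, str)]

    @property
    def spacers(self) -> list[int]:
        return [b for b in self.blocks if isinstance(b, int)]

    @property
    def span(self) -> int:
        return sum(len(b) if isinstance(b, str) else b for b in self.blocks)

    def as_iupac(self) -> str:
        """Flatten to a single IUPAC string (spacers become N runs)."""
        return "".join(b if isinstance(b, str) else "N" * b for b in self.blocks)


def parse_signature(pattern_string: str) -> SignaturePattern:
    """Parse the ``"BLOCK (Nk) BLOCK ..."`` dialect."""
    tokens = pattern_string.split()
    if not tokens:
        raise ValueError("empty signature pattern string")
    blocks: list = []
    for tok in tokens:
        m = _SPACER_RE.match(tok)
        blocks.append(int(m.group(1)) if m else tok.upper())
    return SignaturePattern(tuple(blocks))


DEFAULT_SIGNATURE_PATTERN = parse_signature(DEFAULT_SIGNATURE)


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join("[" + "".join(sorted(IUPAC_NT[c])) + "]" for c in pattern))


def signature_filter(
    npst_nt: str,
    pattern: SignaturePattern = DEFAULT_SIGNATURE_PATTERN,
    max_mismatch: int = 0,
) -> tuple[bool, int | None]:
    """Presence/absence scan for the signature on either strand.

    Fixed blocks must match with at most ``max_mismatch`` mismatches in
    total (default 0; spacer positions always match). Returns
    ``(matched, offset)`` with the offset of the leftmost site in 0-based
    forward-strand coordinates.
    """
    flat = pattern.as_iupac()
    seq = npst_nt.upper()
    if max_mismatch == 0:
        offsets = []
        for strand_pat in (flat, revcomp(flat)):
            rx = _iupac_regex(strand_pat)
            m = rx.search(seq)
            if m:
                offsets.append(m.start())
        return (True, min(offsets)) if offsets else (False, None)
    hits = match_degenerate(seq, flat, max_mismatch)
    if not hits:
        return False, None
    return True, min(off for off, _, _ in hits)


@dataclass(frozen=True)
class ScreenConfig:
    evalue_threshold: float = 1e-25
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    #: Karlin-Altschul gapped parameters for BLOSUM62 11/1
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    signature: SignaturePattern = DEFAULT_SIGNATURE_PATTERN
    signature_mismatch: int = 0

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")


@dataclass
class ScreenHit:
    npst_id: str
    best_ref: str | None
    bitscore: float
    evalue: float
    passed_evalue: bool
    passed_signature: bool
    signature_offset: int | None = None
    note: str = ""

    @property
    def final_call(self) -> bool:
        return self.passed_evalue and self.passed_signature


class UntranslatableError(ValueError):
    """No reading frame yields a usable protein."""


def _local_aligner(config: ScreenConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(config.matrix)
    aligner.open_gap_score = -config.gap_open - config.gap_extend
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def karlin_altschul_evalue(score: float, m: int, n: int, config: ScreenConfig) -> float:
    """E = K * m * n * exp(-lambda * S), underflowing to 0.0."""
    log_e = math.log(config.ka_k) + math.log(max(m, 1)) + math.log(max(n, 1))
    log_e -= config.ka_lambda * score
    try:
        return math.exp(log_e)
    except OverflowError:
        return math.inf


def candidate_frames(nt: str) -> tuple[list[tuple[int, str]], bool]:
    """Translations worth aligning: stop-free frames, else all frames.

    Returns ``(frames, stop_free)``. When no frame is free of internal
    stops, all six stop-bearing translations are returned and alignment
    relies on the substitution matrix penalizing ``*`` (BLASTX-like
    behaviour); ``stop_free`` is False in that case.
    """
    frames = [(f, p) for f, p in six_frame_translations(nt) if p]
    if not frames:
        raise UntranslatableError("sequence too short to translate")
    clean = [(f, p) for f, p in frames if "*" not in p.rstrip("*")]
    if clean:
        return clean, True
    return frames, False


def best_hit(npst: NPST, refs, config: ScreenConfig = ScreenConfig()) -> ScreenHit:
    """Max-bitscore local-alignment hit of the translated centroid.

    ``refs`` must be non-empty reference A-domains (``.id``,
    ``.protein_seq``). E-values use query length m and the summed reference
    lengths n.
    """
    refs = list(refs)
    if not refs:
        raise ValueError("reference list must be non-empty")
    frames, stop_free = candidate_frames(npst.centroid)
    aligner = _local_aligner(config)
    n_total = sum(len(r.protein_seq) for r in refs)
    best: tuple[float, int, str, int] | None = None  # (score, frame, ref_id, m)
    for frame, prot in frames:
        for ref in refs:
            score = aligner.score(prot, ref.protein_seq)
            cand = (score, frame, ref.id, len(prot))
            if best is None or score > best[0] or (score == best[0] and frame < best[1]):
                best = cand
    score, _, ref_id, m = best
    evalue = karlin_altschul_evalue(score, m, n_total, config)
    bitscore = (config.ka_lambda * score - math.log(config.ka_k)) / math.log(2.0)
    return ScreenHit(
        npst_id=npst.npst_id,
        best_ref=ref_id,
        bitscore=bitscore,
        evalue=evalue,
        passed_evalue=evalue < config.evalue_threshold,
        passed_signature=False,
        note="" if stop_free else "no stop-free frame; stop-penalized alignment used",
    )


def two_step_screen(
    npsts: list[NPST], refs, config: ScreenConfig = ScreenConfig()
) -> list[ScreenHit]:
    """E-value filter then signature filter; every NPST gets a record.

    The signature is evaluated only for primary (E-value passing) hits.
    Output is ordered by npst_id.
    """
    hits: list[ScreenHit] = []
    for npst in sorted(npsts, key=lambda n: n.npst_id):
        try:
            hit = best_hit(npst, refs, config)
        except UntranslatableError as exc:
            hits.append(
                ScreenHit(
                    npst_id=npst.npst_id,
                    best_ref=None,
                    bitscore=0.0,
                    evalue=math.inf,
                    passed_evalue=False,
                    passed_signature=False,
                    note=f"untranslatable: {exc}",
                )
            )
            continue
        if hit.passed_evalue:
            ok, offset = signature_filter(
                npst.centroid, config.signature, config.signature_mismatch
            )
            hit.passed_signature = ok
            hit.signature_offset = offset
        else:
            hit.note = (hit.note + "; " if hit.note else "") + "signature not evaluated"
        hits.append(hit)
    return hits


def write_screen_tsv(hits: list[ScreenHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "npst_id\tbest_ref\tbitscore\tevalue\tpassed_evalue\t"
            "passed_signature\tfinal_call\tsignature_offset\tnote\n"
        )
        for h in hits:
            fh.write(
                f"{h.npst_id}\t{h.best_ref or '.'}\t{h.bitscore:.2f}\t{h.evalue:.3e}\t"
                f"{h.passed_evalue}\t{h.passed_signature}\t{h.final_call}\t"
                f"{h.signature_offset if h.signature_offset is not None else '.'}\t"
                f"{h.note}\n"
            )
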