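"""Degenerate-primer in-silico PCR, de-barcoding and NPST clustering.

Reads carrying pool barcodes are assigned to their pool, stripped of the
barcode and the terminal primer-matching segments, and greedily clustered
at a fixed identity threshold into natural product sequence tags (NPSTs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner

from ._seq import IUPAC_NT, revcomp, validate_iupac


@dataclass(frozen=True)
class DegeneratePrimer:
    name: str
    iupac_seq: str

    def __post_init__(self) -> None:
        validate_iupac(self.iupac_seq)
        if len(self.iupac_seq) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 nt")

    def __len__(self) -> int:
        return len(self.iupac_seq)


#: forward primer recognizing the A3 core region
AD_FW = DegeneratePrimer("AD-FW", "GCSTACSYSATSTACACSTCSGG")
#: reverse primer recognizing the A7 core region
AD_RV = DegeneratePrimer("AD-RV", "SASGTCVCCSGTSCGGTA")


@dataclass
class AmpliconRead:
    read_id: str
    pool_id: str
    seq: str
    trimmed: bool = False


@dataclass
class NPST:
    """Cluster centroid (natural product sequence tag) with membership."""

    npst_id: str
    centroid: str
    members: list[str]
    pools: set[str]


@dataclass(frozen=True)
class ClusterConfig:
    identity_threshold: float = 0.95
    order_rule: str = "length_then_lex"

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.order_rule != "length_then_lex":
            raise ValueError(f"unknown order_rule {self.order_rule!r}")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _mismatch_profile(seq_arr: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatch count of ``pattern`` at every offset of the encoded sequence.

    A position matches iff the sequence base is inside the IUPAC class of
    the pattern character; anything else (including non-ACGT sequence
    characters) counts as a mismatch.
    """
    plen = len(pattern)
    n_off = len(seq_arr) - plen + 1
    if n_off <= 0:
        return np.empty(0, dtype=np.int32)
    mism = np.zeros(n_off, dtype=np.int32)
    for k, pc in enumerate(pattern):
        allowed = np.array([ord(b) for b in sorted(IUPAC_NT[pc])], dtype=np.uint8)
        window = seq_arr[k:k + n_off]
        ok = np.isin(window, allowed)
        mism += ~ok
    return mism


def match_degenerate(
    seq: str, pattern: str, max_mismatch: int = 0
) -> list[tuple[int, str, int]]:
    """All matches of an IUPAC pattern on both strands of ``seq``.

    Returns ``(offset, strand, mismatches)`` triples with 0-based offsets on
    the forward strand (leftmost base of the site); ``strand`` is ``"+"`` or
    ``"-"``. A minus-strand hit means the pattern matches the reverse strand,
    i.e. the reverse complement of the pattern occurs on the forward strand.
    """
    validate_iupac(pattern)
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    arr = _encode(seq)
    hits: list[tuple[int, str, int]] = []
    for strand, pat in (("+", pattern), ("-", revcomp(pattern))):
        mism = _mismatch_profile(arr, pat)
        for off in np.nonzero(mism <= max_mismatch)[0]:
            hits.append((int(off), strand, int(mism[off])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def insilico_pcr(
    contig: str,
    fw: DegeneratePrimer = AD_FW,
    rv: DegeneratePrimer = AD_RV,
    max_mismatch: int = 0,
    min_len: int = 100,
    max_len: int = 10000,
) -> list[str]:
    """Amplicons delimited by a forward ``fw`` site and a downstream
    reverse-complement ``rv`` site, inclusive of both primer sites.

    Both orientations of the contig are searched; products are reported
    5'->3' relative to the forward primer. Overlapping products are all
    reported.
    """
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    products: list[str] = []
    rc_rv = revcomp(rv.iupac_seq)
    for strand_seq in (contig, revcomp(contig)):
        arr = _encode(strand_seq)
        fw_offs = np.nonzero(_mismatch_profile(arr, fw.iupac_seq) <= max_mismatch)[0]
        rv_offs = np.nonzero(_mismatch_profile(arr, rc_rv) <= max_mismatch)[0]
        for i in fw_offs:
            for j in rv_offs:
                if j < i + len(fw):
                    continue
                end = int(j) + len(rv)
                length = end - int(i)
                if min_len <= length <= max_len:
                    products.append(strand_seq[int(i):end])
    return products


class BarcodeConfigError(ValueError):
    """Barcode map is unusable (duplicates)."""


def debarcode_and_trim(
    reads,
    barcode_map: dict[str, str],
    fw: DegeneratePrimer = AD_FW,
    rv: DegeneratePrimer = AD_RV,
    max_mismatch: int = 2,
) -> tuple[list[AmpliconRead], list[tuple[str, str, str]]]:
    """Assign reads to pools by exact barcode prefix and trim primer termini.

    ``reads`` is an iterable of ``(read_id, sequence)`` pairs (SeqRecord-like
    objects with ``.id``/``.seq`` also work). Returns ``(assigned,
    unassigned)`` where unassigned entries are ``(read_id, seq, reason)``;
    nothing is silently dropped.
    """
    barcodes = list(barcode_map.values())
    if len(set(barcodes)) != len(barcodes):
        raise BarcodeConfigError("duplicate barcodes in barcode map")
    by_barcode = {bc: pool for pool, bc in barcode_map.items()}
    rc_rv = revcomp(rv.iupac_seq)

    assigned: list[AmpliconRead] = []
    unassigned: list[tuple[str, str, str]] = []
    for rec in reads:
        if hasattr(rec, "id"):
            read_id, seq = rec.id, str(rec.seq)
        else:
            read_id, seq = rec
        matches = [(bc, pool) for bc, pool in by_barcode.items() if seq.startswith(bc)]
        if not matches:
            unassigned.append((read_id, seq, "no matching barcode prefix"))
            continue
        if len(matches) > 1:
            unassigned.append((read_id, seq, "ambiguous barcode prefix"))
            continue
        bc, pool = matches[0]
        body = seq[len(bc):]
        trimmed_fw = trimmed_rv = False
        arr = _encode(body)
        prof = _mismatch_profile(arr, fw.iupac_seq)
        if len(prof) and prof[0] <= max_mismatch:
            body = body[len(fw):]
            trimmed_fw = True
        arr = _encode(body)
        prof = _mismatch_profile(arr, rc_rv)
        if len(prof) and prof[-1] <= max_mismatch:
            body = body[: len(body) - len(rv)]
            trimmed_rv = True
        assigned.append(
            AmpliconRead(read_id, pool, body, trimmed=trimmed_fw and trimmed_rv)
        )
    return assigned, unassigned


def _identity_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _identity_aligner()


def alignment_identity(a: str, b: str) -> float:
    """Matches over alignment columns of a global alignment.

    Scoring is fixed at match +1 / mismatch -1 / gap -2 (linear).
    """
    if a == b:
        return 1.0
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns


def cluster_npst(
    reads: list[AmpliconRead], config: ClusterConfig | None = None
) -> list[NPST]:
    """Greedy centroid clustering of amplicon reads into NPSTs.

    Reads are processed sorted by (length desc, sequence lex asc); each read
    joins the first centroid (in founding order) with global-alignment
    identity >= threshold, otherwise founds a new centroid.
    """
    if not reads:
        raise ValueError("cluster_npst requires at least one read")
    config = config or ClusterConfig()
    ordered = sorted(reads, key=lambda r: (-len(r.seq), r.seq, r.read_id))
    clusters: list[NPST] = []
    for read in ordered:
        placed = False
        for cl in clusters:
            if alignment_identity(read.seq, cl.centroid) >= config.identity_threshold:
                cl.members.append(read.read_id)
                cl.pools.add(read.pool_id)
                placed = True
                break
        if not placed:
            clusters.append(
                NPST(
                    npst_id=f"npst{len(clusters) + 1:04d}",
                    centroid=read.seq,
                    members=[read.read_id],
                    pools={read.pool_id},
                )
            )
    return clusters
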