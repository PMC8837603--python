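"""Seeded synthetic fixtures: reference panels, pooled libraries, reads.

Everything downstream of wet-lab work is exercised on data produced here:
characterized A-domain reference panels (protein + in-frame nucleotide
sequence + pocket code), pooled barcoded clone libraries with planted
amplicon templates, substitution-error reads, and the transcribed
assembly-line architecture of the worked decapeptide example.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from ._seq import AMINO_ACIDS, CODONS_BY_AA, IUPAC_NT, revcomp, translate
from .adomain import ANCHOR_PROTEIN, STACHELHAUS_POSITIONS
from .screen import DEFAULT_SIGNATURE_PATTERN, SignaturePattern, signature_filter
from .structure import (
    ModuleAnnotation,
    ModuleArchitecture,
    ProteinAnnotation,
)

#: documented library density; tests use far smaller pools
DEFAULT_CLONES_PER_POOL = 25000
#: documented cosmid insert scale; tests pass a smaller value
DEFAULT_INSERT_LEN = 40000

#: fixed concrete expansion of the forward primer (23 nt) + 1 pad base so
#: the head spans 8 full codons; encodes AYLMYTSG
FW_EXPANSION = "GCGTACCTGATGTACACGTCGGG"
FW_PAD = "C"
#: fixed concrete expansion of the reverse primer as it anneals; its
#: reverse complement terminates every template and encodes YRTGDV
RV_EXPANSION = "CACGTCGCCGGTCCGGTA"
RC_RV_EXPANSION = revcomp(RV_EXPANSION)

#: in-frame nucleotide offset where the degenerate signature is planted
SIGNATURE_NT_OFFSET = 1200

_HEAD_RES = 8
_TAIL_RES = 6
_ANCHOR_LEN = len(ANCHOR_PROTEIN)

#: synthetic stand-in pocket codes; alpha-amino substrates carry Asp in
#: slot 1, the aryl (PABA-family) substrates carry Ala
SUBSTRATE_CODES: dict[str, str] = {
    "Ala": "DLFNNALTYK",
    "Ser": "DVWHFSLVDK",
    "Cys": "DLYNLSLIWK",
    "Asn": "DLTKLGEVGK",
    "Gly": "DILQLGLIWK",
    "Val": "DAFWIGGTFK",
    "Thr": "DFWNIGMVHK",
    "Leu": "DAWFLGNVVK",
    "Phe": "DAWTIAAICK",
    "PABA": "AWFVIGMVHK",
    "AHIBA": "AWFVIGMIHK",
}

_AA_SUBSTRATE_CYCLE = ("Ala", "Ser", "Cys", "Asn", "Gly", "Val", "Thr", "Leu")

_CODE_IDX = {p - 1 for p in STACHELHAUS_POSITIONS}
_MUTABLE_IDX = tuple(
    i for i in range(_HEAD_RES, _ANCHOR_LEN - _TAIL_RES) if i not in _CODE_IDX
)


@dataclass
class ReferenceADomain:
    id: str
    substrate: str
    protein_seq: str
    nt_seq: str
    code: str
    is_paba_family: bool

    def __post_init__(self) -> None:
        if len(self.code) != 10:
            raise ValueError("specificity code must be 10 characters")
        if self.is_paba_family and self.code[0] != "A":
            raise ValueError("PABA-family codes must carry Ala in slot 1")


@dataclass
class PoolSpec:
    pool_id: str
    barcode: str
    contigs: list
    insert_len: int


@dataclass
class LibraryFixture:
    pools: list
    truth: dict  # plant/read id -> (reference_id, pool_id)
    seed: int
    templates: dict = field(default_factory=dict)  # id -> barcode-prefixed template

    def barcode_map(self) -> dict:
        return {p.pool_id: p.barcode for p in self.pools}


def _mutate_protein(seq: list, rate: float, rng: random.Random) -> None:
    for i in _MUTABLE_IDX:
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(seq[i], "")
            seq[i] = rng.choice(choices)


def _sample_signature(pattern: SignaturePattern, rng: random.Random) -> str:
    out = []
    for block in pattern.blocks:
        if isinstance(block, int):
            out.extend(rng.choice("ACGT") for _ in range(block))
        else:
            out.extend(rng.choice(sorted(IUPAC_NT[c])) for c in block)
    return "".join(out)


def _protein_to_nt(protein: str, rng: random.Random) -> str:
    """In-frame nucleotide sequence with the fixed primer-site head/tail."""
    middle = protein[_HEAD_RES:_ANCHOR_LEN - _TAIL_RES]
    codons = [rng.choice(CODONS_BY_AA[aa]) for aa in middle]
    return FW_EXPANSION + FW_PAD + "".join(codons) + RC_RV_EXPANSION


def _plant_signature(nt: str, rng: random.Random) -> str:
    """Overwrite an in-frame window with a concrete signature expansion.

    Resamples until the affected codons stay stop-free.
    """
    span = DEFAULT_SIGNATURE_PATTERN.span
    for _ in range(1000):
        sig = _sample_signature(DEFAULT_SIGNATURE_PATTERN, rng)
        cand = nt[:SIGNATURE_NT_OFFSET] + sig + nt[SIGNATURE_NT_OFFSET + span:]
        lo = SIGNATURE_NT_OFFSET - SIGNATURE_NT_OFFSET % 3
        hi = SIGNATURE_NT_OFFSET + span
        hi += (3 - hi % 3) % 3
        if "*" not in translate(cand[lo:hi]):
            return cand
    raise RuntimeError("could not plant a stop-free signature expansion")


def generate_reference_panel(
    n_paba: int,
    n_other: int,
    seed: int,
    family_divergence: float = 0.15,
    ref_divergence: float = 0.04,
) -> list[ReferenceADomain]:
    """Characterized A-domain panel with ``n_paba`` PABA-family entries.

    All entries descend from the shipped anchor through a panel-level
    "family" consensus (so distinct seeds give phylogenetically separable
    families) plus per-reference substitutions. PABA entries carry a
    concrete expansion of the degenerate signature in their nucleotide
    sequence; the other entries are guaranteed not to, on either strand.
    """
    if n_paba < 0 or n_other < 0:
        raise ValueError("reference counts must be non-negative")
    rng = random.Random(seed)
    consensus = list(ANCHOR_PROTEIN)
    _mutate_protein(consensus, family_divergence, rng)

    specs = [(f"paba{i + 1:02d}", "PABA") for i in range(n_paba)]
    specs += [
        (f"aa{i + 1:02d}", _AA_SUBSTRATE_CYCLE[i % len(_AA_SUBSTRATE_CYCLE)])
        for i in range(n_other)
    ]
    panel: list[ReferenceADomain] = []
    for ref_id, substrate in specs:
        code = SUBSTRATE_CODES[substrate]
        protein = list(consensus)
        _mutate_protein(protein, ref_divergence, rng)
        for pos, res in zip(STACHELHAUS_POSITIONS, code):
            protein[pos - 1] = res
        is_paba = substrate in ("PABA", "AHIBA")
        for _ in range(100):
            nt = _protein_to_nt("".join(protein), rng)
            if is_paba:
                nt = _plant_signature(nt, rng)
                break
            if not signature_filter(nt)[0]:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not avoid the signature in a background entry")
        final_protein = translate(nt)
        panel.append(
            ReferenceADomain(
                id=ref_id,
                substrate=substrate,
                protein_seq=final_protein,
                nt_seq=nt,
                code=code,
                is_paba_family=is_paba,
            )
        )
    return panel


def _random_nt(length: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def plant_amplicons(
    panel: list,
    n_pools: int,
    clones_per_pool: int,
    planted: dict,
    seed: int,
    insert_len: int = DEFAULT_INSERT_LEN,
    barcode_len: int = 8,
) -> LibraryFixture:
    """Embed reference amplicon templates in random pooled contigs.

    ``planted`` maps pool ids to lists of panel reference ids. Each planted
    template (the reference nucleotide sequence, which starts with the
    forward primer site and ends with the reverse-complement reverse site)
    is spliced into a random background contig of its pool. The truth table
    maps every plant id to its (reference, pool).
    """
    by_id = {ref.id: ref for ref in panel}
    for pool_id, ref_ids in planted.items():
        for rid in ref_ids:
            if rid not in by_id:
                raise LookupError(f"unknown reference id {rid!r} planted in {pool_id}")
    if len(planted) > n_pools:
        raise ValueError("more planted pools than n_pools")

    rng = random.Random(seed)
    pool_ids = sorted(planted)
    k = 1
    while len(pool_ids) < n_pools:
        cand = f"pool{k:02d}"
        if cand not in planted:
            pool_ids.append(cand)
        k += 1

    barcodes: set[str] = set()
    pools: list[PoolSpec] = []
    truth: dict = {}
    templates: dict = {}
    for pool_id in pool_ids:
        while True:
            bc = _random_nt(barcode_len, rng)
            if bc not in barcodes:
                barcodes.add(bc)
                break
        contigs = [_random_nt(insert_len, rng) for _ in range(clones_per_pool)]
        for k_ref, rid in enumerate(planted.get(pool_id, [])):
            ref = by_id[rid]
            ci = rng.randrange(len(contigs))
            pos = rng.randrange(len(contigs[ci]) + 1)
            contigs[ci] = contigs[ci][:pos] + ref.nt_seq + contigs[ci][pos:]
            plant_id = f"{pool_id}:{rid}:{k_ref + 1}"
            truth[plant_id] = (rid, pool_id)
            templates[plant_id] = bc + ref.nt_seq
        pools.append(PoolSpec(pool_id=pool_id, barcode=bc, contigs=contigs, insert_len=insert_len))
    return LibraryFixture(pools=pools, truth=truth, seed=seed, templates=templates)


def simulate_reads(
    fixture: LibraryFixture,
    error_rate: float,
    seed: int,
    reads_per_template: int = 1,
) -> dict:
    """Substitution-only error reads per pool, barcode prefix error-free.

    Returns ``{pool_id: [(read_id, seq), ...]}``; read ids extend the
    fixture plant ids (``<plant_id>/r<j>``), preserving truth linkage.
    """
    if not 0.0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = random.Random(seed)
    bc_len = {p.pool_id: len(p.barcode) for p in fixture.pools}
    reads: dict = {p.pool_id: [] for p in fixture.pools}
    for plant_id in sorted(fixture.templates):
        _, pool_id = fixture.truth[plant_id]
        template = fixture.templates[plant_id]
        protect = bc_len[pool_id]
        for j in range(reads_per_template):
            seq = list(template)
            for i in range(protect, len(seq)):
                if rng.random() < error_rate:
                    seq[i] = rng.choice("ACGT".replace(seq[i], ""))
            reads[pool_id].append((f"{plant_id}/r{j + 1}", "".join(seq)))
    return reads


# ---------------------------------------------------------------------------
# plain-text writers

def reads_to_fasta(reads: dict) -> str:
    out = []
    for pool_id in sorted(reads):
        for read_id, seq in reads[pool_id]:
            out.append(f">{read_id} pool={pool_id}\n{seq}\n")
    return "".join(out)


def panel_to_fasta(panel: list, kind: str = "nt") -> str:
    out = []
    for ref in panel:
        seq = ref.nt_seq if kind == "nt" else ref.protein_seq
        out.append(
            f">{ref.id} substrate={ref.substrate} code={ref.code} "
            f"paba_family={int(ref.is_paba_family)}\n{seq}\n"
        )
    return "".join(out)


def truth_to_tsv(fixture: LibraryFixture) -> str:
    lines = ["read_id\treference_id\tpool_id\n"]
    for plant_id in sorted(fixture.truth):
        rid, pool_id = fixture.truth[plant_id]
        lines.append(f"{plant_id}\t{rid}\t{pool_id}\n")
    return "".join(lines)


def barcodes_to_tsv(fixture: LibraryFixture) -> str:
    lines = ["pool_id\tbarcode\n"]
    for p in sorted(fixture.pools, key=lambda p: p.pool_id):
        lines.append(f"{p.pool_id}\t{p.barcode}\n")
    return "".join(lines)


# ---------------------------------------------------------------------------
# the transcribed worked-example architecture

def lap_architecture_fixture() -> ModuleArchitecture:
    """Transcribed assembly line of the worked decapeptide example.

    Five NRPS proteins in gene order: LapB is a standalone trans-acting
    A-domain (Asn); LapM initiates (Cs starter), LapH terminates (TE).
    The per-protein module partition (3/3/2/2 over LapM/LapK/LapL/LapH) is
    a fixture choice; only the totals and the protein order are fixed by
    the source material.
    """
    mod = ModuleAnnotation
    return ModuleArchitecture(
        proteins=[
            ProteinAnnotation(
                "LapH",
                [
                    mod("AD9", ("C", "A", "T"), "AHIBA"),
                    mod("AD10", ("C", "A", "T", "TE"), "PABA"),
                ],
            ),
            ProteinAnnotation(
                "LapK",
                [
                    mod("AD4", ("C", "A", "T"), "PABA"),
                    mod("AD5", ("Cy", "A", "T"), "Cys"),
                    mod("AD6", ("Cy", "A", "T"), "Cys"),
                ],
            ),
            ProteinAnnotation(
                "LapL",
                [
                    mod("AD7", ("C", "A", "T"), "unknown", a_domain_active=False),
                    mod("AD8", ("C", "A", "T"), "PABA"),
                ],
            ),
            ProteinAnnotation(
                "LapM",
                [
                    mod("AD1", ("Cs", "A", "T"), "Ala"),
                    mod("AD2", ("C", "A", "T"), "Ser"),
                    mod("AD3", ("C", "A", "T"), "Ala"),
                ],
            ),
        ],
        tailoring_genes=[
            ("lapC", "other"),
            ("lapD", "hydroxylase"),
            ("lapF", "o_methyltransferase"),
            ("lapG", "isomethyl"),
            ("lapI", "fmn_oxidase"),
        ],
        standalone_adomains=[("LapB", "Asn")],
    )


def lap_adomain_proteins(seed: int = 11) -> dict:
    """Per-module A-domain protein sequences matching the fixture.

    Each sequence is an anchor variant carrying the module's substrate
    code; the inactive module's sequence has its A7 core motif destroyed.
    """
    arch = lap_architecture_fixture()
    rng = random.Random(seed)
    out: dict = {}
    substrates = {}
    for protein in arch.proteins:
        for module in protein.modules:
            substrates[module.module_id] = (module.substrate, module.a_domain_active)
    substrates["AD7"] = ("Asn", False)  # trans-complemented in the fixture
    for module_id in sorted(substrates, key=lambda m: int(m[2:])):
        substrate, active = substrates[module_id]
        protein = list(ANCHOR_PROTEIN)
        _mutate_protein(protein, 0.05, rng)
        for pos, res in zip(STACHELHAUS_POSITIONS, SUBSTRATE_CODES[substrate]):
            protein[pos - 1] = res
        if not active:
            # wreck the A7 core window
            for i in range(519, len(protein)):
                protein[i] = "G"
        out[module_id] = "".join(protein)
    return out
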