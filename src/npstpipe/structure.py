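"""Rule engine: annotated NRPS architecture -> predicted monomer product.

The engine orders proteins into an assembly line (condensation-starter
protein first, thioesterase protein last), resolves inactive modules via
trans-acting standalone A-domains, applies heterocyclization and aryl
tailoring rules, and emits an ordered monomer list with class counts and
an optional N-terminal lipid.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

DOMAIN_NAMES = {"Cs", "C", "Cy", "A", "T", "E", "TE", "Ox"}
TAILORING_TAGS = {"fmn_oxidase", "hydroxylase", "o_methyltransferase", "isomethyl", "other"}
PABA_FAMILY = {"PABA", "AHIBA"}

PROTEINOGENIC = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
}


class ArchitectureError(ValueError):
    """The annotated architecture violates assembly-line preconditions."""


@dataclass
class ModuleAnnotation:
    module_id: str
    domains: tuple
    substrate: str = "unknown"
    a_domain_active: bool = True

    def __post_init__(self) -> None:
        self.domains = tuple(self.domains)
        bad = set(self.domains) - DOMAIN_NAMES
        if bad:
            raise ArchitectureError(f"unknown domain(s) {sorted(bad)} in {self.module_id}")


@dataclass
class ProteinAnnotation:
    protein_id: str
    modules: list


@dataclass
class ModuleArchitecture:
    proteins: list
    tailoring_genes: list = field(default_factory=list)   # (gene_id, tag)
    standalone_adomains: list = field(default_factory=list)  # (protein_id, substrate)

    def __post_init__(self) -> None:
        for _, tag in self.tailoring_genes:
            if tag not in TAILORING_TAGS:
                raise ArchitectureError(f"unknown tailoring tag {tag!r}")

    def tailoring_tags(self) -> set:
        return {tag for _, tag in self.tailoring_genes}


@dataclass
class Monomer:
    base: str
    ring_state: str = "none"  # none | thiazoline | thiazole
    d_configured: bool = False

    @property
    def monomer_class(self) -> str:
        if self.ring_state != "none":
            return "heterocycle"
        if self.base in PABA_FAMILY:
            return "paba_family"
        return "proteinogenic"

    def label(self) -> str:
        if self.ring_state != "none":
            return f"{self.base}({self.ring_state})"
        return self.base


@dataclass
class LipidRule:
    kind: str = "beta-hydroxy fatty acid"
    chain_range: tuple = (10, 14)
    chosen_chain: int = 14
    stereo: str = "racemic"

    def __post_init__(self) -> None:
        lo, hi = self.chain_range
        if not lo <= self.chosen_chain <= hi:
            raise ValueError("chosen lipid chain outside the allowed range")


@dataclass
class PredictedStructure:
    monomers: list
    lipid: LipidRule | None
    counts: dict
    warnings: list
    log: list

    @property
    def n_residues(self) -> int:
        return len(self.monomers)

    def monomer_string(self) -> str:
        parts = [m.label() for m in self.monomers]
        if self.lipid is not None:
            parts.insert(0, f"C{self.lipid.chosen_chain}-bOH")
        return "—".join(parts)

    def to_json(self) -> str:
        payload = {
            "monomers": [
                {"base": m.base, "ring_state": m.ring_state, "class": m.monomer_class}
                for m in self.monomers
            ],
            "n_residues": self.n_residues,
            "counts": dict(sorted(self.counts.items())),
            "lipid": asdict(self.lipid) if self.lipid else None,
            "monomer_string": self.monomer_string(),
            "warnings": list(self.warnings),
            "log": list(self.log),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _has_domain(protein: ProteinAnnotation, domain: str) -> bool:
    return any(domain in m.domains for m in protein.modules)


def order_proteins(
    arch: ModuleArchitecture, order: list | None = None
) -> tuple[list, list]:
    """Order module-bearing proteins into an assembly line.

    The Cs-bearing protein leads and the TE-bearing protein terminates.
    Internal proteins follow an explicit ``order`` when given, otherwise
    input order (a logged heuristic). With an explicit full ``order`` the
    Cs/TE uniqueness requirement is relaxed to warnings.
    """
    log: list[str] = []
    bearing = [p for p in arch.proteins if p.modules]
    if not bearing:
        raise ArchitectureError("no module-bearing proteins")
    if order is not None:
        by_id = {p.protein_id: p for p in bearing}
        unknown = [pid for pid in order if pid not in by_id]
        if unknown or set(order) != set(by_id):
            raise ArchitectureError(f"explicit order does not cover proteins: {unknown}")
        log.append(f"explicit protein order: {','.join(order)}")
        return [by_id[pid] for pid in order], log

    cs = [p.protein_id for p in bearing if _has_domain(p, "Cs")]
    te = [p.protein_id for p in bearing if _has_domain(p, "TE")]
    if len(cs) != 1 or len(te) != 1:
        raise ArchitectureError(
            f"need exactly one Cs-bearing and one TE-bearing protein "
            f"(Cs: {cs or 'none'}, TE: {te or 'none'})"
        )
    first = next(p for p in bearing if p.protein_id == cs[0])
    last = next(p for p in bearing if p.protein_id == te[0])
    internal = [p for p in bearing if p.protein_id not in (cs[0], te[0])]
    log.append(
        f"Cs protein {cs[0]} first, TE protein {te[0]} last; "
        f"internal proteins in input order: {','.join(p.protein_id for p in internal)}"
    )
    ordered = [first] + internal + ([last] if last is not first else [])
    return ordered, log


def complement_trans(arch: ModuleArchitecture) -> tuple[ModuleArchitecture, list]:
    """Assign unclaimed standalone A-domain substrates to inactive modules.

    Assignment is one-to-one in assembly input order; inactive modules left
    without a donor are flagged in the warnings, never dropped silently.
    """
    arch = copy.deepcopy(arch)
    warnings: list[str] = []
    donors = list(arch.standalone_adomains)
    for protein in arch.proteins:
        for module in protein.modules:
            if module.a_domain_active or module.substrate not in ("unknown", "", None):
                continue
            if donors:
                donor_id, substrate = donors.pop(0)
                module.substrate = substrate
                warnings.append(
                    f"module {module.module_id}: inactive A-domain complemented "
                    f"in trans by {donor_id} ({substrate})"
                )
            else:
                warnings.append(
                    f"module {module.module_id}: inactive A-domain unresolved "
                    "(no standalone A-domain left)"
                )
    for donor_id, substrate in donors:
        warnings.append(f"standalone A-domain {donor_id} ({substrate}) unused")
    return arch, warnings


def apply_heterocycle_rules(
    assembly: list, tailoring_tags: set
) -> tuple[list, list]:
    """Cy + Cys -> thiazoline; an FMN oxidase promotes thiazolines to thiazoles.

    ``assembly`` is a list of ``(ModuleAnnotation, Monomer)`` pairs in
    assembly-line order; non-Cys Cy modules are flagged as anomalies.
    """
    warnings: list[str] = []
    oxidase = "fmn_oxidase" in tailoring_tags
    for module, monomer in assembly:
        if "Cy" not in module.domains:
            continue
        if monomer.base == "Cys":
            monomer.ring_state = "thiazole" if oxidase else "thiazoline"
        else:
            warnings.append(
                f"module {module.module_id}: Cy domain with non-Cys substrate "
                f"{monomer.base!r} (anomaly, no ring formed)"
            )
    return assembly, warnings


def apply_paba_tailoring(assembly: list, tailoring_tags: set) -> tuple[list, list]:
    """Keep AHIBA only with hydroxylase + methylation-class tailoring support."""
    warnings: list[str] = []
    supported = "hydroxylase" in tailoring_tags and (
        "o_methyltransferase" in tailoring_tags or "isomethyl" in tailoring_tags
    )
    modified = 0
    for module, monomer in assembly:
        if monomer.base != "AHIBA":
            continue
        if supported:
            modified += 1
        else:
            monomer.base = "PABA"
            warnings.append(
                f"module {module.module_id}: AHIBA annotation without tailoring "
                "support (hydroxylase + methylation), downgraded to PABA"
            )
    if modified:
        warnings.append(f"{modified} aryl monomer(s) carry tailoring modifications")
    return assembly, warnings


def predict_structure(
    arch: ModuleArchitecture,
    order: list | None = None,
    lipid_chain: int = 14,
) -> PredictedStructure:
    """Full pipeline: order -> trans-complement -> rings -> aryl tailoring."""
    ordered, log = order_proteins(arch, order=order)
    order_ids = [p.protein_id for p in ordered]
    arch2, warnings = complement_trans(arch)
    by_id = {p.protein_id: p for p in arch2.proteins}
    assembly: list = []
    for pid in order_ids:
        for module in by_id[pid].modules:
            if module.substrate in ("unknown", "", None):
                warnings.append(
                    f"module {module.module_id}: no resolved substrate, "
                    "contributes no residue"
                )
                continue
            monomer = Monomer(base=module.substrate, d_configured="E" in module.domains)
            assembly.append((module, monomer))
    tags = arch2.tailoring_tags()
    assembly, w = apply_heterocycle_rules(assembly, tags)
    warnings.extend(w)
    assembly, w = apply_paba_tailoring(assembly, tags)
    warnings.extend(w)

    has_cs = any("Cs" in m.domains for p in arch2.proteins for m in p.modules)
    lipid = LipidRule(chosen_chain=lipid_chain) if has_cs else None
    log.append("lipid attached (Cs starter present)" if has_cs else "no Cs starter, no lipid")
    has_te = any("TE" in m.domains for p in arch2.proteins for m in p.modules)
    log.append("chain released at TE" if has_te else "warning: no TE terminus")

    monomers = [mono for _, mono in assembly]
    counts: dict[str, int] = {}
    for mono in monomers:
        counts[mono.monomer_class] = counts.get(mono.monomer_class, 0) + 1
    return PredictedStructure(
        monomers=monomers, lipid=lipid, counts=counts, warnings=warnings, log=log
    )


# ---------------------------------------------------------------------------
# annotation-table JSON (de)serialization

def architecture_to_json(arch: ModuleArchitecture) -> str:
    payload = {
        "proteins": [
            {
                "protein_id": p.protein_id,
                "modules": [
                    {
                        "module_id": m.module_id,
                        "domains": list(m.domains),
                        "substrate": m.substrate,
                        "a_domain_active": m.a_domain_active,
                    }
                    for m in p.modules
                ],
            }
            for p in arch.proteins
        ],
        "tailoring_genes": [list(t) for t in arch.tailoring_genes],
        "standalone_adomains": [list(t) for t in arch.standalone_adomains],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def architecture_from_json(text: str) -> ModuleArchitecture:
    payload = json.loads(text)
    proteins = [
        ProteinAnnotation(
            protein_id=p["protein_id"],
            modules=[
                ModuleAnnotation(
                    module_id=m["module_id"],
                    domains=tuple(m["domains"]),
                    substrate=m.get("substrate", "unknown"),
                    a_domain_active=m.get("a_domain_active", True),
                )
                for m in p["modules"]
            ],
        )
        for p in payload["proteins"]
    ]
    return ModuleArchitecture(
        proteins=proteins,
        tailoring_genes=[tuple(t) for t in payload.get("tailoring_genes", [])],
        standalone_adomains=[tuple(t) for t in payload.get("standalone_adomains", [])],
    )
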