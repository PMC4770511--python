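"""Family registry: motif definitions for the 39 neuropeptide / protein-
hormone families and peptide/precursor classification.

Motifs are anchored patterns over the mature-peptide *body* (the encoded
segment with the C-terminal amide-donor Gly removed).  The wildcard ``X``
matches any residue except K/R, so a motif can never swallow a convertase
cleavage signal.  Overlaps between families (natalisin vs TKRP, trypto-PK vs
PK, AST-CC vs AST-C) are resolved by explicit integer priorities, longer
anchored patterns carrying the higher value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .models import MaturePeptide

# X wildcard: any standard residue except the basic cleavage-signal residues
X_CLASS = "[ACDEFGHILMNPQSTVWY]"

EXPECTED_FAMILY_COUNT = 39

LIGAND_PVK = "PVK"
LIGAND_TRYPTO_PK = "trypto_PK"
LIGAND_PK = "PK"
LIGAND_OTHER = "other"

# ligand-typing patterns for the capa/pk three-ligand complex; checked in
# priority order trypto_PK > PK > PVK (the three receptor classes are
# mutually exclusive after priority)
_LIGAND_PATTERNS = [
    (LIGAND_TRYPTO_PK, re.compile(f"W[FY]GPRL$".replace("X", X_CLASS))),
    (LIGAND_PK, re.compile(f"F{X_CLASS}PRL$")),
    (LIGAND_PVK, re.compile("PR[VIL]$")),
]

CAPA_COMPLEX = {"CAPA", "PK/PBAN"}


class RegistryError(ValueError):
    pass


def _compile(pattern: str) -> re.Pattern:
    return re.compile(pattern.replace("X", X_CLASS))


@dataclass
class Motif:
    id: str
    pattern: str
    anchor: str  # c_term | n_term | internal | full
    amidated: bool
    regex: re.Pattern = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.anchor not in {"c_term", "n_term", "internal", "full"}:
            raise RegistryError(f"motif {self.id}: bad anchor {self.anchor}")
        self.regex = _compile(self.pattern)

    def match_rate(self) -> float:
        """Expected per-position probability of a chance match in a uniform
        random protein (product of per-token class sizes / 20)."""
        rate = 1.0
        i = 0
        pat = self.pattern
        while i < len(pat):
            ch = pat[i]
            if ch == "[":
                j = pat.index("]", i)
                size = len([c for c in pat[i + 1:j] if c.isalpha()])
                p, i = size / 20.0, j + 1
            elif ch == "X":
                p, i = 18 / 20.0, i + 1
            elif ch == ".":
                p, i = 1.0, i + 1
            else:
                p, i = 1 / 20.0, i + 1
            reps = 1
            if i < len(pat) and pat[i] == "{":
                j = pat.index("}", i)
                reps = int(pat[i + 1:j].split(",")[0])
                i = j + 1
            rate *= p ** reps
        return rate

    def matches_body(self, body: str) -> bool:
        if self.anchor == "c_term":
            return re.search(self.regex.pattern + "$", body) is not None
        if self.anchor == "n_term":
            return self.regex.match(body) is not None
        if self.anchor == "full":
            return self.regex.fullmatch(body) is not None
        return self.regex.search(body) is not None


@dataclass
class FamilyDefinition:
    name: str
    motifs: list[Motif]
    copy_class: str  # single | multiple
    priority: int = 50
    full_name: str = ""
    source: str = ""
    low_confidence: bool = False
    exemplars: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.motifs:
            raise RegistryError(f"family {self.name}: no motifs")
        if self.copy_class not in {"single", "multiple"}:
            raise RegistryError(f"family {self.name}: bad copy_class {self.copy_class}")


class FamilyRegistry:
    def __init__(self, families: list[FamilyDefinition]):
        names = [f.name for f in families]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RegistryError(f"duplicate family names: {sorted(dupes)}")
        self.families = {f.name: f for f in families}

    def __len__(self) -> int:
        return len(self.families)

    def __contains__(self, name: str) -> bool:
        return name in self.families

    def __getitem__(self, name: str) -> FamilyDefinition:
        return self.families[name]

    def unanchored_patterns(self, max_rate: Optional[float] = None) -> list[tuple[str, str, re.Pattern]]:
        """(family, motif id, compiled unanchored regex) for motif scanning
        over whole precursors/translations (artifact flags, site
        protection).  ``max_rate`` keeps only motifs whose chance-match
        probability per position is below the bound (high-specificity
        evidence)."""
        out = []
        for fam in self.families.values():
            for mot in fam.motifs:
                if max_rate is not None and mot.match_rate() > max_rate:
                    continue
                out.append((fam.name, mot.id, mot.regex))
        return out


def peptide_body(peptide: MaturePeptide) -> str:
    """The amide-form body: encoded segment minus the amide-donor Gly."""
    return peptide.raw[:-1] if peptide.amidated else peptide.raw


def default_registry_path() -> Path:
    return Path(resources.files("npmine").joinpath("data/families.yaml"))


def load_registry(path: Optional[str | Path] = None, allow_custom: bool = False) -> FamilyRegistry:
    """Load and validate a registry file.  The default registry must contain
    exactly the 39 screened families; pass ``allow_custom=True`` (CLI
    ``--allow-custom-registry``) to accept a different census."""
    path = Path(path) if path else default_registry_path()
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    families = []
    for block in doc["families"]:
        motifs = [
            Motif(m["id"], m["pattern"], m["anchor"], bool(m["amidated"]))
            for m in block["motifs"]
        ]
        families.append(
            FamilyDefinition(
                name=block["name"],
                motifs=motifs,
                copy_class=block["copy_class"],
                priority=int(block.get("priority", 50)),
                full_name=block.get("full_name", ""),
                source=block.get("source", ""),
                low_confidence=bool(block.get("low_confidence", False)),
                exemplars=list(block.get("exemplars", [])),
            )
        )
    registry = FamilyRegistry(families)
    if len(registry) != EXPECTED_FAMILY_COUNT and not allow_custom:
        raise RegistryError(
            f"registry has {len(registry)} families, expected {EXPECTED_FAMILY_COUNT}"
            " (use allow_custom to override)"
        )
    return registry


def classify_peptide(peptide: MaturePeptide, registry: FamilyRegistry) -> list[tuple[str, str]]:
    """All (family, motif id) matches for one mature peptide, sorted by
    descending family priority.  Amidated motifs only match amidated
    peptides and vice versa."""
    body = peptide_body(peptide)
    hits = []
    for fam in registry.families.values():
        for mot in fam.motifs:
            if mot.amidated != peptide.amidated:
                continue
            if mot.matches_body(body):
                hits.append((fam.name, mot.id))
                break
    hits.sort(key=lambda h: (-registry[h[0]].priority, h[0]))
    return hits


def type_capa_ligand(peptide: MaturePeptide) -> str:
    """Ligand type of a capa/pk-complex peptide: trypto_PK > PK > PVK > other.
    Non-amidated peptides are never capa/pk ligands."""
    if not peptide.amidated:
        return LIGAND_OTHER
    body = peptide_body(peptide)
    for ligand, rx in _LIGAND_PATTERNS:
        if rx.search(body):
            return ligand
    return LIGAND_OTHER


def assign_family(annotated, registry: FamilyRegistry):
    """Assign a precursor to its family from its excised peptides.

    The precursor family is the highest-priority family matched by at least
    one peptide.  Within the capa/pk complex the gene identity follows the
    ligand content (a PVK-containing precursor is CAPA; a PVK-free,
    PK-containing one is PK/PBAN).  ``paracopy_count`` counts the peptides
    matching the winning family (1 per precursor for single-copy families);
    incomplete precursors carry a partial flag so downstream statistics use
    max-only semantics.
    """
    from .models import FamilyAssignment

    per_peptide = [(pep, classify_peptide(pep, registry)) for pep in annotated.peptides]
    matched_families = {fam for _, hits in per_peptide for fam, _ in hits}

    if not matched_families:
        family = "unassigned"
    elif matched_families <= CAPA_COMPLEX and "CAPA" in matched_families:
        ligands = {type_capa_ligand(pep) for pep, hits in per_peptide if hits}
        if LIGAND_PVK in ligands:
            family = "CAPA"
        elif LIGAND_PK in ligands:
            family = "PK/PBAN"
        else:
            family = "CAPA"  # trypto-PK-only gene (locust-style)
    else:
        family = max(matched_families, key=lambda f: (registry[f].priority, f))

    matched = []
    if family != "unassigned":
        for pep, hits in per_peptide:
            for fam, mot_id in hits:
                if fam == family or (family in CAPA_COMPLEX and fam in CAPA_COMPLEX):
                    matched.append((pep.copy_index, mot_id))
                    break
    count = len(matched)
    if family != "unassigned" and registry[family].copy_class == "single":
        count = 1

    annotated.family = family
    annotated.matched_peptides = matched
    annotated.paracopy_count = count
    annotated.partial = annotated.record.is_partial
    return FamilyAssignment(
        precursor_id=annotated.id,
        family=family,
        matched_peptides=matched,
        paracopy_count=count,
        partial=annotated.record.is_partial,
        species=annotated.record.species,
        taxon_group=annotated.record.taxon_group,
    )
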