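"""Classification of a species' capa/pk gene complement into architecture
patterns A, B, B1, C1, C2, C3.

The capa/pk complex encodes up to three ligand classes with distinct
receptors: periviscerokinins (PVK, PRV/I/Lamide), pyrokinins (PK,
FXPRLamide) and the tryptophan-containing trypto-PK (WFGPRLamide class).
The architecture pattern describes how those ligands are distributed over
genes and transcripts: a single two-ligand gene (A, the myriapod/chelicerate
state), a single three-ligand gene (B; with an additional PVK/trypto-PK-only
splice transcript, B1), or duplicated capa and pk genes with different
ligand sortings (C1: pk gene encodes only PKs; C2: the pk gene carries a
trypto-PK in addition to the PKs; C3: the capa gene additionally carries
PKs).  The pattern depends only on presence/absence of ligand types and the
gene/transcript structure, never on paracopy multiplicity — except that
pattern A requires the absence of trypto-PK anywhere.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .models import TaxonGroup
from .registry import LIGAND_PK, LIGAND_PVK, LIGAND_TRYPTO_PK

PATTERNS = ("A", "B", "B1", "C1", "C2", "C3", "unresolved")


@dataclass
class GeneProduct:
    gene_id: str
    transcripts: list[Counter]  # ligand-composition multisets
    splice_group: Optional[str] = None

    def union_types(self) -> frozenset:
        types = set()
        for t in self.transcripts:
            types |= {k for k, v in t.items() if v > 0}
        return frozenset(types)


@dataclass
class GeneComplement:
    species: str
    taxon_group: TaxonGroup
    genes: list[GeneProduct]


@dataclass
class ArchitecturePattern:
    value: str
    rationale: str


def _types(c: Counter) -> frozenset:
    return frozenset(k for k, v in c.items() if v > 0)


_FULL = frozenset({LIGAND_PVK, LIGAND_TRYPTO_PK, LIGAND_PK})
_PVK_TPK = frozenset({LIGAND_PVK, LIGAND_TRYPTO_PK})
_PVK_PK = frozenset({LIGAND_PVK, LIGAND_PK})


def classify_architecture(complement: GeneComplement) -> ArchitecturePattern:
    """Decision table over ligand compositions and gene/transcript counts."""
    if not complement.genes:
        raise ValueError(f"{complement.species}: empty capa/pk complement")
    genes = complement.genes
    if any(not g.transcripts or any(sum(t.values()) == 0 for t in g.transcripts) for g in genes):
        raise ValueError(f"{complement.species}: empty transcript composition")

    if len(genes) == 1:
        gene = genes[0]
        tsets = [_types(t) for t in gene.transcripts]
        if len(tsets) == 1:
            s = tsets[0]
            if s == _PVK_PK:
                return ArchitecturePattern("A", "single gene encoding PVKs and PKs, no trypto-PK")
            if s == _FULL:
                return ArchitecturePattern("B", "single gene, single transcript encoding PVKs, trypto-PK and PKs")
            if s == {LIGAND_PVK}:
                return ArchitecturePattern("unresolved", "derived: PVK-only")
            if s == {LIGAND_PK}:
                return ArchitecturePattern("unresolved", "derived: PK-only")
            return ArchitecturePattern("unresolved", f"single gene with composition {sorted(s)}")
        if len(tsets) == 2 and _FULL in tsets and _PVK_TPK in tsets:
            return ArchitecturePattern(
                "B1", "three-ligand transcript plus a PVK/trypto-PK-only splice transcript"
            )
        return ArchitecturePattern(
            "unresolved", f"single gene with {len(tsets)} transcripts of compositions {sorted(map(sorted, tsets))}"
        )

    if len(genes) == 2:
        sets = {g.gene_id: g.union_types() for g in genes}
        with_pvk = [g for g in genes if LIGAND_PVK in sets[g.gene_id]]
        without_pvk = [g for g in genes if LIGAND_PVK not in sets[g.gene_id]]
        if len(with_pvk) != 1:
            which = "two PVK-containing genes" if len(with_pvk) == 2 else "no PVK-containing gene"
            return ArchitecturePattern("unresolved", f"cannot label capa-like vs pk-like: {which}")
        capa, pk = sets[with_pvk[0].gene_id], sets[without_pvk[0].gene_id]
        if capa == _PVK_TPK and pk == {LIGAND_PK}:
            return ArchitecturePattern("C1", "capa gene: PVK+trypto-PK; pk gene: PKs only")
        if capa == _PVK_TPK and pk == {LIGAND_TRYPTO_PK, LIGAND_PK}:
            return ArchitecturePattern("C2", "capa gene: PVK+trypto-PK; pk gene: trypto-PK+PKs")
        if capa == _FULL and pk == {LIGAND_TRYPTO_PK, LIGAND_PK}:
            return ArchitecturePattern("C3", "capa gene additionally encodes PKs; pk gene: trypto-PK+PKs")
        return ArchitecturePattern(
            "unresolved", f"two genes with compositions capa-like={sorted(capa)}, pk-like={sorted(pk)}"
        )

    return ArchitecturePattern("unresolved", f"{len(genes)} capa/pk-related genes")


def summarize_patterns(complements: list[GeneComplement]) -> dict:
    """Per-taxon histogram of patterns; taxa with more than one observed
    pattern are flagged as mixed."""
    hist: dict[str, Counter] = {}
    for comp in complements:
        taxon = comp.taxon_group.value
        hist.setdefault(taxon, Counter())[classify_architecture(comp).value] += 1
    return {
        taxon: {"patterns": dict(counts), "mixed": len(counts) > 1}
        for taxon, counts in hist.items()
    }


def complements_from_annotations(annotated: list, splice_groups: list) -> list[GeneComplement]:
    """Build per-species capa/pk gene complements from annotated precursors.

    Without genome data, two transcripts that do not share a splice group
    are treated as two genes; splice-grouped transcripts are one gene with
    several transcripts.
    """
    from .registry import CAPA_COMPLEX, LIGAND_OTHER, type_capa_ligand

    splice_of = {}
    for grp in splice_groups:
        for pid, _tag in grp.variants:
            splice_of[pid] = grp.gene_label

    by_species: dict[tuple[str, TaxonGroup], dict[str, list[Counter]]] = {}
    for ann in annotated:
        if ann.family not in CAPA_COMPLEX:
            continue
        comp = Counter(
            lig
            for lig in (type_capa_ligand(p) for p in ann.peptides)
            if lig != LIGAND_OTHER
        )
        if not comp:
            continue
        key = (ann.record.species, ann.record.taxon_group)
        gene = splice_of.get(ann.id, ann.id)
        by_species.setdefault(key, {}).setdefault(gene, []).append(comp)

    out = []
    for (species, taxon), genes in sorted(by_species.items()):
        out.append(
            GeneComplement(
                species=species,
                taxon_group=taxon,
                genes=[GeneProduct(gid, ts) for gid, ts in sorted(genes.items())],
            )
        )
    return out


def pattern_report(complements: list[GeneComplement]):
    """Tabular pattern report: species, taxon, pattern, rationale and a
    per-gene composition string (e.g. 'capa: PVK×3+tryptoPK; pk: PK×4')."""
    import pandas as pd

    short = {LIGAND_PVK: "PVK", LIGAND_TRYPTO_PK: "tryptoPK", LIGAND_PK: "PK"}
    rows = []
    for comp in complements:
        pat = classify_architecture(comp)
        parts = []
        for g in comp.genes:
            merged = Counter()
            for t in g.transcripts:
                merged.update(t)
            label = "capa" if LIGAND_PVK in g.union_types() else "pk"
            desc = "+".join(
                f"{short[k]}×{v}" if v > 1 else short[k]
                for k, v in sorted(merged.items())
            )
            parts.append(f"{label}: {desc}")
        rows.append(
            {
                "species": comp.species,
                "taxon": comp.taxon_group.value,
                "pattern": pat.value,
                "rationale": pat.rationale,
                "composition": "; ".join(parts),
            }
        )
    return pd.DataFrame(rows)
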