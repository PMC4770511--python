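"""Family registry: census, motif classification, ligand typing."""

import textwrap

import pytest

from npmine.models import MaturePeptide
from npmine.registry import (
    CAPA_COMPLEX,
    RegistryError,
    classify_peptide,
    load_registry,
    type_capa_ligand,
)


def _pep(body, amidated=True):
    raw = body + ("G" if amidated else "")
    return MaturePeptide((1, len(raw)), raw, "", amidated, body.startswith("Q"), 1)


def test_default_registry_has_39_families(registry):
    assert len(registry) == 39


def test_trissin_and_cnma_lookup(registry):
    assert "trissin" in registry
    assert "CNMa" in registry


def test_duplicate_family_name_rejected(tmp_path):
    doc = textwrap.dedent(
        """
        families:
          - name: AKH
            copy_class: single
            motifs: [{id: a, pattern: "QLNF", anchor: n_term, amidated: true}]
          - name: AKH
            copy_class: single
            motifs: [{id: b, pattern: "QVNF", anchor: n_term, amidated: true}]
        """
    )
    path = tmp_path / "reg.yaml"
    path.write_text(doc)
    with pytest.raises(RegistryError, match="duplicate"):
        load_registry(path, allow_custom=True)


def test_wrong_family_count_rejected_unless_custom(tmp_path):
    doc = textwrap.dedent(
        """
        families:
          - name: AKH
            copy_class: single
            motifs: [{id: a, pattern: "QLNF", anchor: n_term, amidated: true}]
        """
    )
    path = tmp_path / "reg.yaml"
    path.write_text(doc)
    with pytest.raises(RegistryError, match="expected 39"):
        load_registry(path)
    assert len(load_registry(path, allow_custom=True)) == 1


def test_ccap_variants_classify(registry):
    for body in ("PFCNAFAGC", "TFCNAFTGC"):
        hits = classify_peptide(_pep(body), registry)
        assert hits and hits[0][0] == "CCAP"


def test_unmatched_peptide_returns_empty(registry):
    assert classify_peptide(_pep("AAAAAA"), registry) == []


def test_amidation_state_must_match(registry):
    # CCAP requires amidation: the same body unamidated must not match CCAP
    hits = classify_peptide(_pep("PFCNAFAGC", amidated=False), registry)
    assert all(fam != "CCAP" for fam, _ in hits)


def test_every_exemplar_classifies_to_its_own_family(registry):
    """The registry is internally consistent: each family's exemplar
    peptides hit that family's motifs (capa/pk-complex exemplars may also
    hit the sibling family; those resolve at precursor level)."""
    for fam in registry.families.values():
        amidated = fam.motifs[0].amidated
        for body in fam.exemplars:
            hits = classify_peptide(_pep(body, amidated), registry)
            names = [h[0] for h in hits]
            assert fam.name in names, (fam.name, body, hits)
            if fam.name in CAPA_COMPLEX:
                assert set(names) <= CAPA_COMPLEX
            else:
                assert names[0] == fam.name, (fam.name, body, hits)


def test_classification_deterministic_and_single_after_priority(registry):
    bodies = [ex for fam in registry.families.values() for ex in fam.exemplars]
    for body in bodies:
        for amid in (True, False):
            h1 = classify_peptide(_pep(body, amid), registry)
            h2 = classify_peptide(_pep(body, amid), registry)
            assert h1 == h2


def test_ligand_typing_examples():
    assert type_capa_ligand(_pep("DGSGLWFGPRL")) == "trypto_PK"
    # a trypto-PK also matching FXPRLa still types trypto (priority)
    assert type_capa_ligand(_pep("TGPSASSGLWFGPRL")) == "trypto_PK"
    assert type_capa_ligand(_pep("ASGLVAFPRV")) == "PVK"
    assert type_capa_ligand(_pep("TGPSASSGLFSPRL")) == "PK"
    assert type_capa_ligand(_pep("AWQSLQSSW")) == "other"
    # non-amidated peptides are never capa/pk ligands
    assert type_capa_ligand(_pep("ASGLVAFPRV", amidated=False)) == "other"


def test_ligand_classes_mutually_exclusive(registry):
    """After priority, every amidated exemplar maps to exactly one ligand
    class (trypto-PK ∩ PK = ∅)."""
    seen = {}
    for fam in registry.families.values():
        for body in fam.exemplars:
            lig = type_capa_ligand(_pep(body))
            seen[body] = lig
    assert seen["DGSGLWFGPRL"] == "trypto_PK"
    assert seen["TGPSASSGLFSPRL"] == "PK"
    assert seen["ASGLVAFPRV"] == "PVK"
    non_capa = [b for f in registry.families.values() if f.name not in CAPA_COMPLEX
                for b in f.exemplars]
    assert all(seen[b] == "other" for b in non_capa)
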