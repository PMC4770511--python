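"""capa/pk architecture classification against a brute-force decision table."""

import itertools
from collections import Counter

import pytest

from npmine.capa_pk import (
    ArchitecturePattern,
    GeneComplement,
    GeneProduct,
    classify_architecture,
    summarize_patterns,
)
from npmine.models import TaxonGroup

PVK, TPK, PK = "PVK", "trypto_PK", "PK"


def _comp(*genes, species="sp", taxon=TaxonGroup.OTHER):
    products = [
        GeneProduct(f"g{i}", [Counter(t) for t in transcripts])
        for i, transcripts in enumerate(genes)
    ]
    return GeneComplement(species, taxon, products)


def oracle_pattern(genes):
    """Independent literal evaluation of the A/B/B1/C1-C3 decision table on
    (gene -> transcript ligand-type sets)."""
    tsets = [[frozenset(k for k, v in t.items() if v > 0) for t in g] for g in genes]
    full = frozenset({PVK, TPK, PK})
    pvk_tpk = frozenset({PVK, TPK})
    if len(tsets) == 1:
        g = tsets[0]
        if len(g) == 1:
            if g[0] == {PVK, PK}:
                return "A"
            if g[0] == full:
                return "B"
            return "unresolved"
        if len(g) == 2 and set(g) == {full, pvk_tpk}:
            return "B1"
        return "unresolved"
    if len(tsets) == 2:
        unions = [frozenset().union(*g) for g in tsets]
        pvk_genes = [u for u in unions if PVK in u]
        if len(pvk_genes) != 1:
            return "unresolved"
        capa = pvk_genes[0]
        pk = [u for u in unions if PVK not in u][0]
        if capa == pvk_tpk and pk == {PK}:
            return "C1"
        if capa == pvk_tpk and pk == {TPK, PK}:
            return "C2"
        if capa == full and pk == {TPK, PK}:
            return "C3"
        return "unresolved"
    return "unresolved"


def test_pattern_examples():
    assert classify_architecture(_comp([{PVK: 4, PK: 3}])).value == "A"
    assert classify_architecture(_comp([{PVK: 4, TPK: 1, PK: 3}])).value == "B"
    assert classify_architecture(
        _comp([{PVK: 3, TPK: 1, PK: 2}, {PVK: 3, TPK: 1}])
    ).value == "B1"
    assert classify_architecture(
        _comp([{PVK: 3, TPK: 1}], [{PK: 4}])
    ).value == "C1"
    assert classify_architecture(
        _comp([{PVK: 2, TPK: 2}], [{TPK: 2, PK: 2}])
    ).value == "C2"
    assert classify_architecture(
        _comp([{PVK: 3, TPK: 1, PK: 2}], [{TPK: 1, PK: 2}])
    ).value == "C3"


def test_derived_states_unresolved_with_rationale():
    pvk_only = classify_architecture(_comp([{PVK: 3}]))
    assert pvk_only.value == "unresolved" and "PVK-only" in pvk_only.rationale
    pk_only = classify_architecture(_comp([{PK: 5}]))
    assert pk_only.value == "unresolved" and "PK-only" in pk_only.rationale
    two_pvk = classify_architecture(_comp([{PVK: 1}], [{PVK: 2, PK: 1}]))
    assert two_pvk.value == "unresolved"


def test_empty_complement_raises():
    with pytest.raises(ValueError):
        classify_architecture(GeneComplement("sp", TaxonGroup.OTHER, []))
    with pytest.raises(ValueError):
        classify_architecture(_comp([{}]))


def _multisets(max_copies=6):
    for a, b, c in itertools.product(range(max_copies + 1), repeat=3):
        if a + b + c > 0:
            yield {k: v for k, v in ((PVK, a), (TPK, b), (PK, c)) if v > 0}


def test_single_gene_space_matches_oracle():
    for m in _multisets():
        comp = _comp([m])
        assert classify_architecture(comp).value == oracle_pattern([[Counter(m)]])


def test_two_gene_and_two_transcript_space_matches_oracle():
    """Exhaustive presence/absence structures with multiplicities sampled
    from {1, 2, 6} per present ligand type."""
    type_sets = [s for r in (1, 2, 3) for s in itertools.combinations((PVK, TPK, PK), r)]
    mults = (1, 2, 6)

    def realizations(ts):
        for vals in itertools.product(mults, repeat=len(ts)):
            yield dict(zip(ts, vals))

    comps = [m for ts in type_sets for m in realizations(ts)]
    # two separate genes
    for m1, m2 in itertools.product(comps, comps):
        comp = _comp([m1], [m2])
        assert classify_architecture(comp).value == oracle_pattern(
            [[Counter(m1)], [Counter(m2)]]
        )
    # one gene, two transcripts
    for m1, m2 in itertools.product(comps, comps):
        comp = _comp([m1, m2])
        assert classify_architecture(comp).value == oracle_pattern(
            [[Counter(m1), Counter(m2)]]
        )


def test_pattern_invariant_to_multiplicity():
    base = classify_architecture(_comp([{PVK: 1, TPK: 1, PK: 1}])).value
    scaled = classify_architecture(_comp([{PVK: 6, TPK: 2, PK: 4}])).value
    assert base == scaled == "B"
    # but pattern A requires absence of trypto-PK anywhere
    assert classify_architecture(_comp([{PVK: 1, PK: 1}])).value == "A"
    assert classify_architecture(_comp([{PVK: 1, TPK: 1, PK: 1}])).value != "A"


def test_summarize_patterns_histograms_and_mixed_flags():
    dipl = [
        _comp([{PVK: 3, TPK: 1}], [{PK: 4}], species=f"d{i}",
              taxon=TaxonGroup.DIPLURA)
        for i in range(4)
    ]
    zyg = [
        _comp([{PVK: 2, TPK: 2}], [{TPK: 2, PK: 2}], species=f"z{i}",
              taxon=TaxonGroup.ZYGENTOMA)
        for i in range(3)
    ] + [
        _comp([{PVK: 4, TPK: 1, PK: 1}], [{TPK: 2, PK: 2}], species="thermobia",
              taxon=TaxonGroup.ZYGENTOMA)
    ]
    hist = summarize_patterns(dipl + zyg)
    assert hist["Diplura"] == {"patterns": {"C1": 4}, "mixed": False}
    assert hist["Zygentoma"]["patterns"] == {"C2": 3, "C3": 1}
    assert hist["Zygentoma"]["mixed"]
    assert "Protura" not in hist  # empty taxon absent from histogram
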