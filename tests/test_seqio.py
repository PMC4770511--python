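"""Sequence/annotation IO: header conventions, completeness marks, round trips."""

import pytest

from npmine import seqio
from npmine.models import PrecursorRecord, TaxonGroup, TranscriptRecord
from npmine.pipeline import annotate_dataset
from npmine.registry import load_registry
from npmine.synth import gen_precursor


def test_header_convention_and_metadata_tsv(tmp_path):
    fasta = tmp_path / "in.fasta"
    fasta.write_text(
        ">p1|Lepidocampa weberi|Diplura\nMKTLLVLAVLLAVASADDA\n"
        ">p2\nACGTACGTACGT\n"
    )
    meta = tmp_path / "meta.tsv"
    meta.write_text("id\tspecies\ttaxon_group\np2\tFolsomia candida\tCollembola\n")
    manifest = seqio.read_sequences(fasta, meta)
    assert len(manifest.records) == 2
    p1, p2 = manifest.records
    assert p1.species == "Lepidocampa weberi"
    assert p1.taxon_group is TaxonGroup.DIPLURA
    assert isinstance(p1, PrecursorRecord)
    assert isinstance(p2, TranscriptRecord)  # alphabet auto-detection
    assert p2.taxon_group is TaxonGroup.COLLEMBOLA


def test_metadata_overrides_header(tmp_path, caplog):
    fasta = tmp_path / "in.fasta"
    fasta.write_text(">p1|Wrong species|Protura\nMKTLLVLAVLLAVASADDA\n")
    meta = tmp_path / "meta.tsv"
    meta.write_text("id\tspecies\ttaxon_group\np1\tRight species\tDiplura\n")
    manifest = seqio.read_sequences(fasta, meta)
    assert manifest.records[0].species == "Right species"
    assert manifest.records[0].taxon_group is TaxonGroup.DIPLURA


def test_unknown_taxon_maps_to_other_never_dropped(tmp_path):
    fasta = tmp_path / "in.fasta"
    fasta.write_text(">p1|Some species|Tardigrada\nMKTLLVLAVLLAVASADDA\n")
    manifest = seqio.read_sequences(fasta)
    assert len(manifest.records) == 1
    assert manifest.records[0].taxon_group is TaxonGroup.OTHER


def test_ellipsis_sets_completeness_flags(tmp_path):
    fasta = tmp_path / "in.fasta"
    fasta.write_text(">p1|S|Diplura\n...LLVLAVLLAVASADDA...\n")
    rec = seqio.read_sequences(fasta).records[0]
    assert not rec.n_complete and not rec.c_complete
    assert rec.residues == "LLVLAVLLAVASADDA"


def test_roundtrip_preserves_sequences_and_flags(tmp_path):
    fasta = tmp_path / "in.fasta"
    fasta.write_text(
        ">p1|Sp a|Diplura\n...MKTLLVLAVLLAVASADDA\n"
        ">t1|Sp b|Collembola\nACGTNACGT\n"
    )
    m1 = seqio.read_sequences(fasta)
    out = tmp_path / "out.fasta"
    seqio.write_sequences(m1, out)
    m2 = seqio.read_sequences(out)
    for a, b in zip(m1.records, m2.records):
        assert type(a) is type(b)
        payload_a = a.residues if isinstance(a, PrecursorRecord) else a.sequence
        payload_b = b.residues if isinstance(b, PrecursorRecord) else b.sequence
        assert payload_a == payload_b
        assert (a.species, a.taxon_group) == (b.species, b.taxon_group)
    assert not m2.records[0].n_complete


def test_mixed_alphabet_record_raises_naming_the_record(tmp_path):
    fasta = tmp_path / "in.fasta"
    fasta.write_text(">weird|S|other\nACGTBJZ\n")
    with pytest.raises(seqio.FormatError, match="weird"):
        seqio.read_sequences(fasta)


def test_missing_file_raises_io_error(tmp_path):
    with pytest.raises(IOError):
        seqio.read_sequences(tmp_path / "nope.fasta")


@pytest.fixture(scope="module")
def annotated_precursors():
    registry = load_registry()
    bundles = [gen_precursor("AST-A", 3, seed=5, registry=registry),
               gen_precursor("CCAP", 1, seed=5, registry=registry)]
    return annotate_dataset([b.precursor for b in bundles], registry).annotated


def test_tsv_annotation_rows(tmp_path, annotated_precursors):
    path = tmp_path / "ann.tsv"
    seqio.write_annotations(annotated_precursors, path, "TSV")
    lines = path.read_text().strip().splitlines()
    n_peptides = sum(len(a.peptides) for a in annotated_precursors)
    assert len(lines) == 1 + n_peptides  # header + one row per mature peptide


def test_empty_annotation_list_gives_header_only(tmp_path):
    path = tmp_path / "empty.tsv"
    seqio.write_annotations([], path, "TSV")
    assert path.read_text().strip() == "\t".join(seqio.TSV_COLUMNS)


def test_gff3_roundtrip_spans(tmp_path, annotated_precursors):
    path = tmp_path / "ann.gff3"
    seqio.write_annotations(annotated_precursors, path, "GFF3")
    spans = seqio.read_annotation_spans(path)
    for ann in annotated_precursors:
        assert spans[ann.id] == [p.span for p in ann.peptides]


def test_out_of_range_span_raises(tmp_path, annotated_precursors):
    import copy

    broken = copy.deepcopy(annotated_precursors)
    broken[0].peptides[0].span = (1, len(broken[0].record.residues) + 10)
    with pytest.raises(ValueError, match="span"):
        seqio.write_annotations(broken, tmp_path / "x.tsv", "TSV")
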