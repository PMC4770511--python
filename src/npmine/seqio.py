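"""FASTA/TSV/GFF3 input and output.

Sequence input is FASTA (nucleotide or amino acid, auto-detected per record
by composition).  Species/taxon metadata come either from a sidecar TSV with
columns ``id, species, taxon_group`` or from the header convention
``>id|species|taxon``; the sidecar takes precedence, conflicts are logged as
warnings.  ``...`` (or a run of terminal ``X``) at either end of a protein
sequence marks incompleteness and is stripped into the completeness flags.

All coordinates in annotation output are 1-based inclusive on the precursor
protein (GFF3 convention).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO as _BioSeqIO

from .models import (
    AnnotatedPrecursor,
    DatasetManifest,
    PrecursorRecord,
    TaxonGroup,
    TranscriptRecord,
    NT_ALPHABET,
    AA_ALPHABET,
)

log = logging.getLogger("npmine.seqio")

ELLIPSIS_MARKS = ("...", "…")

TSV_COLUMNS = [
    "precursor_id",
    "family",
    "start",
    "end",
    "processed",
    "amidated",
    "pyroglu",
    "copy_index",
]


class FormatError(ValueError):
    pass


def _strip_incompleteness(seq: str) -> tuple[str, bool, bool]:
    """Remove '...' / terminal X-run markers; return (seq, n_complete, c_complete)."""
    n_complete = True
    c_complete = True
    for mark in ELLIPSIS_MARKS:
        if seq.startswith(mark):
            seq = seq[len(mark):]
            n_complete = False
        if seq.endswith(mark):
            seq = seq[: -len(mark)]
            c_complete = False
    # a run of >=3 terminal X is treated as an incompleteness marker
    if seq.startswith("XXX"):
        seq = seq.lstrip("X")
        n_complete = False
    if seq.endswith("XXX"):
        seq = seq.rstrip("X")
        c_complete = False
    return seq, n_complete, c_complete


def _detect_alphabet(seq: str, record_id: str) -> str:
    letters = set(seq.upper())
    if letters <= NT_ALPHABET:
        return "nt"
    if letters <= AA_ALPHABET:
        return "aa"
    raise FormatError(f"record {record_id}: mixed/unknown alphabet {sorted(letters - AA_ALPHABET)}")


def _read_metadata(path: str | Path) -> dict[str, tuple[str, str]]:
    meta: dict[str, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            meta[row["id"]] = (row["species"], row["taxon_group"])
    return meta


def read_sequences(path: str | Path, metadata: Optional[str | Path] = None) -> DatasetManifest:
    """Read a FASTA file into a :class:`DatasetManifest`.

    Metadata precedence: sidecar TSV overrides the ``id|species|taxon``
    header convention; a conflict is logged as a warning.  No record is
    silently discarded: malformed records raise, naming the record id.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    meta = _read_metadata(metadata) if metadata else {}

    records = []
    for entry in _BioSeqIO.parse(str(path), "fasta"):
        header = entry.description
        parts = header.split("|")
        rec_id = parts[0].strip()
        species, taxon = "unknown", "other"
        if len(parts) >= 3:
            species, taxon = parts[1].strip(), parts[2].strip()
        if rec_id in meta:
            m_species, m_taxon = meta[rec_id]
            if len(parts) >= 3 and (m_species != species or TaxonGroup.coerce(m_taxon) != TaxonGroup.coerce(taxon)):
                log.warning(
                    "record %s: metadata TSV (%s/%s) overrides header (%s/%s)",
                    rec_id, m_species, m_taxon, species, taxon,
                )
            species, taxon = m_species, m_taxon
        raw = str(entry.seq)
        seq, n_complete, c_complete = _strip_incompleteness(raw)
        if not seq:
            raise FormatError(f"record {rec_id}: empty sequence")
        kind = _detect_alphabet(seq, rec_id)
        if kind == "nt":
            records.append(TranscriptRecord(rec_id, species, TaxonGroup.coerce(taxon), seq))
        else:
            records.append(
                PrecursorRecord(
                    rec_id, species, TaxonGroup.coerce(taxon), seq,
                    n_complete=n_complete, c_complete=c_complete,
                )
            )
    return DatasetManifest(records=records, metadata_source=str(metadata) if metadata else None)


def write_sequences(manifest: DatasetManifest, path: str | Path) -> None:
    """Write records back to FASTA using the header convention; reinstates
    '...' incompleteness marks so a round-trip is lossless."""
    with open(path, "w") as fh:
        for rec in manifest.records:
            if isinstance(rec, TranscriptRecord):
                seq = rec.sequence
            else:
                seq = rec.residues
                if not rec.n_complete:
                    seq = "..." + seq
                if not rec.c_complete:
                    seq = seq + "..."
            fh.write(f">{rec.id}|{rec.species}|{rec.taxon_group.value}\n{seq}\n")


def _check_spans(annotated: Iterable[AnnotatedPrecursor]) -> None:
    for ann in annotated:
        n = len(ann.record.residues)
        for pep in ann.peptides:
            s, e = pep.span
            if not (1 <= s <= e <= n):
                raise ValueError(
                    f"precursor {ann.id}: peptide span {pep.span} outside length {n}"
                )


def write_annotations(annotated: list[AnnotatedPrecursor], path: str | Path, format: str = "TSV") -> None:
    """Write annotations as TSV (one row per mature peptide) or GFF3
    (sig_peptide / propeptide / mature_peptide features, 1-based inclusive)."""
    _check_spans(annotated)
    fmt = format.upper()
    if fmt == "TSV":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(TSV_COLUMNS)
            for ann in annotated:
                for pep in ann.peptides:
                    writer.writerow([
                        ann.id, ann.family, pep.span[0], pep.span[1],
                        pep.processed, int(pep.amidated), int(pep.pyroglu),
                        pep.copy_index,
                    ])
    elif fmt == "GFF3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for ann in annotated:
                sid = ann.id
                if ann.signal.present:
                    fh.write(
                        f"{sid}\tnpmine\tsig_peptide\t1\t{ann.signal.cleavage_after}"
                        f"\t{ann.signal.score:.3f}\t.\t.\tID={sid}.sig\n"
                    )
                fh.write(
                    f"{sid}\tnpmine\tpropeptide\t1\t{len(ann.record.residues)}"
                    f"\t.\t.\t.\tID={sid}.pro;family={ann.family}\n"
                )
                for pep in ann.peptides:
                    attrs = (
                        f"ID={sid}.pep{pep.copy_index};processed={pep.processed};"
                        f"amidated={int(pep.amidated)};pyroglu={int(pep.pyroglu)}"
                    )
                    fh.write(
                        f"{sid}\tnpmine\tmature_peptide\t{pep.span[0]}\t{pep.span[1]}"
                        f"\t.\t.\t.\t{attrs}\n"
                    )
    else:
        raise ValueError(f"unknown annotation format: {format}")


def read_annotation_spans(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Re-parse mature_peptide spans from a GFF3 file (round-trip checks)."""
    spans: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if cols[2] == "mature_peptide":
                spans.setdefault(cols[0], []).append((int(cols[3]), int(cols[4])))
    return spans
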