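"""End-to-end orchestration: sequences in, annotations and reports out.

Stages: read -> (six-frame translation + ORF selection for nucleotide
input) -> signal-peptide prediction -> cleavage-site calls -> peptide
excision -> family assignment -> splice-variant grouping.  Per-stage record
conservation holds: every input record is either annotated or itemized as a
reject with a reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .annotate import AnnotationConfig, annotate_precursor, group_splice_variants
from .capa_pk import complements_from_annotations, pattern_report, summarize_patterns
from .models import (
    AnnotatedPrecursor,
    FamilyAssignment,
    PrecursorRecord,
    TranscriptRecord,
)
from .orfs import find_orfs
from .registry import FamilyRegistry, load_registry
from .stats import presence_matrix, render_table, summarize_paracopies

log = logging.getLogger("npmine.pipeline")


@dataclass
class PipelineResult:
    annotated: list[AnnotatedPrecursor]
    assignments: list[FamilyAssignment]
    splice_groups: list
    rejects: list[tuple[str, str]]  # (record id, reason)
    stage_counts: dict = field(default_factory=dict)


def precursor_from_transcript(
    transcript: TranscriptRecord,
    registry: FamilyRegistry,
    config: Optional[AnnotationConfig] = None,
    min_orf_len: int = 40,
) -> Optional[tuple[PrecursorRecord, AnnotatedPrecursor]]:
    """Pick the best precursor ORF of a transcript: the candidate whose
    annotation matches the most family-motif peptides (ties to the longer
    protein)."""
    config = config or AnnotationConfig()
    candidates = find_orfs(transcript, min_len=min_orf_len)
    if not candidates:
        return None
    best = None
    best_key = None
    for cand in candidates:
        record = PrecursorRecord(
            id=f"{transcript.id}_p",
            species=transcript.species,
            taxon_group=transcript.taxon_group,
            residues=cand.protein,
            n_complete=cand.has_start,
            c_complete=cand.has_stop,
            source_transcript=transcript.id,
        )
        ann = annotate_precursor(record, registry=registry, config=config)
        key = (len(ann.matched_peptides), len(cand.protein))
        if best_key is None or key > best_key:
            best, best_key = (record, ann), key
    return best


def annotate_dataset(
    records: list,
    registry: Optional[FamilyRegistry] = None,
    config: Optional[AnnotationConfig] = None,
    min_orf_len: int = 40,
) -> PipelineResult:
    registry = registry or load_registry()
    config = config or AnnotationConfig()
    annotated: list[AnnotatedPrecursor] = []
    rejects: list[tuple[str, str]] = []
    n_nt = n_aa = 0
    for rec in records:
        if isinstance(rec, TranscriptRecord):
            n_nt += 1
            picked = precursor_from_transcript(rec, registry, config, min_orf_len)
            if picked is None:
                rejects.append((rec.id, "no ORF above length threshold"))
                log.info("stage=orf record=%s event=rejected", rec.id)
                continue
            _, ann = picked
        else:
            n_aa += 1
            ann = annotate_precursor(rec, registry=registry, config=config)
        annotated.append(ann)
    splice_groups = group_splice_variants(
        annotated, prefix_len=(config.splice_prefix_len if config else 30)
    )
    from .registry import assign_family  # re-run not needed; assignments already set

    assignments = [
        FamilyAssignment(
            precursor_id=a.id,
            family=a.family,
            matched_peptides=a.matched_peptides,
            paracopy_count=a.paracopy_count,
            partial=a.partial,
            species=a.record.species,
            taxon_group=a.record.taxon_group,
        )
        for a in annotated
    ]
    counts = {
        "input": len(records),
        "nucleotide": n_nt,
        "protein": n_aa,
        "annotated": len(annotated),
        "rejected": len(rejects),
        "assigned": sum(1 for a in annotated if a.family != "unassigned"),
        "splice_groups": len(splice_groups),
    }
    assert counts["annotated"] + counts["rejected"] == counts["input"]
    return PipelineResult(
        annotated=annotated,
        assignments=assignments,
        splice_groups=splice_groups,
        rejects=rejects,
        stage_counts=counts,
    )


def report(result: PipelineResult, registry: Optional[FamilyRegistry] = None,
           species_by_taxon: Optional[dict] = None) -> dict:
    """Summary outputs: paracopy table (rendered and raw), presence/absence
    matrix, capa/pk pattern report and per-taxon pattern histograms."""
    registry = registry or load_registry()
    summaries = summarize_paracopies(result.annotated, registry)
    if species_by_taxon is None:
        species_by_taxon = {}
        for a in result.assignments:
            species_by_taxon.setdefault(a.taxon_group.value, set()).add(a.species)
        species_by_taxon = {k: sorted(v) for k, v in species_by_taxon.items()}
    complements = complements_from_annotations(result.annotated, result.splice_groups)
    return {
        "paracopy_summaries": summaries,
        "paracopy_table": render_table(summaries),
        "presence": presence_matrix(result.assignments, species_by_taxon),
        "capa_pk_report": pattern_report(complements),
        "capa_pk_histogram": summarize_patterns(complements),
        "complements": complements,
    }
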