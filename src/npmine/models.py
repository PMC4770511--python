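"""Core domain types shared across the pipeline.

A *precursor* (prepropeptide) is the ribosomally synthesized protein from
which mature neuropeptides are excised: an N-terminal signal peptide, then
one or more peptide paracopies separated by basic prohormone-convertase
cleavage signals, usually followed by a short acidic tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class TaxonGroup(str, Enum):
    PROTURA = "Protura"
    COLLEMBOLA = "Collembola"
    DIPLURA = "Diplura"
    ARCHAEOGNATHA = "Archaeognatha"
    ZYGENTOMA = "Zygentoma"
    REMIPEDIA = "Remipedia"
    MALACOSTRACA = "Malacostraca"
    BRANCHIOPODA = "Branchiopoda"
    CHILOPODA = "Chilopoda"
    SYMPHYLA = "Symphyla"
    DIPLOPODA = "Diplopoda"
    DIPTERA = "Diptera"
    OTHER = "other"

    @classmethod
    def coerce(cls, value: str) -> "TaxonGroup":
        """Map a free-text taxon label onto the enum; unknown labels map to
        ``other`` (never dropped)."""
        if isinstance(value, TaxonGroup):
            return value
        for member in cls:
            if member.value.lower() == str(value).strip().lower():
                return member
        return cls.OTHER


NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}


@dataclass
class TranscriptRecord:
    id: str
    species: str
    taxon_group: TaxonGroup
    sequence: str  # ACGTN

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id}: empty sequence")
        bad = set(self.sequence.upper()) - NT_ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id}: non-nucleotide characters {sorted(bad)}"
            )
        self.sequence = self.sequence.upper()
        self.taxon_group = TaxonGroup.coerce(self.taxon_group)


@dataclass
class PrecursorRecord:
    id: str
    species: str
    taxon_group: TaxonGroup
    residues: str
    n_complete: bool = True
    c_complete: bool = True
    corrected: bool = False
    source_transcript: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"precursor {self.id}: empty sequence")
        bad = set(self.residues.upper()) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"precursor {self.id}: non-amino-acid characters {sorted(bad)}"
            )
        self.residues = self.residues.upper()
        self.taxon_group = TaxonGroup.coerce(self.taxon_group)

    @property
    def is_partial(self) -> bool:
        return not (self.n_complete and self.c_complete)


@dataclass
class SignalPrediction:
    cleavage_after: int  # 1-based index of the last signal-peptide residue
    score: float
    present: bool
    reason: str = ""


@dataclass
class CleavageSite:
    """One candidate convertase cleavage site.

    ``p1_index`` is the 1-based position of the P1 basic residue (the
    C-terminal residue of the cleavage signal).  ``consumed_span`` is the
    1-based inclusive interval of basic residues removed with the signal
    (e.g. both residues of a KR pair).
    """

    p1_index: int
    site_class: str  # KR | RR | KK | RK | mono_R | mono_K
    accepted: bool
    reason: str
    consumed_span: tuple[int, int] = (0, 0)


@dataclass
class MaturePeptide:
    span: tuple[int, int]  # 1-based inclusive on the precursor
    raw: str  # encoded segment (amide Gly still present)
    processed: str  # display form: pQ prefix, trailing "a" for amide
    amidated: bool
    pyroglu: bool
    copy_index: int


@dataclass
class AnnotatedPrecursor:
    record: PrecursorRecord
    signal: SignalPrediction
    sites: list[CleavageSite]
    peptides: list[MaturePeptide]
    family: str = "unassigned"
    matched_peptides: list[tuple[int, str]] = field(default_factory=list)
    paracopy_count: int = 0
    partial: bool = False
    variant_tag: str = ""

    @property
    def id(self) -> str:
        return self.record.id


@dataclass
class SpliceGroup:
    gene_label: str
    variants: list[tuple[str, str]]  # (precursor id, tag a/b/c...)
    shared_prefix_len: int


@dataclass
class FamilyAssignment:
    precursor_id: str
    family: str
    matched_peptides: list[tuple[int, str]]
    paracopy_count: int
    partial: bool = False
    species: str = ""
    taxon_group: TaxonGroup = TaxonGroup.OTHER


@dataclass
class DatasetManifest:
    records: list
    metadata_source: Optional[str] = None
    registry_path: Optional[str] = None
    rejected: list = field(default_factory=list)

    @property
    def alphabet(self) -> str:
        """'nt' if all records are transcripts, 'aa' if all precursors."""
        kinds = {type(r).__name__ for r in self.records}
        if kinds <= {"TranscriptRecord"}:
            return "nt"
        if kinds <= {"PrecursorRecord"}:
            return "aa"
        return "mixed"
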