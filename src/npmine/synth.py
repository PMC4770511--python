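"""Synthetic transcripts/precursors with planted ground truth.

The generator emulates the statistical structure of non-pterygote hexapod
neuropeptide complements so that every pipeline stage is testable without
downloads: precursors carry a signal peptide (planted cleavage at position
15-25), peptide paracopies built from registry exemplars flanked by acidic
spacers, Gly amidation donors and dibasic KR cleavage signals, optional
N-/C-terminal truncation, splice-variant pairs, and per-species capa/pk
complements realizing architecture patterns A-C3.  Spacer/flank residues
are drawn from an alphabet (D/E/N/S/T) that cannot complete any registry
motif or basic cleavage signal, so the planted truth is exact.

Proteins are back-translated with uniform synonymous codon choice; at
mutation rate 0 regeneration from the same seed is byte-identical, and
mutations never touch motif-critical codons (motif spans, amide donors,
cleavage signals, start/stop).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from Bio.Data import CodonTable

from .models import PrecursorRecord, TaxonGroup, TranscriptRecord
from .registry import FamilyRegistry, load_registry

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in _TABLE.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()
_STOP_CODONS = sorted(_TABLE.stop_codons)

SPACER_ALPHABET = "DENST"
CAPA_EXEMPLARS = {"PVK": "ASGLVAFPRV", "tPK": "DGSGLWFGPRL", "PK": "TGPSASSGLFSPRL"}
CAPA_LIGAND_NAME = {"PVK": "PVK", "tPK": "trypto_PK", "PK": "PK"}


@dataclass
class PeptideTruth:
    span: tuple[int, int]  # segment span on the precursor, 1-based inclusive
    family: str
    ligand: Optional[str]
    amidated: bool
    processed: str
    motif_span: tuple[int, int]  # precursor coordinates of the motif match


@dataclass
class SyntheticTruth:
    precursor_id: str
    signal_end: int
    peptides: list[PeptideTruth]
    splice_partner: Optional[str] = None
    planted_artifacts: list = field(default_factory=list)
    taxon_profile: str = ""


@dataclass
class GeneratedPrecursor:
    transcript: TranscriptRecord
    precursor: PrecursorRecord
    truth: SyntheticTruth
    cds_start: int = 0  # 0-based nt offset of the initiator ATG
    protected_nt: set = field(default_factory=set)


def _gen_signal(rng: random.Random) -> str:
    """Signal peptide: Met + charged n-region + hydrophobic h-core + small
    c-region ending in A/S (the -1 position)."""
    n_region = "".join(rng.choice("KR") for _ in range(rng.randint(2, 3)))
    core = "".join(rng.choice("LLVVIF") for _ in range(rng.randint(9, 12)))
    c_len = rng.randint(3, 6)
    c_region = "".join(rng.choice("AST") for _ in range(c_len - 1)) + rng.choice("AS")
    return "M" + n_region + core + c_region


def _flank(rng: random.Random, first: bool) -> str:
    """Acidic spacer preceding a peptide copy; always starts D/E so the
    residue after the signal cleavage breaks the -1/-3 pattern."""
    head = rng.choice("DE")
    tail = "".join(rng.choice(SPACER_ALPHABET) for _ in range(rng.randint(1, 3) if not first else rng.randint(0, 2)))
    return head + tail


def _tail(rng: random.Random) -> str:
    return "".join(rng.choice(SPACER_ALPHABET) for _ in range(rng.randint(4, 8)))


def _processed(body: str, amidated: bool) -> str:
    out = ("pQ" + body[1:]) if body.startswith("Q") else body
    return out + "a" if amidated else out


class _Builder:
    """Accumulates a precursor protein plus planted truth and the protein
    intervals whose codons must never mutate."""

    def __init__(self, rng: random.Random, registry: FamilyRegistry):
        self.rng = rng
        self.registry = registry
        self.protein = ""
        self.signal_end = 0
        self.peptides: list[PeptideTruth] = []
        self.protected: list[tuple[int, int]] = []  # 1-based protein intervals

    def add_signal(self) -> None:
        sig = _gen_signal(self.rng)
        self.protein = sig
        self.signal_end = len(sig)
        self.protected.append((1, 1))  # initiator Met

    def _motif_span_in_body(self, family: str, body: str) -> tuple[int, int]:
        fam = self.registry[family]
        for mot in fam.motifs:
            if mot.anchor == "c_term":
                m = None
                for cand in mot.regex.finditer(body):
                    if cand.end() == len(body):
                        m = cand
            elif mot.anchor in ("n_term", "full"):
                m = mot.regex.match(body)
            else:
                m = mot.regex.search(body)
            if m:
                return m.start() + 1, m.end()
        raise ValueError(f"exemplar for {family} does not match its own motifs: {body}")

    def add_peptide(
        self,
        family: str,
        body: str,
        amidated: bool,
        ligand: Optional[str] = None,
        with_flank: bool = True,
        first: bool = False,
        with_site: bool = True,
    ) -> None:
        flank = _flank(self.rng, first) if with_flank else ""
        seg = flank + body + ("G" if amidated else "")
        start = len(self.protein) + 1
        self.protein += seg
        span = (start, len(self.protein))
        ms, me = self._motif_span_in_body(family, body)
        motif_span = (start + len(flank) + ms - 1, start + len(flank) + me - 1)
        self.protected.append(motif_span)
        if amidated:
            self.protected.append((span[1], span[1]))  # amide donor Gly
        if with_site:
            site_start = len(self.protein) + 1
            self.protein += "KR"
            self.protected.append((site_start, site_start + 1))
        self.peptides.append(
            PeptideTruth(
                span=span,
                family=family,
                ligand=ligand,
                amidated=amidated,
                processed=_processed(flank + body, amidated),
                motif_span=motif_span,
            )
        )

    def add_tail(self, min_total: int = 46) -> None:
        self.protein += _tail(self.rng)
        # short precursors (AKH, EFLa, proctolin...) get a longer acidic
        # tail so every planted CDS clears the ORF-length floor
        while len(self.protein) < min_total:
            self.protein += self.rng.choice(SPACER_ALPHABET)


def _back_translate(protein: str, rng: random.Random) -> str:
    return "".join(rng.choice(_CODONS_FOR[aa]) for aa in protein)


def _assemble(
    builder: _Builder,
    precursor_id: str,
    species: str,
    taxon: TaxonGroup,
    rng: random.Random,
    mutation_rate: float = 0.0,
    profile_name: str = "",
) -> GeneratedPrecursor:
    protein = builder.protein
    cds = _back_translate(protein, rng)
    utr5 = "".join(rng.choice("ACGT") for _ in range(rng.randint(15, 40))) + "TAA"
    utr3 = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 30)))
    stop = rng.choice(_STOP_CODONS)
    nt = utr5 + cds + stop + utr3
    cds_start = len(utr5)

    protected_nt = set(range(cds_start - 3, cds_start + 3))  # guard TAA + ATG
    protected_nt.update(range(cds_start + 3 * len(protein), cds_start + 3 * len(protein) + 3))
    for a, b in builder.protected:
        protected_nt.update(range(cds_start + 3 * (a - 1), cds_start + 3 * b))

    if mutation_rate > 0:
        # substitutions are missense-only: premature stops are a distinct,
        # explicitly planted lesion kind (corrupt(kind="in_frame_stop")),
        # so the substitution channel never creates one by accident
        cds_end = cds_start + 3 * len(protein)
        bases = list(nt)
        for i in range(len(bases)):
            if i in protected_nt or rng.random() >= mutation_rate:
                continue
            options = [b for b in "ACGT" if b != bases[i]]
            rng.shuffle(options)
            for b in options:
                if cds_start <= i < cds_end:
                    c0 = cds_start + 3 * ((i - cds_start) // 3)
                    codon = "".join(bases[c0:c0 + 3])
                    codon = codon[:i - c0] + b + codon[i - c0 + 1:]
                    if codon in _STOP_CODONS:
                        continue
                bases[i] = b
                break
        nt = "".join(bases)

    transcript = TranscriptRecord(f"{precursor_id}_t", species, taxon, nt)
    precursor = PrecursorRecord(
        precursor_id, species, taxon, protein, source_transcript=transcript.id
    )
    truth = SyntheticTruth(
        precursor_id=precursor_id,
        signal_end=builder.signal_end,
        peptides=builder.peptides,
        taxon_profile=profile_name,
    )
    return GeneratedPrecursor(
        transcript=transcript,
        precursor=precursor,
        truth=truth,
        cds_start=cds_start,
        protected_nt=protected_nt,
    )


def gen_precursor(
    family: str,
    n_copies: int,
    seed: int,
    mutation_rate: float = 0.0,
    registry: Optional[FamilyRegistry] = None,
    species: str = "Synthetica exempli",
    taxon: TaxonGroup = TaxonGroup.OTHER,
    precursor_id: Optional[str] = None,
) -> GeneratedPrecursor:
    """One synthetic precursor for ``family`` with ``n_copies`` paracopies
    (forced to 1 for single-copy families).  Same seed, same output."""
    registry = registry or load_registry()
    if family not in registry:
        raise KeyError(f"unknown family: {family}")
    if not 0 <= mutation_rate <= 0.2:
        raise ValueError("mutation_rate must be in [0, 0.2]")
    fam = registry[family]
    if fam.copy_class == "single":
        n_copies = 1
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = random.Random(f"gen:{family}:{n_copies}:{seed}")
    builder = _Builder(rng, registry)
    builder.add_signal()
    amidated = fam.motifs[0].amidated
    anchored_start = any(m.anchor in ("n_term", "full") for m in fam.motifs)
    for k in range(n_copies):
        body = fam.exemplars[k % len(fam.exemplars)]
        builder.add_peptide(
            family,
            body,
            amidated,
            with_flank=(fam.copy_class == "multiple") and not anchored_start,
            first=(k == 0),
        )
    builder.add_tail()
    pid = precursor_id or f"syn_{family.replace('/', '_')}_{seed}"
    return _assemble(builder, pid, species, taxon, rng, mutation_rate)


def gen_capa_precursor(
    composition: dict[str, int],
    seed: int,
    registry: Optional[FamilyRegistry] = None,
    species: str = "Synthetica exempli",
    taxon: TaxonGroup = TaxonGroup.OTHER,
    precursor_id: str = "syn_capa",
    splice_b1: bool = False,
    mutation_rate: float = 0.0,
) -> list[GeneratedPrecursor]:
    """A capa/pk-complex precursor with the given ligand composition, e.g.
    ``{"PVK": 4, "tPK": 1, "PK": 3}`` (segment order PVK, trypto-PK, PK).
    With ``splice_b1`` a second transcript truncated after the trypto-PK
    block (the pattern-B1 splice variant) is emitted as well."""
    registry = registry or load_registry()
    rng = random.Random(f"capa:{precursor_id}:{seed}")
    builder = _Builder(rng, registry)
    builder.add_signal()
    first = True
    cut_after = None
    for ligand in ("PVK", "tPK", "PK"):
        for _ in range(composition.get(ligand, 0)):
            family = "CAPA" if ligand in ("PVK", "tPK") else "PK/PBAN"
            builder.add_peptide(
                family,
                CAPA_EXEMPLARS[ligand],
                amidated=True,
                ligand=CAPA_LIGAND_NAME[ligand],
                first=first,
            )
            first = False
        if ligand == "tPK":
            cut_after = len(builder.protein)  # end of trypto-PK block (incl. site)
    builder.add_tail()
    out = [_assemble(builder, precursor_id, species, taxon, rng, mutation_rate)]

    if splice_b1:
        vid = precursor_id + "v2"
        vrng = random.Random(f"capa-b1:{precursor_id}:{seed}")
        vbuilder = _Builder(vrng, registry)
        vbuilder.protein = builder.protein[:cut_after]
        vbuilder.signal_end = builder.signal_end
        vbuilder.peptides = [p for p in builder.peptides if p.span[1] <= cut_after]
        vbuilder.protected = [iv for iv in builder.protected if iv[1] <= cut_after]
        vbuilder.protein += "".join(vrng.choice("ANST") for _ in range(10))
        variant = _assemble(vbuilder, vid, species, taxon, vrng, mutation_rate)
        out[0].truth.splice_partner = vid
        variant.truth.splice_partner = precursor_id
        out.append(variant)
    return out


def gen_splice_pair(
    family: str,
    seed: int,
    registry: Optional[FamilyRegistry] = None,
    species: str = "Synthetica exempli",
    taxon: TaxonGroup = TaxonGroup.OTHER,
    id_prefix: str = "syn",
    n_copies: int = 1,
    mutation_rate: float = 0.0,
) -> list[GeneratedPrecursor]:
    """An a/b splice-variant pair: identical through the signal peptide and
    first peptide block, divergent tails (the ITP/ITPL, orcokinin A/B
    situation)."""
    registry = registry or load_registry()
    fam = registry[family]
    base_id = f"{id_prefix}_{family.replace('/', '_')}"
    a = gen_precursor(
        family, max(n_copies, 1), seed, mutation_rate, registry,
        species=species, taxon=taxon, precursor_id=base_id + "a",
    )
    cut = a.truth.peptides[0].span[1] + 2  # through the first cleavage site
    brng = random.Random(f"splice-b:{base_id}:{seed}")
    bbuilder = _Builder(brng, registry)
    bbuilder.protein = a.precursor.residues[:cut]
    bbuilder.signal_end = a.truth.signal_end
    bbuilder.peptides = [p for p in a.truth.peptides if p.span[1] <= cut]
    bbuilder.protected = [(1, 1)] + [p.motif_span for p in bbuilder.peptides]
    alt_tail = "".join(brng.choice("ANSTQ") for _ in range(14))
    bbuilder.protein += alt_tail
    b = _assemble(bbuilder, base_id + "b", species, taxon, brng, mutation_rate)
    a.truth.splice_partner = b.truth.precursor_id
    b.truth.splice_partner = a.truth.precursor_id
    return [a, b]


def corrupt(
    bundle: GeneratedPrecursor,
    kind: str,
    seed: int,
    keep_copies: Optional[int] = None,
) -> GeneratedPrecursor:
    """Plant exactly one lesion in a generated transcript.

    in_frame_stop: a stop codon replacing a motif-internal codon;
    frameshift: a single-nt deletion in the spacer just upstream of a
    peptide motif; truncate_5p/truncate_3p: cut the transcript so the
    encoded precursor loses its N-/C-terminus (truncate_3p keeps
    ``keep_copies`` peptide copies).  The input bundle is not modified.
    """
    rng = random.Random(f"corrupt:{bundle.truth.precursor_id}:{kind}:{seed}")
    nt = bundle.transcript.sequence
    cds = bundle.cds_start
    truth = bundle.truth
    if not truth.peptides:
        raise ValueError("bundle has no planted peptides")

    def codon_start(protein_pos: int) -> int:  # 1-based aa -> 0-based nt
        return cds + 3 * (protein_pos - 1)

    if kind == "in_frame_stop":
        pep = truth.peptides[rng.randrange(len(truth.peptides))]
        ms, me = pep.motif_span
        target = (ms + me) // 2
        pos = codon_start(target)
        new_nt = nt[:pos] + "TAA" + nt[pos + 3:]
        planted = ("in_frame_stop", pos + 1)
    elif kind == "frameshift":
        pep = truth.peptides[rng.randrange(len(truth.peptides))]
        pos = codon_start(pep.span[0]) - 5  # inside the preceding site/spacer codons
        new_nt = nt[:pos] + nt[pos + 1:]
        planted = ("frameshift", pos + 1)
    elif kind == "truncate_5p":
        cut = codon_start(truth.signal_end // 2)
        new_nt = nt[cut:]
        planted = ("truncate_5p", cut + 1)
    elif kind == "truncate_3p":
        keep = keep_copies if keep_copies is not None else max(1, len(truth.peptides) // 2)
        pep = truth.peptides[keep - 1]
        cut = codon_start(pep.span[1] + 2) + 3  # end of the site after copy ``keep``
        new_nt = nt[:cut]
        planted = ("truncate_3p", cut)
    else:
        raise ValueError(f"unknown lesion kind: {kind}")

    transcript = TranscriptRecord(
        bundle.transcript.id, bundle.transcript.species,
        bundle.transcript.taxon_group, new_nt,
    )
    precursor = bundle.precursor
    if kind == "truncate_3p":
        visible_end = pep.span[1] + 2
        precursor = PrecursorRecord(
            precursor.id, precursor.species, precursor.taxon_group,
            precursor.residues[:visible_end], c_complete=False,
            source_transcript=transcript.id,
        )
    elif kind == "truncate_5p":
        lost = truth.signal_end // 2
        precursor = PrecursorRecord(
            precursor.id, precursor.species, precursor.taxon_group,
            precursor.residues[lost:], n_complete=False,
            source_transcript=transcript.id,
        )
    new_truth = SyntheticTruth(
        precursor_id=truth.precursor_id,
        signal_end=truth.signal_end,
        peptides=list(truth.peptides),
        splice_partner=truth.splice_partner,
        planted_artifacts=truth.planted_artifacts + [planted],
        taxon_profile=truth.taxon_profile,
    )
    return GeneratedPrecursor(
        transcript=transcript,
        precursor=precursor,
        truth=new_truth,
        cds_start=bundle.cds_start if kind != "truncate_5p" else 0,
        protected_nt=set(),
    )


# ---------------------------------------------------------------------------
# Taxon profiles: copy numbers, presence/absence and capa/pk patterns
# emulating the published non-pterygote hexapod complements.

@dataclass
class TaxonProfile:
    name: str
    taxon: TaxonGroup
    n_species: int
    multi_counts: dict[str, list[int]]
    capa_pk: list[dict]
    single_families: tuple[str, ...] = (
        "CCAP", "MS", "AKH", "corazonin", "SIFa", "NPF", "AST-C", "proctolin",
        "inotocin", "PDF", "elevenin", "CNMa",
    )
    absent: tuple[str, ...] = ()
    splice_families: tuple[str, ...] = ("ITP",)
    partial_counts: dict[str, int] = field(default_factory=dict)


PROFILES: dict[str, TaxonProfile] = {
    "Protura": TaxonProfile(
        name="Protura",
        taxon=TaxonGroup.PROTURA,
        n_species=3,
        multi_counts={
            "AST-A": [13, 14, 15],
            "MIP": [8, 10],
            "FMRFa": [2, 2, 2],
            "TKRP": [5, 5, 5],
            "natalisin": [6, 6, 6],
            "kinin": [6, 7],
            "RYa": [1, 1, 2],
            "ETH": [2, 2, 2],
            "SK": [2, 2, 2],
        },
        partial_counts={"EFLa": 18},
        capa_pk=[{"pattern": "B", "capa": {"PVK": 4, "tPK": 1, "PK": 3}}],
        absent=("PDF", "CNMa"),
        splice_families=("ITP",),
    ),
    "Collembola": TaxonProfile(
        name="Collembola",
        taxon=TaxonGroup.COLLEMBOLA,
        n_species=9,
        multi_counts={
            "AST-A": [3, 3, 4, 4, 4, 4, 5, 5, 6],
            "MIP": [4, 4, 5, 5, 5, 6, 6, 6, 7],
            "FMRFa": [3] * 9,
            "TKRP": [3, 4, 4, 3, 4, 4, 3, 4, 4],
            "natalisin": [2],
            "EFLa": [4, 4, 5, 5],
            "kinin": [1, 1, 5, 6, 7],
            "RYa": [2] * 9,
            "ETH": [1] * 9,
            "SK": [2, 2, 2, 2, 2, 2, 2, 2, 3],
        },
        capa_pk=[
            {"pattern": "B1", "capa": {"PVK": 3, "tPK": 1, "PK": 2}},
            {"pattern": "B", "capa": {"PVK": 3, "tPK": 1, "PK": 3}},
            {"pattern": "B", "capa": {"PVK": 3, "tPK": 1, "PK": 3}},
            {"pattern": "B1", "capa": {"PVK": 3, "tPK": 1, "PK": 3}},
            {"pattern": "B", "capa": {"PVK": 3, "tPK": 1, "PK": 4}},
            {"pattern": "B", "capa": {"PVK": 3, "tPK": 1, "PK": 4}},
            {"pattern": "B1", "capa": {"PVK": 3, "tPK": 1, "PK": 4}},
            {"pattern": "B", "capa": {"PVK": 3, "tPK": 1, "PK": 6}},
            {"pattern": "B1", "capa": {"PVK": 3, "tPK": 1, "PK": 3}},
        ],
        absent=("elevenin", "CNMa"),
        splice_families=("ITP", "orcokinin"),
    ),
    "Diplura": TaxonProfile(
        name="Diplura",
        taxon=TaxonGroup.DIPLURA,
        n_species=4,
        multi_counts={
            "AST-A": [12, 12, 13, 13],
            "MIP": [11, 11, 11, 11],
            "FMRFa": [4, 4, 4, 4],
            "TKRP": [4, 4, 4, 4],
            "natalisin": [3],
            "EFLa": [6, 8, 10, 12],
            "kinin": [5],
            "RYa": [3, 3, 3, 3],
            "ETH": [2, 2, 2, 2],
            "SK": [2, 2, 2, 2],
        },
        capa_pk=[
            {"pattern": "C1", "capa": {"PVK": 3, "tPK": 1}, "pk": {"PK": 4}},
            {"pattern": "C1", "capa": {"PVK": 3, "tPK": 1}, "pk": {"PK": 4}},
            {"pattern": "C1", "capa": {"PVK": 4, "tPK": 1}, "pk": {"PK": 5}},
            {"pattern": "C1", "capa": {"PVK": 4, "tPK": 1}, "pk": {"PK": 5}},
        ],
        absent=("PDF",),
        splice_families=("ITP",),
    ),
    "Archaeognatha": TaxonProfile(
        name="Archaeognatha",
        taxon=TaxonGroup.ARCHAEOGNATHA,
        n_species=4,
        multi_counts={
            "AST-A": [13, 16, 17],
            "MIP": [9, 9, 10, 10],
            "FMRFa": [6, 7, 8],
            "TKRP": [4, 4, 4],
            "EFLa": [12],
            "RYa": [3, 3, 3, 3],
            "ETH": [2, 2, 2, 2],
            "SK": [2, 2, 2, 2],
        },
        partial_counts={"natalisin": 10, "kinin": 20},
        capa_pk=[
            {"pattern": "B", "capa": {"PVK": 4, "tPK": 1, "PK": 3}},
            {"pattern": "B", "capa": {"PVK": 4, "tPK": 1, "PK": 4}},
            {"pattern": "B", "capa": {"PVK": 4, "tPK": 1, "PK": 4}},
            {"pattern": "PVK_only", "capa": {"PVK": 4}},
        ],
        splice_families=("ITP", "orcokinin"),
    ),
    "Zygentoma": TaxonProfile(
        name="Zygentoma",
        taxon=TaxonGroup.ZYGENTOMA,
        n_species=4,
        multi_counts={
            "AST-A": [14, 17, 19, 22],
            "MIP": [11, 12, 12, 14],
            "FMRFa": [7, 10, 12, 14, 15],
            "TKRP": [9, 9],
            "EFLa": [17, 17, 18, 18],
            "RYa": [3, 3, 3, 3],
            "ETH": [2],
            "SK": [2, 2, 2, 2],
        },
        partial_counts={"natalisin": 9, "kinin": 19},
        capa_pk=[
            {"pattern": "C2", "capa": {"PVK": 2, "tPK": 2}, "pk": {"tPK": 2, "PK": 2}},
            {"pattern": "C2", "capa": {"PVK": 2, "tPK": 2}, "pk": {"tPK": 2, "PK": 2}},
            {"pattern": "C2", "capa": {"PVK": 4, "tPK": 2}, "pk": {"tPK": 1, "PK": 2}},
            {"pattern": "C3", "capa": {"PVK": 4, "tPK": 1, "PK": 1}, "pk": {"tPK": 2, "PK": 2}},
        ],
        splice_families=("ITP", "orcokinin"),
    ),
}


@dataclass
class Panel:
    profile: TaxonProfile
    bundles: list[GeneratedPrecursor]
    species: list[str]
    planted_patterns: dict[str, str]  # species -> capa/pk pattern

    @property
    def transcripts(self) -> list[TranscriptRecord]:
        return [b.transcript for b in self.bundles]

    @property
    def precursors(self) -> list[PrecursorRecord]:
        return [b.precursor for b in self.bundles]


def gen_taxon_panel(
    profile: TaxonProfile,
    n_species: Optional[int] = None,
    seed: int = 0,
    registry: Optional[FamilyRegistry] = None,
    mutation_rate: float = 0.0,
) -> Panel:
    """A per-species precursor panel realizing the profile: multi-copy
    counts distributed round-robin across species (extra counts become
    same-species gene duplicates), capa/pk complements realizing the
    planted patterns, splice pairs, deliberate family absences, and
    truncated partial precursors for families without full-length
    evidence."""
    registry = registry or load_registry()
    n_species = n_species or profile.n_species
    species = [f"{profile.name} sp{i + 1}" for i in range(n_species)]
    bundles: list[GeneratedPrecursor] = []
    planted_patterns: dict[str, str] = {}

    for fam, counts in sorted(profile.multi_counts.items()):
        for k, count in enumerate(counts):
            sp_idx = k % n_species
            pid = f"{profile.name.lower()}{sp_idx + 1}_{fam.replace('/', '_')}_{k}"
            bundles.append(
                gen_precursor(
                    fam, count, seed * 1000 + k, mutation_rate, registry,
                    species=species[sp_idx], taxon=profile.taxon, precursor_id=pid,
                )
            )

    for fam, visible in sorted(profile.partial_counts.items()):
        pid = f"{profile.name.lower()}1_{fam.replace('/', '_')}_part"
        whole = gen_precursor(
            fam, visible, seed * 1000 + 77, mutation_rate, registry,
            species=species[0], taxon=profile.taxon, precursor_id=pid,
        )
        bundles.append(corrupt(whole, "truncate_3p", seed, keep_copies=visible))

    for fam in sorted(profile.single_families):
        if fam in profile.absent:
            continue
        for sp_idx in range(n_species):
            pid = f"{profile.name.lower()}{sp_idx + 1}_{fam.replace('/', '_')}"
            bundles.append(
                gen_precursor(
                    fam, 1, seed * 1000 + sp_idx, mutation_rate, registry,
                    species=species[sp_idx], taxon=profile.taxon, precursor_id=pid,
                )
            )

    for fam in sorted(profile.splice_families):
        for sp_idx in range(n_species):
            bundles.extend(
                gen_splice_pair(
                    fam, seed * 1000 + sp_idx, registry,
                    species=species[sp_idx], taxon=profile.taxon,
                    id_prefix=f"{profile.name.lower()}{sp_idx + 1}",
                    n_copies=3 if registry[fam].copy_class == "multiple" else 1,
                    mutation_rate=mutation_rate,
                )
            )

    for sp_idx in range(n_species):
        plan = profile.capa_pk[sp_idx % len(profile.capa_pk)]
        pattern = plan["pattern"]
        planted_patterns[species[sp_idx]] = pattern if pattern in ("A", "B", "B1", "C1", "C2", "C3") else "unresolved"
        base = f"{profile.name.lower()}{sp_idx + 1}"
        if pattern in ("A", "B", "B1", "PVK_only"):
            bundles.extend(
                gen_capa_precursor(
                    plan["capa"], seed * 1000 + sp_idx, registry,
                    species=species[sp_idx], taxon=profile.taxon,
                    precursor_id=f"{base}_capa",
                    splice_b1=(pattern == "B1"),
                    mutation_rate=mutation_rate,
                )
            )
        else:  # two-gene C patterns
            bundles.extend(
                gen_capa_precursor(
                    plan["capa"], seed * 1000 + sp_idx, registry,
                    species=species[sp_idx], taxon=profile.taxon,
                    precursor_id=f"{base}_capa", mutation_rate=mutation_rate,
                )
            )
            bundles.extend(
                gen_capa_precursor(
                    plan["pk"], seed * 2000 + sp_idx, registry,
                    species=species[sp_idx], taxon=profile.taxon,
                    precursor_id=f"{base}_pk", mutation_rate=mutation_rate,
                )
            )

    for b in bundles:
        b.truth.taxon_profile = profile.name
    return Panel(
        profile=profile, bundles=bundles, species=species,
        planted_patterns=planted_patterns,
    )


def write_panel(panel: Panel, fasta_path, metadata_path=None, truth_path=None, kind: str = "nt") -> None:
    """Write a panel as FASTA (+ optional metadata TSV and truth TSV)."""
    with open(fasta_path, "w") as fh:
        for b in panel.bundles:
            if kind == "nt":
                rec = b.transcript
                seq = rec.sequence
            else:
                rec = b.precursor
                seq = rec.residues
            fh.write(f">{rec.id}|{rec.species}|{rec.taxon_group.value}\n{seq}\n")
    if metadata_path:
        with open(metadata_path, "w") as fh:
            fh.write("id\tspecies\ttaxon_group\n")
            for b in panel.bundles:
                rec = b.transcript if kind == "nt" else b.precursor
                fh.write(f"{rec.id}\t{rec.species}\t{rec.taxon_group.value}\n")
    if truth_path:
        with open(truth_path, "w") as fh:
            fh.write("precursor_id\tsignal_end\tfamily\tligand\tspan_start\tspan_end\tprocessed\n")
            for b in panel.bundles:
                for p in b.truth.peptides:
                    fh.write(
                        f"{b.truth.precursor_id}\t{b.truth.signal_end}\t{p.family}\t"
                        f"{p.ligand or ''}\t{p.span[0]}\t{p.span[1]}\t{p.processed}\n"
                    )
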