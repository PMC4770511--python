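"""Precursor annotation: signal peptide, convertase cleavage sites, mature
peptide excision (amidation / pyroGlu) and splice-variant grouping.

Cleavage-site calls follow the classical prohormone-convertase criteria
(Veenstra 2000, Arch Insect Biochem Physiol 43:49): dibasic sites (KR, RR,
and with reduced confidence KK/RK) are cleaved; a single Arg is cleaved only
when another basic residue sits at P4, P6 or P8; a single Lys is not
cleaved; Pro at P1' blocks cleavage, as does a Cys within two residues
downstream (disulfide protection).  All candidate basic positions are
returned with their accept/reject decision and reason, so every manual-style
call is auditable.

Signal peptides are scored with a transparent von Heijne-style heuristic
(charged n-region, hydrophobic h-core, small residues at the -3/-1
positions), not a neural network; precomputed external predictions can be
supplied via a TSV adapter instead.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from typing import Optional

from .models import (
    AnnotatedPrecursor,
    CleavageSite,
    MaturePeptide,
    PrecursorRecord,
    SignalPrediction,
    SpliceGroup,
)

# Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

SMALL_RESIDUES = set("AGSCTV")  # tolerated at -3
SMALL_M1 = set("AGS")  # tolerated at -1
BASIC = set("KR")

SIGNAL_MIN_CLEAVAGE = 10
SIGNAL_MAX_CLEAVAGE = 45
HCORE_WINDOW = 8


@dataclass
class AnnotationConfig:
    signal_threshold: float = 3.5
    allow_KK: bool = True
    allow_RK: bool = True
    mono_r_basic_positions: tuple[int, ...] = (4, 6, 8)
    splice_prefix_len: int = 30
    min_peptide_len: int = 3


def predict_signal_peptide(
    precursor: PrecursorRecord, threshold: float = 3.5
) -> SignalPrediction:
    """Scan cleavage positions 10-45 and score each as the last residue of a
    putative signal peptide.

    Per-position score = capped net positive charge of the n-region
    (residues 1-5) + best mean Kyte-Doolittle hydropathy over an 8-residue
    h-core window ending close to the cleavage point + a bonus for small
    residues at the -3/-1 positions - a penalty for charged residues in the
    c-region.  Ties go to the most C-terminal position.
    """
    if not precursor.n_complete:
        return SignalPrediction(0, 0.0, False, "N-terminally incomplete")
    seq = precursor.residues
    if len(seq) < 25:
        return SignalPrediction(0, 0.0, False, "too short")

    charge = sum(
        (1 if aa in BASIC else -1 if aa in "DE" else 0) for aa in seq[:5]
    )
    charge = max(0, min(2, charge))

    best_p, best_score = 0, float("-inf")
    p_hi = min(SIGNAL_MAX_CLEAVAGE, len(seq) - 1)
    for p in range(max(SIGNAL_MIN_CLEAVAGE, HCORE_WINDOW + 5), p_hi + 1):
        # best h-core window (8-mers within residues 2..p-3, ending near p)
        lo_end = max(HCORE_WINDOW + 1, p - 9)  # 1-based window end
        hi_end = p - 3
        if hi_end < lo_end:
            continue
        hydro = max(
            sum(KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq[end - HCORE_WINDOW:end]) / HCORE_WINDOW
            for end in range(lo_end, hi_end + 1)
        )
        bonus = 1.0 if (seq[p - 1] in SMALL_M1 and seq[p - 3] in SMALL_RESIDUES) else 0.0
        c_penalty = 0.7 * sum(1 for aa in seq[max(0, p - 5):p] if aa in "DEKR")
        score = charge + hydro + bonus - c_penalty
        if score >= best_score:  # >= : ties resolved toward larger p
            best_p, best_score = p, score
    if best_p == 0:
        return SignalPrediction(0, 0.0, False, "no candidate position")
    present = best_score >= threshold
    return SignalPrediction(
        best_p, best_score, present, "" if present else "below threshold"
    )


def read_external_signal_predictions(path) -> dict[str, SignalPrediction]:
    """Adapter for precomputed signal predictions (TSV: id, cleavage_after,
    score)."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            ca = int(row["cleavage_after"])
            out[row["id"]] = SignalPrediction(ca, float(row["score"]), ca > 0)
    return out


def _site_decision(
    seq: str,
    i: int,  # 0-based index of the candidate P1 basic residue
    signal_end: int,  # 1-based last signal residue (0 if absent)
    config: AnnotationConfig,
) -> tuple[str, bool, str]:
    """Rule-table decision for one candidate basic residue.  Returns
    (site_class, accepted, reason)."""
    aa = seq[i]
    prev = seq[i - 1] if i > 0 else ""
    if prev in BASIC:
        site_class = prev + aa  # KR / RR / KK / RK
    else:
        site_class = "mono_R" if aa == "R" else "mono_K"

    p1 = i + 1  # 1-based
    if p1 <= signal_end:
        return site_class, False, "within signal peptide"
    p1p = seq[i + 1] if i + 1 < len(seq) else ""
    p2p = seq[i + 2] if i + 2 < len(seq) else ""
    if p1p == "P":
        return site_class, False, "proline at P1'"
    if p1p == "C" or p2p == "C":
        return site_class, False, "cysteine within 2 residues downstream"

    if site_class in ("KR", "RR"):
        return site_class, True, "dibasic"
    if site_class == "KK":
        if config.allow_KK:
            return site_class, True, "dibasic KK (reduced confidence)"
        return site_class, False, "KK disabled"
    if site_class == "RK":
        if config.allow_RK:
            return site_class, True, "dibasic RK (reduced confidence)"
        return site_class, False, "RK disabled"
    if site_class == "mono_R":
        for off in config.mono_r_basic_positions:
            j = i - (off - 1)
            if j >= 0 and seq[j] in BASIC:
                return site_class, True, f"mono-R with basic at P{off}"
        return site_class, False, "mono-R without upstream basic at P4/P6/P8"
    return site_class, False, "mono-K not cleaved"


def predict_cleavage_sites(
    precursor: PrecursorRecord,
    signal: SignalPrediction,
    config: Optional[AnnotationConfig] = None,
    registry=None,
) -> list[CleavageSite]:
    """All candidate basic positions with accept/reject decisions.

    Post-processing: within a run of adjacent basic residues only the most
    C-terminal accepted candidate is kept (the true P1); when a registry is
    supplied, accepted sites falling inside a family-motif match are
    rejected (single interior basics of a motif-matched peptide, e.g. in
    kinins or SIFamide, are not processing signals).
    """
    config = config or AnnotationConfig()
    seq = precursor.residues
    signal_end = signal.cleavage_after if signal.present else 0
    sites: list[CleavageSite] = []
    for i, aa in enumerate(seq):
        if aa not in BASIC:
            continue
        site_class, accepted, reason = _site_decision(seq, i, signal_end, config)
        sites.append(CleavageSite(i + 1, site_class, accepted, reason))

    # collapse basic runs: keep only the last accepted candidate of each run
    for a, b in itertools.pairwise(sites):
        if b.p1_index == a.p1_index + 1 and a.accepted and b.accepted:
            a.accepted = False
            a.reason = "internal to basic signal run"

    # motif protection
    if registry is not None:
        spans = []
        for fam, mot_id, rx in registry.unanchored_patterns():
            for m in rx.finditer(seq):
                spans.append((m.start() + 1, m.end(), fam, mot_id))
        for site in sites:
            if not site.accepted:
                continue
            for s, e, fam, mot_id in spans:
                if s <= site.p1_index <= e:
                    site.accepted = False
                    site.reason = f"inside motif-matched peptide ({fam}:{mot_id})"
                    break

    # consumed spans for accepted sites: maximal adjacent basic run ending at
    # P1 (capped at 4); a furin-like R-X-(K/R)-R signal extends to P4.
    # Spans are clipped against the previous accepted site so the partition
    # stays consistent.
    prev_end = 0
    for site in sites:
        if not site.accepted:
            continue
        start = site.p1_index
        while start > 1 and seq[start - 2] in BASIC and site.p1_index - start < 3:
            start -= 1
        if (
            site.p1_index - start == 1
            and site.p1_index >= 4
            and seq[site.p1_index - 4] == "R"
            and seq[site.p1_index - 3] != "G"  # Gly at P3 is an amide donor, not furin X
            and seq[site.p1_index - 1] in BASIC
        ):
            start = site.p1_index - 3  # R-X-K/R-R furin signal
        start = max(start, prev_end + 1)
        site.consumed_span = (start, site.p1_index)
        prev_end = site.p1_index
    return sites


def excise_peptides(
    precursor: PrecursorRecord,
    signal: SignalPrediction,
    sites: list[CleavageSite],
) -> list[MaturePeptide]:
    """Partition the precursor at the accepted sites into mature peptides.

    The P1 basic residue and any adjacent basics are consumed as cleavage
    signal, not peptide.  A segment ending in Gly immediately before a site
    (or before the precursor C-terminus of a complete sequence) is amidated;
    the Gly is dropped from the processed display form.  An N-terminal Gln
    is marked pyroGlu and displayed as pQ.  Concatenating the signal
    peptide, raw segments and consumed cleavage residues reconstructs the
    precursor exactly.
    """
    seq = precursor.residues
    accepted = [s for s in sites if s.accepted]
    for a, b in itertools.pairwise(accepted):
        if b.consumed_span[0] <= a.consumed_span[1]:
            raise ValueError(
                f"precursor {precursor.id}: overlapping cleavage sites at "
                f"{a.p1_index} and {b.p1_index}"
            )

    peptides: list[MaturePeptide] = []
    start = (signal.cleavage_after + 1) if signal.present else 1
    copy_index = 0
    bounds = [(s.consumed_span[0], s.consumed_span[1], True) for s in accepted]
    bounds.append((len(seq) + 1, len(seq) + 1, False))
    for cs, ce, is_site in bounds:
        if cs < start:
            raise ValueError(
                f"precursor {precursor.id}: cleavage site at {cs} out of order"
            )
        raw = seq[start - 1:cs - 1]
        span = (start, cs - 1)
        start = ce + 1
        if not raw:
            continue
        copy_index += 1
        amidated = raw.endswith("G") and (
            is_site or (precursor.c_complete and cs == len(seq) + 1)
        )
        body = raw[:-1] if amidated else raw
        pyroglu = body.startswith("Q")
        processed = ("pQ" + body[1:]) if pyroglu else body
        if amidated:
            processed += "a"
        peptides.append(
            MaturePeptide(
                span=span,
                raw=raw,
                processed=processed,
                amidated=amidated,
                pyroglu=pyroglu,
                copy_index=copy_index,
            )
        )
    return peptides


def annotate_precursor(
    record: PrecursorRecord,
    registry=None,
    config: Optional[AnnotationConfig] = None,
    signal: Optional[SignalPrediction] = None,
) -> AnnotatedPrecursor:
    """Full single-precursor annotation: signal -> cleavage -> excision ->
    family assignment (when a registry is given)."""
    config = config or AnnotationConfig()
    if signal is None:
        signal = predict_signal_peptide(record, config.signal_threshold)
    sites = predict_cleavage_sites(record, signal, config, registry=registry)
    peptides = excise_peptides(record, signal, sites)
    ann = AnnotatedPrecursor(record=record, signal=signal, sites=sites, peptides=peptides)
    if registry is not None:
        from .registry import assign_family

        assign_family(ann, registry)
    return ann


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def group_splice_variants(
    annotated: list[AnnotatedPrecursor], prefix_len: int = 30
) -> list[SpliceGroup]:
    """Group same-species precursors sharing an identical N-terminal prefix
    (>= prefix_len residues, covering the signal peptide) but divergent
    tails — the ITP/ITPL and orcokinin A/B situation.  Exact full-length
    duplicates collapse; a sequence that is a strict prefix of another is
    treated as a truncation, not a splice variant."""
    by_species: dict[str, list[AnnotatedPrecursor]] = {}
    seen_seqs: dict[tuple[str, str], str] = {}
    for ann in annotated:
        key = (ann.record.species, ann.record.residues)
        if key in seen_seqs:
            continue  # exact duplicate: deduplicated, never grouped
        seen_seqs[key] = ann.id
        by_species.setdefault(ann.record.species, []).append(ann)

    groups: list[SpliceGroup] = []
    for species, anns in by_species.items():
        unassigned = list(anns)
        while unassigned:
            seedling = unassigned.pop(0)
            members = [seedling]
            rest = []
            for other in unassigned:
                cpl = _common_prefix_len(seedling.record.residues, other.record.residues)
                is_prefix = cpl == min(
                    len(seedling.record.residues), len(other.record.residues)
                )
                if cpl >= prefix_len and not is_prefix:
                    members.append(other)
                else:
                    rest.append(other)
            unassigned = rest
            if len(members) < 2:
                continue
            members.sort(key=lambda a: (-len(a.record.residues), a.id))
            shared = min(
                _common_prefix_len(members[0].record.residues, m.record.residues)
                for m in members[1:]
            )
            variants = []
            for tag, member in zip("abcdefgh", members):
                member.variant_tag = tag
                variants.append((member.id, tag))
            label = f"{species}|{members[0].family}" if members[0].family != "unassigned" else f"{species}|{members[0].id}"
            groups.append(SpliceGroup(gene_label=label, variants=variants, shared_prefix_len=shared))
    return groups
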