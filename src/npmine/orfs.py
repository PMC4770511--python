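"""Six-frame translation, ORF extraction and sequencing-artifact flags.

Candidate precursors are obtained by translating each transcript in all six
frames and extracting Met-initiated, stop-terminated ORFs plus edge-truncated
ORFs (running off a transcript end without start and/or stop), so that
incomplete precursors remain representable.  Artifact flags mark likely
assembly/sequencing errors: an in-frame stop interrupting a region that would
match a family motif were the stop masked, and a suspected frameshift where a
family motif is completed in a different frame close to the breakpoint.
Flags are advisory; they never mutate the stored input sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .models import TranscriptRecord

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)

FRAMES = (1, 2, 3, -1, -2, -3)


def _translate_codon(codon: str) -> str:
    if codon in _FORWARD:
        return _FORWARD[codon]
    if codon in _STOPS:
        return "*"
    # ambiguous (contains N): translate only if all resolutions agree
    if "N" in codon:
        options = {codon.replace("N", b, 1) for b in "ACGT"}
        expanded = set()
        for c in options:
            expanded.add(_translate_codon(c))
        if len(expanded) == 1:
            return expanded.pop()
    return "X"


def translate(nt: str) -> str:
    """Translate a forward-frame nucleotide string (standard genetic code;
    stops rendered '*', ambiguous N-codons rendered 'X')."""
    nt = nt.upper()
    return "".join(
        _translate_codon(nt[i:i + 3]) for i in range(0, len(nt) - 2, 3)
    )


def translate_frames(nt: str) -> dict[int, str]:
    """All six reading frames; frames -1..-3 translate the reverse complement.
    Sequences shorter than 3 nt give empty strings in every frame."""
    nt = nt.upper()
    rc = str(Seq(nt).reverse_complement())
    out = {}
    for f in (1, 2, 3):
        out[f] = translate(nt[f - 1:])
        out[-f] = translate(rc[f - 1:])
    return out


def frame_aa_to_nt(frame: int, aa_index: int, seq_len: int) -> tuple[int, int]:
    """Map a 0-based amino-acid index in a frame translation to the 1-based
    inclusive forward-strand nt interval of its codon."""
    if frame > 0:
        start = frame + 3 * aa_index  # 1-based
        return start, start + 2
    # negative frame: position on the reverse complement, mapped back
    off = -frame - 1
    rc_start = off + 3 * aa_index  # 0-based on revcomp
    fwd_end = seq_len - rc_start  # 1-based
    return fwd_end - 2, fwd_end


@dataclass
class OrfCandidate:
    transcript_id: str
    frame: int
    nt_span: tuple[int, int]  # 1-based inclusive, forward strand
    protein: str
    has_start: bool
    has_stop: bool
    aa_offset: int = 0  # 0-based index of the first ORF residue in the frame translation


@dataclass
class ArtifactFlag:
    transcript_id: str
    kind: str  # in_frame_stop | frameshift_suspect
    position: int  # 1-based nt coordinate, forward strand
    evidence: str


def _span_for(frame: int, aa_start: int, aa_len: int, include_stop: bool, seq_len: int) -> tuple[int, int]:
    s1, _ = frame_aa_to_nt(frame, aa_start, seq_len)
    last = aa_start + aa_len - 1 + (1 if include_stop else 0)
    _, e1 = frame_aa_to_nt(frame, last, seq_len)
    if frame > 0:
        return s1, e1
    # reverse strand: codons run backwards on the forward strand
    s2, _ = frame_aa_to_nt(frame, last, seq_len)
    _, e2 = frame_aa_to_nt(frame, aa_start, seq_len)
    return s2, e2


def find_orfs(transcript: TranscriptRecord, min_len: int = 40) -> list[OrfCandidate]:
    """Extract ORF candidates from all six frames, sorted by descending
    protein length.  Edge-truncated ORFs carry has_start/has_stop=False."""
    seq = transcript.sequence
    n = len(seq)
    out: list[OrfCandidate] = []
    for frame, prot in translate_frames(seq).items():
        # stop-delimited segments of the frame translation
        start = 0
        segments = []
        for i, aa in enumerate(prot):
            if aa == "*":
                segments.append((start, i, True))  # [start, i) terminated by stop
                start = i + 1
        if start < len(prot):
            segments.append((start, len(prot), False))  # runs off the 3' end
        for seg_start, seg_end, has_stop in segments:
            seg = prot[seg_start:seg_end]
            if not seg:
                continue
            at_5p_edge = seg_start == 0
            m = seg.find("M")
            candidates = []
            if m >= 0:
                candidates.append((seg_start + m, seg[m:], True))
            if at_5p_edge and m != 0:
                # ORF running off the 5' end of the transcript without ATG
                candidates.append((seg_start, seg, False))
            for aa_start, protein, has_start in candidates:
                if len(protein) < min_len:
                    continue
                span = _span_for(frame, aa_start, len(protein), has_stop, n)
                out.append(
                    OrfCandidate(
                        transcript_id=transcript.id,
                        frame=frame,
                        nt_span=span,
                        protein=protein,
                        has_start=has_start,
                        has_stop=has_stop,
                        aa_offset=aa_start,
                    )
                )
    out.sort(key=lambda c: (-len(c.protein), c.frame, c.nt_span))
    return out


def flag_artifacts(
    candidate: OrfCandidate,
    registry,
    transcript: TranscriptRecord,
    window: int = 60,
) -> list[ArtifactFlag]:
    """Advisory artifact flags for one ORF candidate.

    in_frame_stop: a '*' in the candidate's frame translation such that
    substituting any residue for the stop yields a family-motif match
    covering its position.  frameshift_suspect: a family motif matched in a
    different same-strand frame whose nt interval lies within ``window`` nt
    of the candidate's interval.
    """
    flags: list[ArtifactFlag] = []
    seq = transcript.sequence
    n = len(seq)
    frames = translate_frames(seq)
    prot = frames[candidate.frame]
    patterns = registry.unanchored_patterns()

    # --- in-frame stops at/inside the candidate region (a stop that breaks
    # the ORF sits at its boundary)
    lo = max(0, candidate.aa_offset - 3)
    hi = min(len(prot), candidate.aa_offset + len(candidate.protein) + 3)
    for q in range(lo, hi):
        if prot[q] != "*":
            continue
        ctx_lo = max(0, q - 25)
        ctx = prot[ctx_lo:q + 26]
        rel = q - ctx_lo
        hit = None
        for fam, mot_id, rx in patterns:
            for aa in "ACDEFGHIKLMNPQRSTVWY":
                masked = ctx[:rel] + aa + ctx[rel + 1:]
                m = rx.search(masked)
                if m and m.start() <= rel < m.end():
                    hit = (fam, mot_id)
                    break
            if hit:
                break
        if hit:
            pos = frame_aa_to_nt(candidate.frame, q, n)[0]
            flags.append(
                ArtifactFlag(
                    transcript_id=candidate.transcript_id,
                    kind="in_frame_stop",
                    position=pos,
                    evidence=f"{hit[0]}:{hit[1]} spans masked stop",
                )
            )

    # --- motifs completed in a different same-strand frame within the
    # window of the candidate interval; only high-specificity motifs count
    # as evidence (chance-match probability below 1e-5 per position)
    same_strand = [f for f in FRAMES if (f > 0) == (candidate.frame > 0) and f != candidate.frame]
    c_lo, c_hi = candidate.nt_span
    specific = registry.unanchored_patterns(max_rate=1e-5)
    for f in same_strand:
        other = frames[f]
        for fam, mot_id, rx in specific:
            for m in rx.finditer(other):
                s_nt = frame_aa_to_nt(f, m.start(), n)[0]
                e_nt = frame_aa_to_nt(f, m.end() - 1, n)[1]
                lo_nt, hi_nt = min(s_nt, e_nt), max(s_nt, e_nt)
                gap = max(c_lo - hi_nt, lo_nt - c_hi, 0)
                if gap <= window:
                    flags.append(
                        ArtifactFlag(
                            transcript_id=candidate.transcript_id,
                            kind="frameshift_suspect",
                            position=lo_nt,
                            evidence=f"{fam}:{mot_id} completed in frame {f:+d}",
                        )
                    )
    # dedupe by (kind, position)
    seen = set()
    unique = []
    for fl in flags:
        key = (fl.kind, fl.position)
        if key not in seen:
            seen.add(key)
            unique.append(fl)
    return unique
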