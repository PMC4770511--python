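"""Comparative statistics: paracopy summaries (family × taxon), a
presence/absence matrix, and sequence-logo matrices.

The dispersion statistic for paracopy counts is the *uncorrected* sample
standard deviation S_N = sqrt((1/N) Σ (x_i − mean)²) — denominator N, not
N−1.  Only full-length precursors contribute means; a taxon with only
partial precursors for a family reports the maximum visible copy number as
a "(≥k)" lower bound.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import numpy as np
import pandas as pd

from .registry import (
    CAPA_COMPLEX,
    LIGAND_OTHER,
    LIGAND_PK,
    LIGAND_PVK,
    LIGAND_TRYPTO_PK,
    type_capa_ligand,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Table row order: capa/pk appears as three ligand rows
ROW_ORDER = [
    "AST-A", "MIP", "CAPA/PK:PVK", "CAPA/PK:trypto-PK", "CAPA/PK:PK",
    "FMRFa", "TKRP", "natalisin", "EFLa", "kinin", "RYa", "ETH", "SK",
]
TAXON_ORDER = ["Protura", "Collembola", "Diplura", "Archaeognatha", "Zygentoma"]

_LIGAND_ROW = {
    LIGAND_PVK: "CAPA/PK:PVK",
    LIGAND_TRYPTO_PK: "CAPA/PK:trypto-PK",
    LIGAND_PK: "CAPA/PK:PK",
}


@dataclass
class ParacopySummary:
    family: str
    taxon: str
    n_full: int
    mean: Optional[float]
    s_n: Optional[float]
    max_partial: Optional[int] = None
    values: list = field(default_factory=list)


def s_n(values) -> float:
    """Uncorrected sample standard deviation (denominator N)."""
    x = np.asarray(list(values), dtype=float)
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def _collect_counts(annotated, registry):
    """(row, taxon) -> (full-length counts, partial maxima)."""
    full: dict[tuple[str, str], list[int]] = {}
    partial: dict[tuple[str, str], list[int]] = {}
    for ann in annotated:
        if ann.family == "unassigned":
            continue
        taxon = ann.record.taxon_group.value
        if ann.family in CAPA_COMPLEX:
            ligands = Counter(
                lig
                for lig in (type_capa_ligand(p) for p in ann.peptides)
                if lig != LIGAND_OTHER
            )
            rows = [(_LIGAND_ROW[lig], n) for lig, n in ligands.items()]
        else:
            if registry[ann.family].copy_class != "multiple":
                continue
            rows = [(ann.family, ann.paracopy_count)]
        target = partial if ann.partial else full
        for row, n in rows:
            if n > 0:
                target.setdefault((row, taxon), []).append(n)
    return full, partial


def summarize_paracopies(annotated, registry) -> list[ParacopySummary]:
    """Per (family row, taxon) paracopy statistics from annotated
    precursors.  Rows with no evidence at all are omitted; partial-only
    cells carry the maximum visible count."""
    full, partial = _collect_counts(annotated, registry)
    out = []
    for key in sorted(set(full) | set(partial)):
        row, taxon = key
        values = full.get(key, [])
        if values:
            out.append(
                ParacopySummary(
                    family=row,
                    taxon=taxon,
                    n_full=len(values),
                    mean=float(np.mean(values)),
                    s_n=s_n(values) if len(values) >= 2 else None,
                    values=sorted(values),
                )
            )
        else:
            out.append(
                ParacopySummary(
                    family=row,
                    taxon=taxon,
                    n_full=0,
                    mean=None,
                    s_n=None,
                    max_partial=max(partial[key]),
                )
            )
    return out


def _round_half_up(x: float, places: int) -> float:
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_mean(mean: float) -> str:
    """Display rounding: integral means print as integers; means exact at
    two decimals print both (e.g. 1.75); otherwise one decimal."""
    if abs(mean - round(mean)) < 1e-9:
        return str(int(round(mean)))
    r1 = _round_half_up(mean, 1)
    if abs(mean - r1) < 1e-9:
        return f"{r1:.1f}"
    r2 = _round_half_up(mean, 2)
    if abs(mean - r2) < 1e-9:
        return f"{r2:.2f}"
    return f"{r1:.1f}"


def format_sn(value: float) -> str:
    r1 = _round_half_up(value, 1)
    if abs(r1 - round(r1)) < 1e-9:
        return str(int(round(r1)))
    return f"{r1:.1f}"


def render_cell(summary: ParacopySummary) -> str:
    if summary.n_full == 0:
        return f"(≥{summary.max_partial})"
    if summary.s_n is None:
        return format_mean(summary.mean)
    return f"{format_mean(summary.mean)} ± {format_sn(summary.s_n)}"


def render_table(summaries: list[ParacopySummary]) -> pd.DataFrame:
    """Family × taxon table of rendered 'mean ± S_N' cells."""
    cells: dict[str, dict[str, str]] = {}
    for s in summaries:
        cells.setdefault(s.family, {})[s.taxon] = render_cell(s)
    rows = [r for r in ROW_ORDER if r in cells] + sorted(set(cells) - set(ROW_ORDER))
    cols_present = {s.taxon for s in summaries}
    cols = [t for t in TAXON_ORDER if t in cols_present] + sorted(cols_present - set(TAXON_ORDER))
    frame = pd.DataFrame(index=rows, columns=cols, dtype=object)
    for fam, by_taxon in cells.items():
        for taxon, cell in by_taxon.items():
            frame.loc[fam, taxon] = cell
    frame.index.name = "family"
    return frame.fillna("")


def presence_matrix(assignments, species_by_taxon: dict[str, list[str]]) -> pd.DataFrame:
    """Family × taxon matrix of the number of species with at least one
    assigned precursor.  0 means surveyed-but-absent; taxa not in the
    census are simply not columns, so absence is distinct from missing
    data."""
    seen: dict[str, dict[str, set]] = {}
    for a in assignments:
        if a.family == "unassigned":
            continue
        taxon = a.taxon_group.value
        if taxon not in species_by_taxon:
            continue
        seen.setdefault(a.family, {}).setdefault(taxon, set()).add(a.species)
    families = sorted(seen)
    taxa = list(species_by_taxon)
    frame = pd.DataFrame(0, index=families, columns=taxa, dtype=int)
    for fam, by_taxon in seen.items():
        for taxon, species in by_taxon.items():
            frame.loc[fam, taxon] = len(species)
    frame.index.name = "family"
    return frame


@dataclass
class LogoMatrix:
    length: int
    freqs: np.ndarray  # positions × 20
    info: np.ndarray  # bits per position
    heights: np.ndarray  # positions × 20
    n_seqs: int
    gap_policy: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.length):
            for j, aa in enumerate(AA20):
                if self.freqs[i, j] > 0:
                    rows.append(
                        {
                            "position": i + 1,
                            "residue": aa,
                            "freq": self.freqs[i, j],
                            "height": self.heights[i, j],
                            "info": self.info[i],
                        }
                    )
        return pd.DataFrame(rows)


def build_logo(
    peptides: list[str],
    small_sample_correction: bool = False,
    gap_policy: str = "ignore_gaps",
) -> LogoMatrix:
    """Sequence-logo matrix for pre-aligned equal-length peptides.

    Per position i: info[i] = log2(20) − H[i] − e_n, with H the Shannon
    entropy of the observed residue frequencies and e_n =
    (1/ln 2)·(20−1)/(2n) the optional small-sample correction.  Letter
    heights are freq × info, so each stack sums to the information content.
    Gaps ('-') and the no-residue marker 'X' are ignored under the default
    gap policy (frequencies renormalized over non-gap observations).
    """
    if not peptides:
        raise ValueError("no sequences")
    length = len(peptides[0])
    for s in peptides:
        if len(s) != length:
            raise ValueError(f"alignment error: lengths {length} vs {len(s)}")
    if gap_policy not in ("ignore_gaps", "count_gaps"):
        raise ValueError(f"unknown gap policy: {gap_policy}")

    n_seqs = len(peptides)
    idx = {aa: j for j, aa in enumerate(AA20)}
    counts = np.zeros((length, 20))
    gap_counts = np.zeros(length)
    for s in peptides:
        for i, aa in enumerate(s.upper()):
            if aa in idx:
                counts[i, idx[aa]] += 1
            elif aa in "-X.":
                gap_counts[i] += 1
            else:
                raise ValueError(f"unknown residue {aa!r} at position {i + 1}")

    freqs = np.zeros_like(counts)
    info = np.zeros(length)
    heights = np.zeros_like(counts)
    max_bits = math.log2(20)
    for i in range(length):
        n_obs = counts[i].sum()
        denom = n_obs if gap_policy == "ignore_gaps" else n_obs + gap_counts[i]
        if denom == 0:
            continue
        freqs[i] = counts[i] / denom
        p = freqs[i][freqs[i] > 0]
        h = float(-(p * np.log2(p)).sum())
        e_n = (19.0 / (2.0 * denom)) / math.log(2) if small_sample_correction else 0.0
        info[i] = max(0.0, max_bits - h - e_n)
        heights[i] = freqs[i] * info[i]
    return LogoMatrix(
        length=length,
        freqs=freqs,
        info=info,
        heights=heights,
        n_seqs=n_seqs,
        gap_policy=gap_policy,
    )


def pad_cterm(peptides: list[str], pad: str = "-") -> list[str]:
    """C-terminal-anchored padding helper for unaligned amidated peptides of
    unequal length (alignment proper is input, not computed)."""
    width = max(len(p) for p in peptides)
    return [pad * (width - len(p)) + p for p in peptides]
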