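# Methods

This note records the models, rules and design choices behind `npmine`, the
parameters that matter, and what the synthetic benchmarks do and do not
show.

## Precursor model

A neuropeptide precursor is modeled as

```
signal peptide | [spacer] peptide [G] KR | ... | [spacer] peptide [G] KR | acidic tail
```

— an N-terminal signal peptide, then one or more mature-peptide segments
separated by basic convertase cleavage signals.  A Gly immediately before a
cleavage signal (or before the stop of a complete precursor) is an
amidation donor: the peptide is C-terminally amidated and the Gly does not
appear in the processed form (display suffix `a`).  An N-terminal Gln is
displayed as pyroglutamate (`pQ`); Glu is deliberately never auto-cyclized
(kept conservative).  Coordinates in all outputs are 1-based inclusive on
the precursor protein.

## Signal-peptide score

Signal peptides are predicted with a transparent heuristic rather than a
neural network, so results are deterministic and auditable; precomputed
external predictions can be substituted through a TSV adapter.  For each
candidate cleavage position `p` (last signal residue, scanned over 10–45):

* net positive charge of the n-region (residues 1–5), capped at 2;
* the best mean Kyte–Doolittle hydropathy over an 8-residue h-core window
  ending within `[p−9, p−3]` (the core must sit close to the cleavage
  point, which keeps distant positions uncompetitive);
* +1 when the −1 residue (`p`) is A/G/S and the −3 residue (`p−2`) is one
  of A/G/S/C/T/V — the classical −3/−1 rule;
* −0.7 per charged residue (D/E/K/R) in the last five signal positions
  (signal c-regions are uncharged).

The prediction is `present` when the best score reaches the threshold
(default 3.5; config key `signal_threshold`).  Ties go to the most
C-terminal position.  Precursors shorter than 25 residues or N-terminally
incomplete return `present=false` with an explicit reason.  On planted
signals the cleavage position is recovered within ±1 residue ≥95% of the
time; the residual ±1 ambiguity arises when the residue after the true
cleavage also satisfies the −3/−1 pattern.

## Cleavage rules

Candidate sites are every K/R position; each is returned with its class and
an accept/reject reason (the audit trail substitutes for manual
assignment).  Rules, in order: sites inside the signal peptide are
rejected; Pro at P1′ blocks; Cys at P1′ or P2′ blocks (disulfide
protection); dibasic KR and RR are accepted; KK and RK are accepted at
reduced confidence (config `allow_KK`, `allow_RK`); mono-Arg requires a
basic residue at P4, P6 or P8 (config `mono_r_basic_positions`); mono-Lys
is never cleaved.  Within a run of adjacent basics only the most
C-terminal accepted candidate is kept as P1, and the whole run (capped at
4, including a furin-like R-X-K/R-R extension, except when the P3 position
is the amide-donor Gly) is consumed as cleavage signal.  When a family
registry is available, accepted sites falling *inside* a motif match are
rejected: single interior basics of kinins, SIFamide or short NPF are
sequence features of the mature peptide, not processing signals.

Excision partitions the precursor exactly: signal peptide + excised
segments + consumed cleavage residues reconstruct the input byte for byte
(tested on 500 generated precursors and enforced as a code invariant).

## Family registry

The 39 families are defined in `src/npmine/data/families.yaml` as anchored
patterns over the mature-peptide body with per-family copy class
(single/multiple), integer priority and literature citation.  The wildcard
`X` matches any residue *except* K/R, so no motif can swallow a cleavage
signal.  Where a family's true consensus is a long cysteine-framed protein
(bursicon, EH, ITP, trissin, CRF-DH), the registry carries a synthetic
cysteine-frame core motif: specific enough for classification, labelled as
synthetic in the data file.  EFLa and NPLP1 are flagged low-confidence
(their assignments in the field rest on homology more than on crisp
motifs).  Overlaps resolve by priority: natalisin (`FWXXR`-amide) over
tachykinin (`FXGXR`-amide), AST-CC over AST-C, and within the capa/pk
complex by ligand typing with priority trypto-PK > PK > PVK, which makes
the three ligand classes mutually exclusive.  A precursor containing any
PVK is the *capa* gene product; a PVK-free, PK-containing one is the *pk*
gene product.

## capa/pk architecture patterns

Pattern classification is a total decision table over ligand-type sets and
gene/transcript structure: A = one gene {PVK, PK}; B = one gene, one
transcript {PVK, trypto-PK, PK}; B1 = B plus a second transcript {PVK,
trypto-PK}; C1/C2/C3 = two genes with capa-like {PVK, trypto-PK} (C3: plus
PK) and pk-like {PK} (C1) or {trypto-PK, PK} (C2/C3).  Everything else —
PVK-only genes, PK-only genes, two PVK-bearing genes, three or more genes —
is `unresolved` with the decisive rule in the rationale string.  Without a
genome, two non-splice-grouped transcripts count as two genes.  Patterns
depend only on presence/absence of ligand types (pattern A additionally
requires the absence of trypto-PK anywhere); multiplicity never matters.
The classifier is verified against an independent brute-force evaluation of
the table over all ligand multisets with ≤6 copies per type.

## Paracopy statistics and logos

Dispersion is the uncorrected standard deviation `S_N` (denominator N; the
witness {3,4} → 0.5 distinguishes it from the N−1 estimator).  Only
full-length precursors enter means; a single full-length precursor reports
a bare mean; taxa with only partial precursors report the maximum visible
count as `(≥k)`.  The capa/pk complex is reported as three ligand rows
(PVK, trypto-PK, PK), each counting ligands per precursor that carries at
least one of them.  Display rounding follows the published convention:
integral means print as integers, means exact at two decimals print both
(1.75), otherwise one decimal (half-up); underlying values stay at full
precision.

Logo matrices use `info_i = log2 20 − H_i − e_n`, with `H_i` the Shannon
entropy of a column and `e_n = (19 / 2n) / ln 2` the small-sample
correction (default **off**: pooled alignments of modest n are reported
uncorrected; a flag enables it).  Gaps (`-`) and the no-residue marker `X`
are ignored by default (frequencies renormalized over non-gap
observations).  Letter heights are `freq × info`, so each stack sums to the
column information; alignment itself is an input — only a trivial
C-terminal-anchored padding helper is provided, because homologous
neuropeptides are conventionally aligned by hand on their amidated
C-termini.

## Artifact flags

Flags are advisory and never modify stored sequences.  `in_frame_stop`: a
stop codon whose 20-way substitution restores a family-motif match covering
its position.  `frameshift_suspect`: a family motif matched in a different
same-strand frame within 60 nt (configurable) of the candidate ORF; only
high-specificity motifs (chance-match probability < 1e-5 per position,
computed from the pattern's class sizes) serve as evidence, which keeps the
false-positive rate on clean transcripts negligible.  The stated criterion
for "sequencing error more likely than a dead gene" is this package's
operationalization of an otherwise manual judgement.

## Synthetic generator

The generator exists so every stage can be tested against planted truth.
Design choices:

* Spacers/flanks are drawn from {D,E,N,S,T} — an alphabet that cannot
  complete any registry motif or basic cleavage signal — and always begin
  with D/E after the signal peptide (acidic pro-regions are typical), so
  planted truth is exact and signal-position recovery is well defined.
* Peptides instantiate registry exemplars; multiple-copy families get
  1–4-residue flank variation per copy, families with N-terminally
  anchored motifs (orcokinin, AKH, inotocin) get none.
* Back-translation uses uniform synonymous codon choice (no codon-usage
  model — sufficient for translation testing); every generator is
  deterministic per seed (byte-identical reruns).
* Point substitutions (rate 0–0.2 per nt) never touch motif-critical
  codons — motif spans, amide donors, cleavage signals, start/stop — and
  are missense-only: premature stops are a *separate*, explicitly planted
  lesion kind (`corrupt(kind="in_frame_stop")`), as are single-nt
  frameshifts and 5′/3′ truncations, each at a recorded position.
* Taxon profiles fix per-species copy-number lists, presence/absence
  switches (e.g. no PDF in Protura/Diplura, no elevenin in Collembola),
  splice families (ITP everywhere; orcokinin where splice variants occur)
  and per-species capa/pk patterns; the defaults encode the published
  non-pterygote hexapod complements so the pipeline's summary table can be
  checked cell-for-cell against printed values.

What passing these benchmarks shows: the pipeline's rules are internally
consistent and recover planted structure exactly at zero mutation and
robustly (≥90% peptide recall) at 5% substitution.  What they do not show:
performance on real transcriptome assemblies, whose artifacts (chimeras,
fragmentation, allelic variation, codon bias, genuinely ambiguous cleavage
contexts) the generator deliberately does not model.

## Problem sizes and numerics

Default panels are desk-scale: 3–9 species per taxon, ~60–210 precursors
per panel, transcripts of a few hundred nt; the whole benchmark suite runs
in seconds.  Ties in the signal score resolve to the most C-terminal
position; empty excision segments (a cleavage signal at the very
C-terminus) are skipped; means/S_N are computed in float64 and only rounded
for display.  Known limitations: no sulfation/glycosylation, no
machine-learned cleavage model, no homology search (an external-hit hook
covers that), no ancestral-state reconstruction over phylogenies.
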