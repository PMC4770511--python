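# npmine

Neuropeptide precursor mining, annotation and comparative evolution from
transcriptome assemblies.

Neuropeptides are the most diverse class of messenger molecules in animals.
They are made as *precursors* (prepropeptides): a signal peptide followed by
one or more short bioactive peptides flanked by basic prohormone-convertase
cleavage signals, often with a C-terminal Gly that is converted to an amide.
Surveys of insect and other arthropod transcriptomes — for example of the
wingless "basal" hexapod lineages Protura, Collembola, Diplura,
Archaeognatha and Zygentoma — mine assembled transcripts for such
precursors, annotate their processing, assign them to neuropeptide/protein
hormone families, and compare copy numbers and gene architectures across
taxa.  `npmine` packages that workflow as a tested, reusable pipeline for
people doing comparative peptidomics from sequence data alone.

## What it computes

* **ORF discovery** — six-frame translation (standard code, ambiguous
  N-codons → X), Met-initiated and edge-truncated ORFs, and advisory flags
  for likely sequencing artifacts (in-frame stops interrupting a family
  motif; motifs completed in a shifted frame).
* **Precursor annotation** — a transparent von Heijne-style signal-peptide
  score (charged n-region, hydrophobic h-core, small −3/−1 residues);
  prohormone-convertase cleavage calls after the classical criteria
  (dibasic KR/RR always, KK/RK at reduced confidence, mono-Arg only with a
  basic residue at P4/P6/P8, mono-Lys never, Pro at P1′ and nearby Cys
  block); peptide excision with amidation (`…Ca` for a C-terminal amide)
  and pyroGlu (`pQ…`) conventions; splice-variant grouping by shared
  N-terminal prefix.
* **Family classification** — an editable YAML registry of the 39
  neuropeptide / protein-hormone families (anchored motifs such as CCAP
  `[PT]FCNAFXGC`-amide, pyrokinin `FXPRL`-amide, SIFamide
  `…GSI[FY]`-amide), plus PVK / trypto-PK / PK ligand typing for the
  capa/pk complex.
* **Comparative statistics** — paracopy counts per family × taxon with the
  uncorrected standard deviation `S_N = sqrt((1/N) Σ (x_i − x̄)²)`,
  presence/absence matrices, and sequence-logo matrices
  (`info_i = log2 20 − H_i`, letter heights `freq × info`).
* **capa/pk gene architectures** — classification of a species' complement
  into patterns A, B, B1, C1, C2, C3 (one two-ligand gene → one
  three-ligand gene → duplicated *capa*/*pk* genes with different ligand
  sortings).
* **Synthetic data** — a generator that plants precursors with known
  signal positions, peptide spans, families, splice pairs, capa/pk
  architectures and lesion types, so every stage is testable without
  downloads.

## Worked example

Generate a synthetic dipluran panel and run the full pipeline on its
nucleotide transcripts:

```bash
$ npmine synth --taxon Diplura --seed 3 --out synth_dipl
wrote 94 records for 4 Diplura species -> synth_dipl

$ npmine report synth_dipl/panel.fasta --metadata synth_dipl/metadata.tsv --out rep_dipl
                      Diplura
family
AST-A              12.5 ± 0.5
MIP                    11 ± 0
CAPA/PK:PVK         3.5 ± 0.5
CAPA/PK:trypto-PK       1 ± 0
CAPA/PK:PK          4.5 ± 0.5
FMRFa                   4 ± 0
TKRP                    4 ± 0
natalisin                   3
EFLa                  9 ± 2.2
kinin                       5
RYa                     3 ± 0
ETH                     2 ± 0
SK                      2 ± 0
```

Each cell is `mean ± S_N` of paracopy counts over full-length precursors
of that family in the taxon (a bare number means a single full-length
precursor; `(≥k)` means only partial precursors were seen, with at most
`k` visible copies).  For example, the four dipluran species carry 12–13
FGLamide allatostatin (AST-A) copies per precursor (12.5 ± 0.5), and their
capa/pk complements split into a *capa* gene (PVK + trypto-PK) and a *pk*
gene (PKs only) — pattern C1, visible in
`rep_dipl/capa_pk_patterns.tsv`.  `npmine annotate` writes the underlying
per-peptide calls (TSV and GFF3, 1-based inclusive coordinates on the
precursor), including every accepted *and rejected* cleavage site with its
reason, so any summary number can be traced to individual decisions.

The library surface mirrors the CLI: `npmine.read_sequences`,
`npmine.annotate_dataset`, `npmine.report`, `npmine.build_logo`,
`npmine.gen_taxon_panel`, etc.

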