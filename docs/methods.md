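# Methods

## Coordinate model

All genomic coordinates are GFF3-style — 1-based, inclusive on both ends —
throughout the in-memory model; conversions to half-open coordinates
happen only inside interval-tree queries and are never exposed. A
transcript is a set of non-overlapping exon intervals plus CDS intervals
contained in the exon union; UTRs are *always* derived as exonic bases
outside the CDS (5′/3′ split by strand), even when the input GFF3 carries
UTR features. This makes the invariant "every UTR base is an exonic,
non-coding base" hold by construction and makes write→read round-trips
structurally exact. Noncoding exonic bases *between* CDS intervals (which
occur in aberrant fused models) belong to neither UTR list; they are
neither 5′ nor 3′ of the coding region, and no screen depends on them.

CDS phase is recomputed on write by walking CDS intervals in translation
order (coordinate order on `+`, reversed on `-`).

## Screen definitions and numerical choices

**Ortholog length ratio.** r = L_focal / L_ref on integer amino-acid
lengths of the longest isoform per gene (length ties broken by the
lexicographically smallest protein id, for determinism). Candidates:
r ≥ c (too-long) or r ≤ 1/c (too-short), default c = 2. The boundary is
inclusive by default — a ratio of exactly 2 is already the fusion of two
equal-sized genes — with a `strict_greater` switch for the exclusive
reading. Pearson's r is computed by `scipy.stats.pearsonr`; fewer than 3
pairs or zero variance on either side is an error for the standalone
correlation and a NaN in the screen summary.

**Domain screens.** Domain hits are read from HMMER per-domain tables and
filtered at read time on the per-domain *independent* e-value < 10⁻³ (the
independent e-value is the per-domain significance; the conditional
e-value is only meaningful given the full-sequence hit). The census counts
proteins, not domain instances, and uses unordered pairs of distinct
families as its default key: a fusion of two single-domain genes creates
exactly one novel pair, whereas whole-architecture keys (`full-set` mode,
also provided) would treat every multi-domain protein as its own key. A
combination is atypical when absent from every reference census and
carried by fewer than `max_count = 10` focal proteins.

Family deciles use the nearest-rank percentile (value at rank
⌈q·n⌉ in sorted order, q = 0.1 and 0.8) with *strict* inequalities, so
members sitting exactly on a decile are kept; for distinct lengths this
flags at most 10% + 20% of members (±2 boundary members). Families under
10 members are skipped — percentile thresholds on a handful of values are
noise — which matches the screen's intended use on highly abundant
families.

**SSOG calling.** A gene is an orphan iff none of its isoforms has a
BLASTP hit below the e-value cutoff (default 10⁻³) in any *homology*
subject set; hits in designated focal-transcriptome ORF sets instead set
the `has_orf_support` flag (transcriptomic, not homology, evidence). A
hit with an unrecognised subject-set tag is a hard error, since silently
ignoring it could miscall orphans in either direction. "No hit" is read
as "no hit below the cutoff": an insignificant alignment is not evidence
of homology.

**SSOG classification priority.** antisense-CDS ≻ antisense-UTR ≻
same-strand overlap (`other`) ≻ expression ≻ no support. Antisense calls
require ≥ 1 bp of exon–CDS (or exon–UTR) intersection on opposite
strands; CDS outranks UTR because the two classes are reported disjointly
and a CDS overlap is the stronger indictment. Same-strand entanglement is
ranked above the expression check: it is structural evidence of the same
kind as the antisense cases and such genes need locus-level review, not a
coverage threshold. "Some expression" means same-strand coverage depth
> 0 over ≥ 50% of the orphan's exonic bases (configurable; the original
assessment of such loci is inherently visual, so the 50% default is a
reproducible stand-in). Removal is proposed for `no_support`,
`antisense_cds` and `antisense_utr`; `some_expression`, `supported` and
`other` are kept. Printed percentages round half away from zero.

## Curation engine

Actions are applied in one validated batch: duplicate actions for a gene,
actions on unknown genes, and replacement transcripts missing from the
evidence set abort before any mutation. Replacement transcripts are
promoted to single-transcript genes named `<old_gene_id>.split<N>` in the
order listed, with the source gene and evidence transcript recorded in
the gene attributes; the scheme is deterministic so curated annotations
are reproducible and traceable. The engine permits promoted genes to
overlap retained neighbours (real loci do); it does not infer
neighbourhood edits — curating a neighbour requires its own explicit
action.

Protein-coding megabases are the *union* of CDS bases across all
transcripts of all genes, so shared exons between isoforms are not
double-counted and the statistic is invariant under splitting a CDS
interval in two. Read assignability is deliberately simple: an alignment
counts as assigned iff it overlaps ≥ 1 bp of exon of exactly one gene,
unstranded, whole alignments only — a reproducible simplification of
feature-counting tools, not a reimplementation of their overlap modes.

## The synthetic study

The simulator emulates the defect classes the screens target, on a
deliberately idealised genome:

- baseline genes: 1–5 exons of 100–600 bp, introns 50–200 bp, UTRs
  30–60 bp per end, CDS length a multiple of 3 and ≥ 150 bp, intergenic
  gaps 200–600 bp, genes packed sequentially on `n_sequences` chromosomes;
- **fusions**: two adjacent same-strand genes merged; the fused protein
  is exactly the sum of the parts, the ortholog table pairs the fused
  model with a reference of the *shorter* part's length (so the ratio is
  ≥ 2 by construction), and the two real transcripts go to the evidence
  annotation;
- **antisense SSOGs**: single-exon genes opposite a host CDS, or entirely
  inside a host UTR; they receive no significant BLAST hits and no
  same-strand coverage;
- **family outliers**: extra members of Pfam-defined families at 3× or
  ⅓× the family baseline length. Baseline members of a family share one
  exact length, so the truth table is crisp: with all-equal baselines the
  deciles sit on the baseline and only planted outliers fall outside. A
  feasibility check refuses configurations whose planted tails would
  swallow their own decile. The 10%/20% tail calibration that a real,
  continuous length distribution produces is exercised separately on
  10,000 i.i.d. draws;
- **atypical combinations**: one protein gains a domain pair from a
  reserved accession range never emitted into reference species' tables.

Ortholog reference lengths for clean genes are jittered by ×U(0.92, 1.08),
far inside the two-fold band, so clean genes are never flagged and
planted-defect recovery is exact (precision = recall = 1) at fixture
scale. That is what the recovery tests demonstrate: the *logic* of each
screen, not its operating characteristics on real data. Real proteomes
have genuine length divergence, promiscuous domains, and expression
noise; on real data all screens are enrichment devices feeding manual
curation, and their false-positive rates are necessarily non-zero.

All randomness flows from the mandatory seed. Per-gene quantities
(protein sequences, ortholog jitter) come from generators keyed by
(seed, gene id) via CRC-32, so regeneration and re-derivation are
order-independent and emitted files are byte-identical across runs.

Default problem sizes — 80–200 genes per study, 10,000-draw calibration,
≤ 30-protein brute-force oracles — keep the full test suite and the
acceptance script in the seconds range while every planted defect class
is still represented several times over.

## Known limitations

- Orthology is consumed as a table, never inferred; the screens are only
  as good as the ortholog pairs given.
- The GFF3 reader expects canonical gene→mRNA→exon/CDS files; GTF and
  other dialects need external conversion.
- Coverage is interval-averaged, strand-tagged depth, not per-base; the
  expression fraction is computed against depth > 0, so shallow uniform
  coverage and deep partial coverage are not distinguished.
- BUSCO-style completeness is out of scope (external tool and lineage
  databases); annotation comparisons here rest on gene counts, coding
  megabases, screen deltas and read assignability.
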