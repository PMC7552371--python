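# annotqc

Comparative-genomic quality control and curation for draft gene
annotations.

Automated gene annotation pipelines leave characteristic errors behind:
two adjacent genes fused into one model (often through overlapping UTRs in
gene-dense regions), truncated or bloated members of large gene families,
and spurious single-exon predictions sitting antisense inside real genes
that later masquerade as species-specific orphan genes (SSOGs). `annotqc`
implements the screens that find these suspicious models, the
classification logic that sorts orphan candidates by their evidence, and a
curation engine that applies keep / remove / replace-with-transcripts
decisions and recomputes annotation statistics. It is aimed at genome
projects for non-classical model organisms — particularly nematodes —
where a reference annotation is audited against well-curated relatives.

## The screens

**Ortholog length ratios.** For each one-to-one ortholog pair between the
focal and a reference species, compare longest-isoform protein lengths
and compute r = L_focal / L_ref. Pairs with r ≥ c or r ≤ 1/c (default
c = 2, boundary inclusive, `--strict-greater` available) are curation
candidates: a doubled protein is the classic fusion signature. The screen
also reports Pearson's correlation of the two length vectors.

**Atypical domain combinations.** From per-species Pfam domain tables
(HMMER `domtblout`, per-domain independent e-value < 10⁻³), each protein's
architecture is reduced to unordered pairs of distinct domain families. A
focal protein is flagged when it carries a pair absent from every
reference species and present in fewer than 10 focal proteins — a fusion
joins two repertoires and creates exactly such a pair.

**Family length deciles.** Within each large Pfam-defined gene family
(collagens, C-type lectins, ...), members whose protein length falls
strictly below the first or strictly above the eighth decile
(nearest-rank percentiles) are candidates; families with fewer than 10
members are skipped.

**SSOG calling and classification.** A gene is an SSOG if no isoform has
a BLASTP hit with e < 10⁻³ in any reference proteome/ORF set. Unsupported
SSOGs (no hit in the focal transcriptome ORFs either) are classified by
priority: antisense overlap with another gene's CDS → `antisense_cds`;
antisense overlap with a UTR only → `antisense_utr`; same-strand
entanglement → `other`; same-strand read coverage over ≥ 50% of exonic
bases → `some_expression`; else `no_support`. The default removal policy
proposes dropping `no_support` and both antisense categories.

The curation engine applies an action table (keep / remove / replace),
promotes replacement transcripts from an evidence annotation to new genes
(`<gene>.split<N>`), and reports gene counts, unique protein-coding
megabases (union over isoforms), per-screen candidate deltas between
versions, and a featureCounts-style percentage of alignments assignable
to exactly one gene.

A fully seeded simulator (`annotqc simulate`) generates annotation,
proteome, ortholog, domain, BLAST and coverage fixtures with planted
defects of every class plus a truth table, so the whole workflow runs
without any external data.

## Worked example

```bash
annotqc simulate --seed 42 --out demo/bundle --n-genes 100 \
    --fusions 1 --antisense-cds-ssogs 1 --family-outliers 1 \
    --atypical-combinations 1
annotqc screen-all --dir demo/bundle --out demo/screens
```

`demo/screens/length_candidates.tsv`:

```
gene    direction  focal_len  ref_len  ratio
g0001   too-long   532        131      4.0611
```

The planted fusion `g0001` translates to 532 aa against a 131-aa
reference ortholog — four-fold too long, so it is flagged. The summary
(`length_summary.json`) shows the screen context: 99 ortholog pairs,
Pearson's r = 0.9609, 1 candidate. The union table collects one
candidate per screen, each found only by the screen aimed at its defect
class:

```
gene        domain_combination  family_outlier  length  ssog
g0001       0                   0               1       0
g0053       0                   1               0       0
g0054       1                   0               0       0
ssog_g0055  0                   0               0       1
```

and `ssog_classification.tsv` pinpoints the planted antisense model and
the real gene it shadows:

```
gene         category       triggering_gene
ssog_g0055   antisense_cds  g0055
```

Applying the bundle's action table (replace the fusion with its two
evidence transcripts, remove the antisense SSOG) keeps the gene count at
100 (−1 removed, −1 replaced, +2 promoted) while the coding megabases are
unchanged — removing an antisense model nested in a host CDS removes no
unique coding sequence:

```bash
annotqc curate --annotation demo/bundle/annotation.gff3 \
    --actions demo/bundle/actions.tsv \
    --evidence demo/bundle/evidence.gff3 --out demo/curated
# curation_stats.json: before 100 genes / 0.0798 Mb, after 100 / 0.0798 Mb
```

## Layout

- `src/annotqc/model.py` — coordinate model (GFF3 convention, 1-based
  inclusive) and interval arithmetic
- `src/annotqc/io.py` — GFF3 / FASTA / BLAST tabular / domtblout / TSV
  readers and writers, longest-isoform selection
- `src/annotqc/length_screen.py`, `domains.py`, `ssog.py` — the screens
- `src/annotqc/curation.py` — action application and statistics
- `src/annotqc/simulate.py` — seeded fixture generator with planted defects
- `src/annotqc/cli.py` — `annotqc` subcommands
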