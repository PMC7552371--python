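"""Species-specific orphan gene (SSOG) calling and classification.

An SSOG is a focal gene whose protein has no BLASTP hit below an e-value
cutoff in any reference proteome or reference ORF set. Many annotated
SSOGs turn out to be gene-prediction artifacts: single-exon models sitting
antisense inside the CDS or UTR of a well-supported gene, with no
strand-specific transcriptomic support of their own. The classifier sorts
unsupported SSOGs into mutually exclusive categories by a fixed priority
and proposes removal for the artifact-like ones.

Categories, in decision order:

``antisense_cds``
    an SSOG exon shares >= 1 bp with another gene's CDS on the opposite
    strand (CDS overlap outranks UTR overlap);
``antisense_utr``
    opposite-strand overlap with another gene's UTR only;
``other``
    overlap with a same-strand gene — structurally entangled but not an
    antisense artifact, left for ad-hoc review;
``some_expression``
    same-strand read coverage over at least half the SSOG's exonic bases,
    short of supporting the full structure;
``no_support``
    none of the above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .model import AnnotationError, AnnotationSet, BlastHit, ProteinRecord

SUPPORTED = "supported"
NO_SUPPORT = "no_support"
SOME_EXPRESSION = "some_expression"
ANTISENSE_CDS = "antisense_cds"
ANTISENSE_UTR = "antisense_utr"
OTHER = "other"

CATEGORIES = (SUPPORTED, NO_SUPPORT, SOME_EXPRESSION,
              ANTISENSE_CDS, ANTISENSE_UTR, OTHER)

REMOVABLE_CATEGORIES = frozenset({NO_SUPPORT, ANTISENSE_CDS, ANTISENSE_UTR})


@dataclass
class SSOGRecord:
    gene_id: str
    is_ssog: bool
    has_orf_support: bool
    category: str | None = None
    triggering_gene: str | None = None


@dataclass
class CoverageTrack:
    """Strand-tagged expression coverage as non-overlapping intervals."""

    intervals: list[tuple[str, int, int, str, float]] = field(default_factory=list)
    # (sequence_id, start, end, strand, mean depth); 1-based inclusive

    def __post_init__(self) -> None:
        trees: dict[tuple[str, str], IntervalTree] = {}
        for seqid, start, end, strand, depth in self.intervals:
            if depth < 0:
                raise AnnotationError("coverage depth must be >= 0")
            tree = trees.setdefault((seqid, strand), IntervalTree())
            if tree.overlap(start, end + 1):
                raise AnnotationError(
                    f"overlapping coverage intervals on {seqid}{strand}")
            tree.addi(start, end + 1, depth)
        self._trees = trees

    def covered_bases(self, seqid: str, start: int, end: int, strand: str,
                      min_depth: float = 0.0) -> int:
        """Bases of [start, end] with coverage depth > min_depth on strand."""
        tree = self._trees.get((seqid, strand))
        if tree is None:
            return 0
        total = 0
        for iv in tree.overlap(start, end + 1):
            if iv.data > min_depth:
                total += min(end + 1, iv.end) - max(start, iv.begin)
        return total

    @classmethod
    def from_bed(cls, path) -> "CoverageTrack":
        """Read a 6-column BED (0-based half-open; score column = depth)."""
        intervals = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end, _name, depth, strand = line.split("\t")[:6]
                intervals.append((chrom, int(start) + 1, int(end),
                                  strand.strip(), float(depth)))
        return cls(intervals)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for seqid, start, end, strand, depth in sorted(self.intervals):
                fh.write(f"{seqid}\t{start - 1}\t{end}\tcov\t{depth:g}\t{strand}\n")


def call_ssogs(focal_proteins: list[ProteinRecord],
               blast_hits: list[BlastHit],
               homology_sets: list[str],
               orf_support_sets: list[str],
               evalue_cutoff: float = 1e-3) -> list[SSOGRecord]:
    """Call orphans: no significant hit in any homology reference set.

    ``has_orf_support`` is set when a significant hit exists in one of the
    focal-transcriptome ORF sets, which counts as transcriptomic (not
    homology) evidence. Hits carrying an unknown subject-set tag are a hard
    error, since silently ignoring them would miscall orphans.
    """
    known = set(homology_sets) | set(orf_support_sets)
    homology_queries: set[str] = set()
    orf_queries: set[str] = set()
    for hit in blast_hits:
        if hit.subject_set not in known:
            raise AnnotationError(f"unknown subject_set tag {hit.subject_set!r}")
        if hit.evalue >= evalue_cutoff:
            continue
        if hit.subject_set in homology_sets:
            homology_queries.add(hit.query_id)
        else:
            orf_queries.add(hit.query_id)

    by_gene: dict[str, set[str]] = {}
    for protein in focal_proteins:
        by_gene.setdefault(protein.gene_id, set()).add(protein.protein_id)
    records = []
    for gene_id in sorted(by_gene):
        isoforms = by_gene[gene_id]
        records.append(SSOGRecord(
            gene_id=gene_id,
            is_ssog=not (isoforms & homology_queries),
            has_orf_support=bool(isoforms & orf_queries)))
    return records


def _feature_trees(annotation: AnnotationSet):
    """Interval trees of CDS, UTR and exon features keyed by sequence."""
    cds_tree: dict[str, IntervalTree] = {}
    utr_tree: dict[str, IntervalTree] = {}
    exon_tree: dict[str, IntervalTree] = {}
    for gene in annotation:
        for tx in gene.transcripts:
            for iv in tx.cds:
                cds_tree.setdefault(iv.sequence_id, IntervalTree()).addi(
                    iv.start, iv.end + 1, (gene.gene_id, iv.strand))
            for iv in tx.utr5 + tx.utr3:
                utr_tree.setdefault(iv.sequence_id, IntervalTree()).addi(
                    iv.start, iv.end + 1, (gene.gene_id, iv.strand))
            for iv in tx.exons:
                exon_tree.setdefault(iv.sequence_id, IntervalTree()).addi(
                    iv.start, iv.end + 1, (gene.gene_id, iv.strand))
    return cds_tree, utr_tree, exon_tree


def classify_ssog(record: SSOGRecord, annotation: AnnotationSet,
                  coverage: CoverageTrack | None = None,
                  expression_fraction_threshold: float = 0.5,
                  _trees=None) -> SSOGRecord:
    """Assign one unsupported SSOG to a category (see module docstring)."""
    if not record.is_ssog or record.has_orf_support:
        raise AnnotationError(
            f"{record.gene_id}: classify_ssog needs an unsupported SSOG")
    gene = annotation.genes.get(record.gene_id)
    if gene is None:
        raise AnnotationError(f"SSOG {record.gene_id} absent from annotation")
    cds_tree, utr_tree, exon_tree = _trees or _feature_trees(annotation)

    def overlapping_genes(tree_by_seq, same_strand: bool) -> set[str]:
        found = set()
        for tx in gene.transcripts:
            for exon in tx.exons:
                tree = tree_by_seq.get(exon.sequence_id)
                if tree is None:
                    continue
                for hit in tree.overlap(exon.start, exon.end + 1):
                    other_gene, other_strand = hit.data
                    if other_gene == gene.gene_id:
                        continue
                    if (other_strand == exon.strand) == same_strand:
                        found.add(other_gene)
        return found

    antisense_cds = overlapping_genes(cds_tree, same_strand=False)
    if antisense_cds:
        record.category = ANTISENSE_CDS
        record.triggering_gene = min(antisense_cds)
        return record
    antisense_utr = overlapping_genes(utr_tree, same_strand=False)
    if antisense_utr:
        record.category = ANTISENSE_UTR
        record.triggering_gene = min(antisense_utr)
        return record
    sense_neighbors = overlapping_genes(exon_tree, same_strand=True)
    if sense_neighbors:
        record.category = OTHER
        record.triggering_gene = min(sense_neighbors)
        return record

    if coverage is not None:
        exonic = covered = 0
        for tx in gene.transcripts:
            for exon in tx.exons:
                exonic += len(exon)
                covered += coverage.covered_bases(
                    exon.sequence_id, exon.start, exon.end, exon.strand)
        if exonic and covered / exonic >= expression_fraction_threshold:
            record.category = SOME_EXPRESSION
            return record
    record.category = NO_SUPPORT
    return record


def classify_all(records: list[SSOGRecord], annotation: AnnotationSet,
                 coverage: CoverageTrack | None = None,
                 expression_fraction_threshold: float = 0.5) -> list[SSOGRecord]:
    """Classify every unsupported SSOG; supported ones are labelled as such."""
    trees = _feature_trees(annotation)
    out = []
    for rec in records:
        if not rec.is_ssog:
            continue
        if rec.has_orf_support:
            rec.category = SUPPORTED
            out.append(rec)
        else:
            out.append(classify_ssog(rec, annotation, coverage,
                                     expression_fraction_threshold,
                                     _trees=trees))
    return out


def removal_policy(records: list[SSOGRecord],
                   removable: frozenset[str] = REMOVABLE_CATEGORIES):
    """Propose keep/remove actions from the category table.

    Returns :class:`~annotqc.curation.CurationAction` rows: remove for the
    artifact-like categories, keep otherwise.
    """
    from .curation import CurationAction  # deferred: avoids an import cycle
    actions = []
    for rec in records:
        if rec.category is None:
            raise AnnotationError(f"{rec.gene_id}: record not classified")
        action = "remove" if rec.category in removable else "keep"
        actions.append(CurationAction(gene_id=rec.gene_id, action=action,
                                      provenance=f"ssog:{rec.category}"))
    return actions


def round_half_away(x: float) -> int:
    """Round half away from zero (the convention used in printed shares)."""
    import math
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def category_summary(records: list[SSOGRecord]) -> dict[str, dict[str, float]]:
    """Counts and integer percentages per category; empty input -> {}."""
    if not records:
        return {}
    counts: dict[str, int] = {}
    for rec in records:
        if rec.category is None:
            raise AnnotationError(f"{rec.gene_id}: record not classified")
        counts[rec.category] = counts.get(rec.category, 0) + 1
    total = len(records)
    return {cat: {"count": n, "percent": round_half_away(100 * n / total)}
            for cat, n in sorted(counts.items())}
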