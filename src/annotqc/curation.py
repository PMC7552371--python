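"""Curation engine: apply keep/remove/replace decisions and recompute stats.

A curation action targets one gene of the working annotation. ``remove``
deletes the gene model; ``replace`` deletes it and promotes one or more
evidence transcripts (assembled from RNA-seq) to new stand-alone genes —
the standard fix for an artificial fusion, where one bogus model is
replaced by the two real transcripts it spans. Promoted genes get
deterministic ids ``<old_gene_id>.split<N>`` and carry their provenance in
the gene attributes.

The module also computes annotation-level statistics (gene count, unique
protein-coding megabases), before/after screen-count deltas, a
featureCounts-style read-assignability percentage, and the per-screen
overlap report used to compare candidate lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .model import (
    AnnotationError,
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
    span_union_length,
)

ACTIONS = ("keep", "remove", "replace")


@dataclass
class CurationAction:
    gene_id: str
    action: str
    replacement_transcripts: list[str] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise AnnotationError(f"unknown action {self.action!r}")
        if self.action == "replace" and not self.replacement_transcripts:
            raise AnnotationError(
                f"{self.gene_id}: replace requires >= 1 replacement transcript")


@dataclass
class AnnotationStats:
    n_genes: int
    coding_mb: float
    screen_counts: dict[str, int] = field(default_factory=dict)


def apply_actions(annotation: AnnotationSet, actions: list[CurationAction],
                  evidence: AnnotationSet | None = None) -> AnnotationSet:
    """Produce a corrected AnnotationSet from a batch of curation actions.

    Duplicate actions for one gene, actions on unknown genes, and
    replacement transcripts absent from the evidence set are hard errors:
    a curation table with such rows is inconsistent and must be fixed, not
    partially applied.
    """
    seen: set[str] = set()
    for act in actions:
        if act.gene_id in seen:
            raise AnnotationError(f"duplicate actions for gene {act.gene_id}")
        seen.add(act.gene_id)
        if act.gene_id not in annotation.genes:
            raise AnnotationError(f"action on unknown gene {act.gene_id}")

    evidence_tx: dict[str, TranscriptModel] = {}
    if evidence is not None:
        evidence_tx = {t.transcript_id: t for t in evidence.transcripts()}

    new_genes: dict[str, GeneModel] = {
        gid: gene for gid, gene in annotation.genes.items()}
    for act in actions:
        if act.action == "keep":
            continue
        del new_genes[act.gene_id]
        if act.action == "remove":
            continue
        for n, tid in enumerate(act.replacement_transcripts, start=1):
            if tid not in evidence_tx:
                raise AnnotationError(
                    f"{act.gene_id}: replacement transcript {tid!r} "
                    f"not in evidence set")
            src = evidence_tx[tid]
            new_gid = f"{act.gene_id}.split{n}"
            tx = TranscriptModel(transcript_id=f"{new_gid}.t1", gene_id=new_gid,
                                 exons=list(src.exons), cds=list(src.cds))
            new_genes[new_gid] = GeneModel(
                new_gid, [tx],
                attributes={"curation_source": act.gene_id,
                            "evidence_transcript": tid,
                            "provenance": act.provenance or "curation"})
    return AnnotationSet(genes=dict(sorted(new_genes.items())),
                         version_label=annotation.version_label + "+curated"
                         if annotation.version_label else "curated")


def annotation_stats(annotation: AnnotationSet,
                     screen_counts: dict[str, int] | None = None) -> AnnotationStats:
    """Gene count and unique coding megabases.

    ``coding_mb`` counts genomic bases covered by at least one CDS interval
    of any transcript — a union, so shared exons between isoforms are not
    double-counted.
    """
    spans_by_seq: dict[str, list[tuple[int, int]]] = {}
    for gene in annotation:
        for tx in gene.transcripts:
            for iv in tx.cds:
                spans_by_seq.setdefault(iv.sequence_id, []).append(
                    (iv.start, iv.end))
    coding = sum(span_union_length(spans) for spans in spans_by_seq.values())
    return AnnotationStats(n_genes=len(annotation), coding_mb=coding / 1e6,
                           screen_counts=dict(screen_counts or {}))


def rescreen_delta(stats_before: AnnotationStats,
                   stats_after: AnnotationStats) -> dict[str, dict[str, float]]:
    """Per-screen candidate-count change between two annotation versions."""
    if set(stats_before.screen_counts) != set(stats_after.screen_counts):
        raise AnnotationError("screen-count keys differ between versions")
    table = {}
    for screen, before in sorted(stats_before.screen_counts.items()):
        after = stats_after.screen_counts[screen]
        change = after - before
        pct = 100 * change / before if before else float("nan")
        table[screen] = {
            "before": before, "after": after, "change": change,
            "percent_change": pct,
            "direction": "down" if change < 0 else ("up" if change > 0 else "flat"),
        }
    return table


def assign_alignments(alignments: list[GenomicInterval],
                      annotation: AnnotationSet) -> float:
    """Percent of alignments assignable to exactly one gene's exons.

    An alignment is assigned iff it overlaps >= 1 bp of exon of exactly one
    gene; overlap with exons of two or more genes is ambiguous and with none
    is intergenic — both unassigned. Strand is ignored. A simplification of
    featureCounts-style counting: whole alignments, no fractional overlap
    modes.
    """
    if not alignments:
        raise AnnotationError("no alignments to assign")
    exon_tree: dict[str, IntervalTree] = {}
    for gene in annotation:
        for tx in gene.transcripts:
            for iv in tx.exons:
                exon_tree.setdefault(iv.sequence_id, IntervalTree()).addi(
                    iv.start, iv.end + 1, gene.gene_id)
    assigned = 0
    for aln in alignments:
        tree = exon_tree.get(aln.sequence_id)
        if tree is None:
            continue
        genes = {hit.data for hit in tree.overlap(aln.start, aln.end + 1)}
        if len(genes) == 1:
            assigned += 1
    return 100.0 * assigned / len(alignments)


def screen_overlap_report(candidate_sets: dict[str, set[str]]) -> dict:
    """Per-screen specific counts plus full intersection-pattern counts.

    ``specific`` = ids found by that screen and no other; ``patterns`` maps
    each non-empty membership pattern (sorted tuple of screen names) to the
    number of ids showing exactly that pattern.
    """
    if len(candidate_sets) < 2:
        raise AnnotationError("need >= 2 candidate sets to compare")
    all_ids = set().union(*candidate_sets.values())
    patterns: dict[tuple[str, ...], int] = {}
    for gid in all_ids:
        pattern = tuple(sorted(name for name, ids in candidate_sets.items()
                               if gid in ids))
        patterns[pattern] = patterns.get(pattern, 0) + 1
    specific = {name: patterns.get((name,), 0) for name in candidate_sets}
    return {"specific": specific,
            "patterns": dict(sorted(patterns.items())),
            "union_size": len(all_ids)}
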