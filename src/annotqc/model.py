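"""In-memory annotation model.

Coordinates follow the GFF3 convention everywhere: 1-based, inclusive on
both ends. Conversions to half-open coordinates happen only inside
computations and are never exposed on the public types.

The object hierarchy mirrors a GFF3 file: an :class:`AnnotationSet` holds
:class:`GeneModel` objects, each gene holds one or more
:class:`TranscriptModel` objects, and a transcript is a bag of exon, CDS
and UTR :class:`GenomicInterval` lists sharing one sequence and strand.
UTRs are always derived as exonic bases outside the CDS, split into 5'
and 3' by strand, so the invariant "UTR = exon minus CDS" holds by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field


STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised when an annotation object violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a sequence, 1-based inclusive."""

    sequence_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise AnnotationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise AnnotationError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in STRANDS:
            raise AnnotationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases, ignoring strand; 0 on different sequences."""
        if self.sequence_id != other.sequence_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


# ---------------------------------------------------------------------------
# interval arithmetic on (start, end) pairs, 1-based inclusive

def merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended (adjacent) spans into a sorted union."""
    if not spans:
        return []
    out: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_spans(minuend: list[tuple[int, int]],
                   subtrahend: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference minuend \\ subtrahend; both merged internally."""
    result: list[tuple[int, int]] = []
    sub = merge_spans(subtrahend)
    for s, e in merge_spans(minuend):
        cur = s
        for bs, be in sub:
            if be < cur or bs > e:
                continue
            if bs > cur:
                result.append((cur, bs - 1))
            cur = max(cur, be + 1)
            if cur > e:
                break
        if cur <= e:
            result.append((cur, e))
    return result


def span_union_length(spans: list[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in merge_spans(spans))


def spans_of(intervals: list[GenomicInterval]) -> list[tuple[int, int]]:
    return [(iv.start, iv.end) for iv in intervals]


# ---------------------------------------------------------------------------


@dataclass
class TranscriptModel:
    """One transcript: exons, CDS and strand-split UTRs on a single strand.

    ``utr5``/``utr3`` are derived from exons and CDS unless explicitly
    supplied, in which case they are validated against the derivation.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        seqids = {iv.sequence_id for iv in self.exons + self.cds}
        strands = {iv.strand for iv in self.exons + self.cds}
        if len(seqids) != 1 or len(strands) != 1:
            raise AnnotationError(
                f"transcript {self.transcript_id}: intervals span multiple "
                f"sequences {seqids} or strands {strands}")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        exon_spans = spans_of(self.exons)
        merged = merge_spans(exon_spans)
        if span_union_length(exon_spans) != sum(len(iv) for iv in self.exons):
            raise AnnotationError(
                f"transcript {self.transcript_id}: overlapping exons")
        if subtract_spans(spans_of(self.cds), merged):
            raise AnnotationError(
                f"transcript {self.transcript_id}: CDS outside exons")
        if not self.utr5 and not self.utr3:
            self.utr5, self.utr3 = self._derive_utrs()
        else:
            self.utr5 = sorted(self.utr5, key=lambda iv: iv.start)
            self.utr3 = sorted(self.utr3, key=lambda iv: iv.start)

    def _derive_utrs(self) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
        if not self.cds:
            return [], []
        seqid, strand = self.sequence_id, self.strand
        cds_lo = min(iv.start for iv in self.cds)
        cds_hi = max(iv.end for iv in self.cds)
        noncoding = subtract_spans(spans_of(self.exons), spans_of(self.cds))
        left = [GenomicInterval(seqid, s, e, strand) for s, e in noncoding if e < cds_lo]
        right = [GenomicInterval(seqid, s, e, strand) for s, e in noncoding if s > cds_hi]
        if strand == "+":
            return left, right
        return right, left

    @property
    def sequence_id(self) -> str:
        return self.exons[0].sequence_id

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.sequence_id,
                               min(iv.start for iv in self.exons),
                               max(iv.end for iv in self.exons),
                               self.strand)

    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds)

    def exonic_length(self) -> int:
        return sum(len(iv) for iv in self.exons)


@dataclass
class GeneModel:
    """A gene with >= 1 transcript; span is derived from the transcripts."""

    gene_id: str
    transcripts: list[TranscriptModel]
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        seqids = {t.sequence_id for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(seqids) != 1 or len(strands) != 1:
            raise AnnotationError(
                f"gene {self.gene_id}: transcripts on multiple sequences/strands")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise AnnotationError(
                    f"transcript {t.transcript_id} claims gene {t.gene_id}, "
                    f"stored under {self.gene_id}")
        self.transcripts = sorted(self.transcripts, key=lambda t: t.transcript_id)

    @property
    def span(self) -> GenomicInterval:
        spans = [t.span for t in self.transcripts]
        return GenomicInterval(spans[0].sequence_id,
                               min(s.start for s in spans),
                               max(s.end for s in spans),
                               spans[0].strand)

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def sequence_id(self) -> str:
        return self.transcripts[0].sequence_id


@dataclass
class AnnotationSet:
    """All gene models of one annotation version, keyed by gene id."""

    genes: dict[str, GeneModel] = field(default_factory=dict)
    version_label: str = ""

    def __post_init__(self) -> None:
        tids: set[str] = set()
        for gid, gene in self.genes.items():
            if gid != gene.gene_id:
                raise AnnotationError(f"key {gid} != gene_id {gene.gene_id}")
            for t in gene.transcripts:
                if t.transcript_id in tids:
                    raise AnnotationError(
                        f"duplicate transcript id {t.transcript_id}")
                tids.add(t.transcript_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def transcripts(self):
        for gene in self:
            yield from gene.transcripts

    def structurally_equal(self, other: "AnnotationSet") -> bool:
        """Equality of gene structure, ignoring version labels/attributes."""
        if set(self.genes) != set(other.genes):
            return False
        for gid, g in self.genes.items():
            o = other.genes[gid]
            if len(g.transcripts) != len(o.transcripts):
                return False
            for tg, to in zip(g.transcripts, o.transcripts):
                if (tg.transcript_id, tg.exons, tg.cds, tg.utr5, tg.utr3) != \
                        (to.transcript_id, to.exons, to.cds, to.utr5, to.utr3):
                    return False
        return True


@dataclass(frozen=True)
class ProteinRecord:
    """A translated isoform linked to its gene; length in amino acids."""

    protein_id: str
    gene_id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise AnnotationError(f"protein {self.protein_id}: length < 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise AnnotationError(
                f"protein {self.protein_id}: sequence length "
                f"{len(self.sequence)} != length field {self.length}")


@dataclass(frozen=True)
class BlastHit:
    """One row of a tabular BLASTP report, tagged with its subject set."""

    query_id: str
    subject_id: str
    subject_set: str
    evalue: float
    bitscore: float
    query_start: int = 1
    query_end: int = 1
    subject_start: int = 1
    subject_end: int = 1

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise AnnotationError("e-value must be non-negative")
        if min(self.query_start, self.query_end,
               self.subject_start, self.subject_end) < 1:
            raise AnnotationError("alignment coordinates must be >= 1")


@dataclass(frozen=True)
class DomainHit:
    """A significant profile match on a protein (envelope coords in aa)."""

    protein_id: str
    domain_family: str
    evalue: float
    envelope_start: int
    envelope_end: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise AnnotationError("e-value must be non-negative")
        if not 1 <= self.envelope_start <= self.envelope_end:
            raise AnnotationError(
                f"bad envelope {self.envelope_start}..{self.envelope_end}")
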