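"""Readers and writers for the external formats the toolkit touches.

GFF3 is read through :mod:`gffutils` (in-memory database, so Parent/ID
links are resolved the way browsers resolve them) and written by a small
canonical formatter: features sorted by coordinate, CDS phase recomputed
in translation order, UTRs emitted explicitly. Reading what the writer
emitted reconstructs a structurally equal :class:`AnnotationSet`.

Tabular BLASTP reports (the 12-column ``-outfmt 6`` dialect) go through
pandas; HMMER per-domain tables go through ``Bio.SearchIO``. The per-domain
*independent* e-value is the significance used, and hits at or above the
0.001 cutoff are dropped at read time.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SearchIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    AnnotationError,
    AnnotationSet,
    BlastHit,
    DomainHit,
    GeneModel,
    GenomicInterval,
    ProteinRecord,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

DOMAIN_EVALUE_CUTOFF = 1e-3

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

GENE_TYPES = {"gene"}
TRANSCRIPT_TYPES = {"mRNA", "transcript"}


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path, version_label: str = "") -> AnnotationSet:
    """Parse a GFF3 file with gene/mRNA/exon/CDS records into an AnnotationSet.

    UTRs are re-derived as exonic bases outside the CDS regardless of any
    UTR features present in the file, which makes the UTR invariant hold by
    construction and round-trips exact.

    Raises :class:`AnnotationError` on dangling Parent links (naming the
    offending record) and on CDS intervals outside their transcript's exons.
    """
    db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                            merge_strategy="error")
    tx_parent: dict[str, str] = {}
    tx_features: dict[str, dict[str, list[GenomicInterval]]] = {}
    gene_feats: dict[str, gffutils.Feature] = {
        f.id: f for t in GENE_TYPES for f in db.features_of_type(t)}

    for ttype in TRANSCRIPT_TYPES:
        for f in db.features_of_type(ttype):
            parents = f.attributes.get("Parent", [])
            if len(parents) != 1 or parents[0] not in gene_feats:
                raise AnnotationError(
                    f"transcript with missing/ambiguous Parent gene: {f}")
            tx_parent[f.id] = parents[0]
            tx_features[f.id] = {"exon": [], "CDS": []}

    for ftype in ("exon", "CDS"):
        for f in db.features_of_type(ftype):
            for parent in f.attributes.get("Parent", []) or [None]:
                if parent not in tx_features:
                    raise AnnotationError(
                        f"{ftype} with missing Parent transcript: {f}")
                tx_features[parent][ftype].append(
                    GenomicInterval(f.seqid, f.start, f.end, f.strand))

    genes: dict[str, list[TranscriptModel]] = {}
    for tid, feats in tx_features.items():
        gid = tx_parent[tid]
        exons = feats["exon"] or feats["CDS"]  # CDS-only records
        genes.setdefault(gid, []).append(
            TranscriptModel(tid, gid, exons=exons, cds=feats["CDS"]))

    gene_models = {}
    for gid, transcripts in genes.items():
        attrs = {k: v[0] for k, v in gene_feats[gid].attributes.items()
                 if k not in ("ID",)}
        gene_models[gid] = GeneModel(gid, transcripts, attributes=attrs)
    return AnnotationSet(genes=dict(sorted(gene_models.items())),
                         version_label=version_label)


def _cds_phases(cds: list[GenomicInterval], strand: str) -> list[int]:
    """GFF3 phase column for each CDS interval (given in coordinate order)."""
    order = cds if strand == "+" else list(reversed(cds))
    phases, consumed = {}, 0
    for iv in order:
        phases[id(iv)] = (3 - consumed % 3) % 3
        consumed += len(iv)
    return [phases[id(iv)] for iv in cds]


def write_gff3(annotation: AnnotationSet, path: str | Path) -> Path:
    """Emit a sorted, GFF3-conformant rendering of the annotation."""
    path = Path(path)
    lines = ["##gff-version 3"]

    def fmt(seqid, ftype, start, end, strand, phase, attrs):
        attr_str = ";".join(f"{k}={v}" for k, v in attrs)
        return f"{seqid}\tannotqc\t{ftype}\t{start}\t{end}\t.\t{strand}\t{phase}\t{attr_str}"

    for gene in sorted(annotation, key=lambda g: (g.sequence_id, g.span.start,
                                                  g.gene_id)):
        span = gene.span
        attrs = [("ID", gene.gene_id)] + sorted(gene.attributes.items())
        lines.append(fmt(span.sequence_id, "gene", span.start, span.end,
                         span.strand, ".", attrs))
        for tx in gene.transcripts:
            ts = tx.span
            lines.append(fmt(ts.sequence_id, "mRNA", ts.start, ts.end,
                             ts.strand, ".",
                             [("ID", tx.transcript_id), ("Parent", gene.gene_id)]))
            parent = [("Parent", tx.transcript_id)]
            for iv in tx.exons:
                lines.append(fmt(iv.sequence_id, "exon", iv.start, iv.end,
                                 iv.strand, ".", parent))
            for iv, phase in zip(tx.cds, _cds_phases(tx.cds, tx.strand)):
                lines.append(fmt(iv.sequence_id, "CDS", iv.start, iv.end,
                                 iv.strand, phase, parent))
            for ivs, ftype in ((tx.utr5, "five_prime_UTR"),
                               (tx.utr3, "three_prime_UTR")):
                for iv in ivs:
                    lines.append(fmt(iv.sequence_id, ftype, iv.start, iv.end,
                                     iv.strand, ".", parent))
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# protein FASTA

def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read proteins; the gene link comes from a ``gene=`` tag in the header.

    A trailing stop symbol ``*`` is not part of the protein and is stripped
    before the length is taken.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        for token in rec.description.split()[1:]:
            if token.startswith("gene="):
                gene_id = token[len("gene="):]
        seq = str(rec.seq).rstrip("*")
        records.append(ProteinRecord(rec.id, gene_id, len(seq), seq))
    return records


def write_protein_fasta(proteins: list[ProteinRecord], path: str | Path) -> Path:
    path = Path(path)
    recs = [SeqRecord(Seq(p.sequence or "X" * p.length), id=p.protein_id,
                      description=f"gene={p.gene_id}") for p in proteins]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
    return path


# ---------------------------------------------------------------------------
# BLAST tabular

def read_blast_tab(path: str | Path, subject_set: str) -> list[BlastHit]:
    """Read a 12-column tabular BLAST report, tagging rows with *subject_set*."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS,
                         comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    evalues = pd.to_numeric(df["evalue"], errors="coerce")
    bad = evalues.isna()
    if bad.any():
        lineno = int(bad.idxmax()) + 1
        raise AnnotationError(
            f"{path}: non-numeric e-value on line {lineno}: "
            f"{df.loc[bad.idxmax(), 'evalue']!r}")
    hits = []
    for row, ev in zip(df.itertuples(index=False), evalues):
        hits.append(BlastHit(
            query_id=row.qseqid, subject_id=row.sseqid, subject_set=subject_set,
            evalue=float(ev), bitscore=float(row.bitscore),
            query_start=int(row.qstart), query_end=int(row.qend),
            subject_start=int(row.sstart), subject_end=int(row.send)))
    return hits


def write_blast_tab(hits: list[BlastHit], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, "90.0", 100, 5, 0,
                h.query_start, h.query_end, h.subject_start, h.subject_end,
                f"{h.evalue:.2g}", h.bitscore])) + "\n")
    return path


# ---------------------------------------------------------------------------
# HMMER per-domain tables

def read_domtbl(path: str | Path,
                evalue_cutoff: float = DOMAIN_EVALUE_CUTOFF) -> list[DomainHit]:
    """Read a hmmsearch per-domain table; keep hits with i-Evalue < cutoff.

    The per-domain independent e-value is the significance criterion; the
    number of dropped rows is logged.
    """
    hits, dropped = [], 0
    try:
        for qresult in SearchIO.parse(str(path), "hmmsearch3-domtab"):
            family = qresult.accession if qresult.accession not in ("-", "", None) \
                else qresult.id
            for hit in qresult:
                for hsp in hit:
                    if hsp.evalue >= evalue_cutoff:
                        dropped += 1
                        continue
                    hits.append(DomainHit(
                        protein_id=hit.id, domain_family=family,
                        evalue=float(hsp.evalue),
                        envelope_start=hsp.env_start + 1,  # 0-based in parser
                        envelope_end=hsp.env_end))
    except (ValueError, IndexError) as exc:
        raise AnnotationError(f"{path}: malformed per-domain table: {exc}") from exc
    if dropped:
        logger.info("read_domtbl(%s): dropped %d hits at e-value >= %g",
                    path, dropped, evalue_cutoff)
    return hits


DOMTBL_HEADER = (
    "#                                                               "
    "--- full sequence --- -------------- this domain -------------   "
    "hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           accession  "
    " qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias"
    "  from    to  from    to  from    to  acc description of target\n"
    "#------------------- ---------- ----- -------------------- ----------"
    " ----- --------- ------ ----- --- --- --------- --------- ------ -----"
    " ----- ----- ----- ----- ----- ----- ---- ---------------------\n")


def write_domtbl(hits: list[DomainHit], path: str | Path,
                 protein_lengths: dict[str, int] | None = None) -> Path:
    """Emit hits in the hmmsearch per-domain table layout (fixture output)."""
    path = Path(path)
    lengths = protein_lengths or {}
    with open(path, "w") as fh:
        fh.write(DOMTBL_HEADER)
        for h in hits:
            tlen = lengths.get(h.protein_id, h.envelope_end)
            qlen = h.envelope_end - h.envelope_start + 1
            fh.write(
                f"{h.protein_id:<20} {'-':<10} {tlen:>5} "
                f"{h.domain_family:<20} {h.domain_family:<10} {qlen:>5} "
                f"{h.evalue:>9.2g} {50.0:>6.1f} {0.1:>5.1f} {1:>3} {1:>3} "
                f"{h.evalue / 10:>9.2g} {h.evalue:>9.2g} {48.0:>6.1f} {0.1:>5.1f} "
                f"{1:>5} {qlen:>5} {h.envelope_start:>5} {h.envelope_end:>5} "
                f"{h.envelope_start:>5} {h.envelope_end:>5} 0.90 -\n")
    return path


# ---------------------------------------------------------------------------
# small TSV tables

def read_pair_table(path: str | Path) -> list[tuple[str, str]]:
    """Ortholog pair table: two columns, focal_gene and reference_gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"focal_gene", "reference_gene"} - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    return list(zip(df["focal_gene"], df["reference_gene"]))


def write_pair_table(pairs: list[tuple[str, str]], path: str | Path) -> Path:
    pd.DataFrame(pairs, columns=["focal_gene", "reference_gene"]).to_csv(
        path, sep="\t", index=False)
    return Path(path)


def read_action_table(path: str | Path):
    """Curation action TSV: gene_id, action, replacement_ids, provenance."""
    from .curation import CurationAction
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene_id", "action"}
    if missing := required - set(df.columns):
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    actions = []
    for row in df.itertuples(index=False):
        reps = getattr(row, "replacement_ids", "")
        actions.append(CurationAction(
            gene_id=row.gene_id, action=row.action,
            replacement_transcripts=[r for r in reps.split(",") if r],
            provenance=getattr(row, "provenance", "")))
    return actions


def write_action_table(actions, path: str | Path) -> Path:
    rows = [(a.gene_id, a.action, ",".join(a.replacement_transcripts),
             a.provenance) for a in actions]
    pd.DataFrame(rows, columns=["gene_id", "action", "replacement_ids",
                                "provenance"]).to_csv(path, sep="\t", index=False)
    return Path(path)


def proteins_from_annotation(annotation: AnnotationSet) -> list[ProteinRecord]:
    """One protein per coding transcript, length = CDS length / 3.

    Used when the proteome FASTA for an annotation version does not exist
    yet (e.g. right after curation) and only lengths are needed.
    """
    proteins = []
    for gene in annotation:
        for tx in gene.transcripts:
            cds_len = tx.cds_length()
            if cds_len >= 3:
                proteins.append(ProteinRecord(
                    f"{tx.transcript_id}.p", gene.gene_id, cds_len // 3))
    return proteins


# ---------------------------------------------------------------------------
# isoform selection

def longest_isoform(gene_id: str, proteins: list[ProteinRecord]) -> ProteinRecord:
    """The longest isoform of a gene; length ties go to the smallest id."""
    candidates = [p for p in proteins if p.gene_id == gene_id]
    if not candidates:
        raise AnnotationError(f"no translated isoform for gene {gene_id}")
    return min(candidates, key=lambda p: (-p.length, p.protein_id))
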