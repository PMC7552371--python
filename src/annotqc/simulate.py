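"""Synthetic annotation fixtures with planted defects.

Generates everything the screens and the curation engine consume — a gene
annotation, proteome, ortholog table, per-species domain tables, BLASTP
reports, strand-specific coverage and an evidence annotation of assembled
transcripts — together with a truth table naming every planted defect.

The planted defect classes emulate the error classes real annotations
exhibit:

* **fusion** — two adjacent same-strand genes merged into one model whose
  protein is the concatenation of both parts; the ortholog table links the
  fused model to a reference ortholog of the shorter part's length, so the
  length-ratio screen sees at least a two-fold excess. The two real
  transcripts are emitted into the evidence annotation, ready for a
  replace action.
* **antisense SSOG** — a single-exon gene on the opposite strand of a host
  gene's CDS (or, in the ``utr`` flavour, entirely inside a host UTR), with
  no homology hits and coverage only on the host strand.
* **family length outlier** — an extra member of a Pfam-defined family
  whose protein is several-fold longer or shorter than the family
  baseline; baseline members share one length so the decile screen's truth
  is exact.
* **atypical domain combination** — a protein granted a domain pair drawn
  from a reserved accession range that never appears in any reference
  species' table.

All randomness flows from the mandatory seed. Per-gene quantities
(sequences, ortholog length jitter) are drawn from generators keyed by
``(seed, gene id)``, so regenerating or re-deriving a bundle is
order-independent and byte-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as aio
from .curation import CurationAction
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
from .ssog import CoverageTrack

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

FUSION = "fusion"
ANTISENSE_CDS_SSOG = "antisense_cds_ssog"
ANTISENSE_UTR_SSOG = "antisense_utr_ssog"
FAMILY_OUTLIER = "family_outlier"
ATYPICAL_COMBINATION = "atypical_combination"

FOCAL_SPECIES = "ppacificus"
DOMAIN_REFERENCE_SPECIES = ("celegans", "bxylophilus", "sratti")
HOMOLOGY_SETS = ("pexspectatus", "parcanus", "pmaxplancki", "pjaponica")
ORF_SUPPORT_SET = "ppacificus_orfs"

VOCAB_FAMILIES = tuple(f"PF{i:05d}" for i in range(1, 11))


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic bundle; the seed is mandatory."""

    seed: int
    n_genes: int = 80
    n_sequences: int = 2
    chrom_length: int = 2_000_000
    exon_count: tuple[int, int] = (1, 5)
    exon_length: tuple[int, int] = (100, 600)
    intron_length: tuple[int, int] = (50, 200)
    utr_length: tuple[int, int] = (30, 60)
    intergenic_gap: tuple[int, int] = (200, 600)
    family_accessions: tuple[str, ...] = ("PF01391", "PF00059")
    family_size: int = 25
    family_baseline_lengths: tuple[int, ...] = (300, 150)
    n_fusions: int = 0
    n_antisense_cds_ssogs: int = 0
    n_antisense_utr_ssogs: int = 0
    n_family_outliers: int = 0
    n_atypical_combinations: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise AnnotationError("a seed is mandatory")
        defects = (self.n_fusions + self.n_antisense_cds_ssogs +
                   self.n_antisense_utr_ssogs + self.n_family_outliers +
                   self.n_atypical_combinations)
        if defects > self.n_genes:
            raise AnnotationError("more planted defects than genes")
        specials = (2 * self.n_fusions + self.n_antisense_cds_ssogs +
                    self.n_antisense_utr_ssogs + self.n_family_outliers +
                    self.n_atypical_combinations +
                    self.family_size * len(self.family_accessions))
        if specials > self.n_genes:
            raise AnnotationError(
                f"config needs {specials} role-bearing genes but n_genes is "
                f"{self.n_genes}")


@dataclass
class TruthRecord:
    defect: str
    gene_id: str
    detail: str = ""


@dataclass
class FixtureBundle:
    """A synthetic study: annotation, evidence, derived inputs and truth."""

    config: FixtureConfig
    annotation: AnnotationSet
    evidence: AnnotationSet
    truth: list[TruthRecord]
    # planting metadata (drives derivation of the downstream inputs)
    ssog_kinds: dict[str, str] = field(default_factory=dict)
    fused: dict[str, tuple[str, str, int, int]] = field(default_factory=dict)
    combo_plants: dict[str, tuple[str, str]] = field(default_factory=dict)
    family_roles: dict[str, tuple[str, str]] = field(default_factory=dict)
    # derived inputs, recomputed by refresh()
    proteins: list[ProteinRecord] = field(default_factory=list)
    reference_proteins: list[ProteinRecord] = field(default_factory=list)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    blast_hits: list[BlastHit] = field(default_factory=list)
    domain_hits: dict[str, list[DomainHit]] = field(default_factory=dict)
    coverage: CoverageTrack = field(default_factory=CoverageTrack)
    actions: list[CurationAction] = field(default_factory=list)

    def truth_genes(self, defect: str) -> set[str]:
        return {t.gene_id for t in self.truth if t.defect == defect}


def _tag_rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(tag.encode())])


def _random_protein(seed: int, tag: str, length: int) -> str:
    rng = _tag_rng(seed, "aa:" + tag)
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def _carve_cds(exons: list[GenomicInterval], strand: str, utr5_len: int,
               cds_len: int) -> list[GenomicInterval]:
    """Map transcript-coordinate CDS [utr5_len, utr5_len+cds_len) to genome."""
    order = exons if strand == "+" else list(reversed(exons))
    cds, offset = [], 0
    lo, hi = utr5_len, utr5_len + cds_len  # half-open, transcript coords
    for exon in order:
        elen = len(exon)
        a, b = max(lo, offset), min(hi, offset + elen)
        if a < b:
            if strand == "+":
                cds.append(GenomicInterval(exon.sequence_id,
                                           exon.start + (a - offset),
                                           exon.start + (b - offset) - 1, strand))
            else:
                cds.append(GenomicInterval(exon.sequence_id,
                                           exon.end - (b - offset) + 1,
                                           exon.end - (a - offset), strand))
        offset += elen
    return sorted(cds, key=lambda iv: iv.start)


def _plain_gene(gene_id: str, seqid: str, start: int, strand: str,
                cfg: FixtureConfig, rng: np.random.Generator) -> GeneModel:
    n_exons = int(rng.integers(cfg.exon_count[0], cfg.exon_count[1] + 1))
    exon_lens = [int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
                 for _ in range(n_exons)]
    intron_lens = [int(rng.integers(cfg.intron_length[0],
                                    cfg.intron_length[1] + 1))
                   for _ in range(n_exons - 1)]
    u5 = int(rng.integers(cfg.utr_length[0], cfg.utr_length[1] + 1))
    u3 = int(rng.integers(cfg.utr_length[0], cfg.utr_length[1] + 1))
    total = sum(exon_lens)
    if total < u5 + u3 + 150:  # guarantee a respectable ORF
        exon_lens[-1] += u5 + u3 + 150 - total
        total = sum(exon_lens)
    cds_len = (total - u5 - u3) // 3 * 3
    exons, pos = [], start
    for i, elen in enumerate(exon_lens):
        exons.append(GenomicInterval(seqid, pos, pos + elen - 1, strand))
        pos += elen + (intron_lens[i] if i < n_exons - 1 else 0)
    cds = _carve_cds(exons, strand, u5, cds_len)
    tx = TranscriptModel(f"{gene_id}.t1", gene_id, exons=exons, cds=cds)
    return GeneModel(gene_id, [tx])


def _family_gene(gene_id: str, seqid: str, start: int, strand: str,
                 protein_len: int) -> GeneModel:
    # canonical single-exon structure so family members share exact lengths
    exon = GenomicInterval(seqid, start, start + 45 + 3 * protein_len + 45 - 1,
                           strand)
    cds = [GenomicInterval(seqid, start + 45, start + 45 + 3 * protein_len - 1,
                           strand)]
    tx = TranscriptModel(f"{gene_id}.t1", gene_id, exons=[exon], cds=cds)
    return GeneModel(gene_id, [tx])


def _check_family_plan(cfg: FixtureConfig,
                       planted: list[tuple[str, int]]) -> None:
    """Fail fast if a planted tail would swallow its family's own decile."""
    import math
    for j, acc in enumerate(cfg.family_accessions):
        base = cfg.family_baseline_lengths[j]
        lengths = [base] * cfg.family_size + [l for a, l in planted if a == acc]
        lengths.sort()
        m = len(lengths)
        d1 = lengths[max(1, math.ceil(0.1 * m)) - 1]
        d8 = lengths[max(1, math.ceil(0.8 * m)) - 1]
        want_short = sum(1 for a, l in planted if a == acc and l < base)
        want_long = sum(1 for a, l in planted if a == acc and l > base)
        got_short = sum(1 for l in lengths if l < d1)
        got_long = sum(1 for l in lengths if l > d8)
        if (got_short, got_long) != (want_short, want_long):
            raise AnnotationError(
                f"family {acc}: {want_short}+{want_long} planted outliers "
                f"overwhelm the deciles of a {cfg.family_size}-member family; "
                f"increase family_size or plant fewer outliers")


def generate_annotation(config: FixtureConfig) -> FixtureBundle:
    """Build a complete fixture bundle from a config (see module docstring)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    per_chrom = -(-cfg.n_genes // cfg.n_sequences)

    # --- role assignment over gene indices ------------------------------
    idx = 0

    def take(n):
        nonlocal idx
        block = list(range(idx, idx + n))
        idx += n
        return block

    fusion_pairs_idx = [tuple(take(2)) for _ in range(cfg.n_fusions)]
    fam_idx = {acc: take(cfg.family_size) for acc in cfg.family_accessions}
    outlier_idx = take(cfg.n_family_outliers)
    combo_idx = take(cfg.n_atypical_combinations)
    cds_host_idx = take(cfg.n_antisense_cds_ssogs)
    utr_host_idx = take(cfg.n_antisense_utr_ssogs)
    for a, b in fusion_pairs_idx:
        if a // per_chrom != b // per_chrom:
            raise AnnotationError(
                "fusion pair straddles a sequence boundary; increase n_genes")

    forced_plus = {i for pair in fusion_pairs_idx for i in pair}
    fam_of_idx: dict[int, tuple[str, int]] = {}
    for acc, block in fam_idx.items():
        base = cfg.family_baseline_lengths[
            list(cfg.family_accessions).index(acc)]
        for i in block:
            fam_of_idx[i] = (acc, base)
    # spread outliers over (family, direction) so neither tail of any family
    # holds enough plants to drag its own decile onto the planted value
    n_fam = len(cfg.family_accessions)
    for k, i in enumerate(outlier_idx):
        acc = cfg.family_accessions[k % n_fam]
        base = cfg.family_baseline_lengths[k % n_fam]
        length = base * 3 if (k // n_fam) % 2 == 0 else max(50, base // 3)
        fam_of_idx[i] = (acc, length)
    _check_family_plan(cfg, [fam_of_idx[i] for i in outlier_idx])

    # --- place genes ----------------------------------------------------
    genes: dict[str, GeneModel] = {}
    truth: list[TruthRecord] = []
    family_roles: dict[str, tuple[str, str]] = {}
    combo_plants: dict[str, tuple[str, str]] = {}
    cursors = {f"chr{c + 1}": 1000 for c in range(cfg.n_sequences)}
    gene_ids = []
    for i in range(cfg.n_genes):
        gid = f"g{i + 1:04d}"
        gene_ids.append(gid)
        seqid = f"chr{i // per_chrom + 1}"
        strand = "+" if i in forced_plus else ("+", "-")[int(rng.integers(2))]
        start = cursors[seqid]
        if i in fam_of_idx:
            acc, plen = fam_of_idx[i]
            gene = _family_gene(gid, seqid, start, strand, plen)
            if i in outlier_idx:
                base = cfg.family_baseline_lengths[
                    list(cfg.family_accessions).index(acc)]
                direction = "too-long" if plen > base else "too-short"
                truth.append(TruthRecord(FAMILY_OUTLIER, gid,
                                         f"{acc}:{direction}"))
                family_roles[gid] = (acc, direction)
            else:
                family_roles[gid] = (acc, "baseline")
        else:
            gene = _plain_gene(gid, seqid, start, strand, cfg, rng)
        gap = int(rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1))
        cursors[seqid] = gene.span.end + 1 + gap
        if cursors[seqid] > cfg.chrom_length:
            raise AnnotationError(
                f"cannot pack {cfg.n_genes} genes into {cfg.n_sequences} "
                f"sequences of {cfg.chrom_length} bp")
        genes[gid] = gene

    bundle = FixtureBundle(
        config=cfg,
        annotation=AnnotationSet(genes=dict(sorted(genes.items())),
                                 version_label="synthetic-v1"),
        evidence=AnnotationSet(version_label="synthetic-evidence"),
        truth=truth,
        family_roles=family_roles,
        combo_plants=combo_plants,
    )

    for a, b in fusion_pairs_idx:
        plant_fusion(bundle, (gene_ids[a], gene_ids[b]), _refresh=False)
    for i in cds_host_idx:
        plant_antisense_ssog(bundle, "cds", host_gene=gene_ids[i],
                             _refresh=False)
    for i in utr_host_idx:
        plant_antisense_ssog(bundle, "utr", host_gene=gene_ids[i],
                             _refresh=False)
    for k, i in enumerate(combo_idx):
        pair = (f"PFX{2 * k + 1:04d}", f"PFX{2 * k + 2:04d}")
        plant_atypical_combination(bundle, protein_id=f"{gene_ids[i]}.t1.p",
                                   pair=pair, _refresh=False)
    refresh_bundle(bundle)
    return bundle


# ---------------------------------------------------------------------------
# planting operations


def _adjacent(bundle: FixtureBundle, ga: GeneModel, gb: GeneModel) -> bool:
    if ga.sequence_id != gb.sequence_id or ga.strand != gb.strand:
        return False
    lo, hi = sorted((ga.span.end, gb.span.start))
    lo2, hi2 = min(ga.span.start, gb.span.start), max(ga.span.end, gb.span.end)
    for other in bundle.annotation:
        if other.gene_id in (ga.gene_id, gb.gene_id):
            continue
        if other.sequence_id == ga.sequence_id and \
                other.span.start <= hi2 and other.span.end >= lo2:
            return False
    return True


def plant_fusion(bundle: FixtureBundle, gene_pair: tuple[str, str],
                 _refresh: bool = True) -> FixtureBundle:
    """Merge two adjacent same-strand genes into one artificial fusion."""
    ga = bundle.annotation.genes.get(gene_pair[0])
    gb = bundle.annotation.genes.get(gene_pair[1])
    if ga is None or gb is None:
        raise AnnotationError(f"unknown gene in fusion pair {gene_pair}")
    if not _adjacent(bundle, ga, gb):
        raise AnnotationError(
            f"{gene_pair}: fusion parts must be adjacent and on one strand")
    if ga.span.start > gb.span.start:
        ga, gb = gb, ga
    ta, tb = ga.transcripts[0], gb.transcripts[0]
    fused_id = ga.gene_id
    fused_tx = TranscriptModel(f"{fused_id}.t1", fused_id,
                               exons=list(ta.exons) + list(tb.exons),
                               cds=list(ta.cds) + list(tb.cds))
    genes = dict(bundle.annotation.genes)
    del genes[ga.gene_id], genes[gb.gene_id]
    genes[fused_id] = GeneModel(fused_id, [fused_tx])
    bundle.annotation = AnnotationSet(genes=dict(sorted(genes.items())),
                                      version_label=bundle.annotation.version_label)

    ev_genes = dict(bundle.evidence.genes)
    ev_tids = []
    for part, tx in (("1", ta), ("2", tb)):
        ev_gid = f"{fused_id}.evidence{part}"
        ev_tid = f"{ev_gid}.t1"
        ev_tx = TranscriptModel(ev_tid, ev_gid, exons=list(tx.exons),
                                cds=list(tx.cds))
        ev_genes[ev_gid] = GeneModel(ev_gid, [ev_tx])
        ev_tids.append(ev_tid)
    bundle.evidence = AnnotationSet(genes=dict(sorted(ev_genes.items())),
                                    version_label=bundle.evidence.version_label)

    la, lb = ta.cds_length() // 3, tb.cds_length() // 3
    bundle.fused[fused_id] = (ev_tids[0], ev_tids[1], la, lb)
    bundle.truth.append(TruthRecord(FUSION, fused_id, ",".join(ev_tids)))
    if _refresh:
        refresh_bundle(bundle)
    return bundle


def plant_antisense_ssog(bundle: FixtureBundle, kind: str,
                         host_gene: str | None = None,
                         _refresh: bool = True) -> FixtureBundle:
    """Add a spurious single-exon gene antisense to a host CDS or UTR."""
    if kind not in ("cds", "utr"):
        raise AnnotationError(f"kind must be 'cds' or 'utr', got {kind!r}")
    if host_gene is None:
        host_gene = _pick_host(bundle, kind)
    host = bundle.annotation.genes.get(host_gene)
    if host is None:
        raise AnnotationError(f"unknown host gene {host_gene}")
    tx = host.transcripts[0]
    pool = tx.cds if kind == "cds" else tx.utr5 + tx.utr3
    pool = [iv for iv in pool if len(iv) >= 3]
    if not pool:
        raise AnnotationError(
            f"host {host_gene} has no {kind.upper()} interval to overlap")
    target = max(pool, key=len)
    length = min(len(target) // 3 * 3, 90)
    start = target.start + max(0, (len(target) - length) // 2)
    strand = "-" if host.strand == "+" else "+"
    ssog_id = f"ssog_{host_gene}"
    exon = GenomicInterval(target.sequence_id, start, start + length - 1, strand)
    ssog_tx = TranscriptModel(f"{ssog_id}.t1", ssog_id, exons=[exon],
                              cds=[exon])
    genes = dict(bundle.annotation.genes)
    genes[ssog_id] = GeneModel(ssog_id, [ssog_tx])
    bundle.annotation = AnnotationSet(genes=dict(sorted(genes.items())),
                                      version_label=bundle.annotation.version_label)
    bundle.ssog_kinds[ssog_id] = kind
    defect = ANTISENSE_CDS_SSOG if kind == "cds" else ANTISENSE_UTR_SSOG
    bundle.truth.append(TruthRecord(defect, ssog_id, f"host={host_gene}"))
    if _refresh:
        refresh_bundle(bundle)
    return bundle


def _pick_host(bundle: FixtureBundle, kind: str) -> str:
    used = {t.detail.removeprefix("host=") for t in bundle.truth
            if t.defect in (ANTISENSE_CDS_SSOG, ANTISENSE_UTR_SSOG)}
    for gene in bundle.annotation:
        gid = gene.gene_id
        if gid in used or gid in bundle.ssog_kinds or gid in bundle.fused:
            continue
        tx = gene.transcripts[0]
        pool = tx.cds if kind == "cds" else tx.utr5 + tx.utr3
        if any(len(iv) >= 3 for iv in pool):
            return gid
    raise AnnotationError(f"no suitable host gene for a {kind} antisense SSOG")


def plant_atypical_combination(bundle: FixtureBundle,
                               protein_id: str | None = None,
                               pair: tuple[str, str] | None = None,
                               _refresh: bool = True) -> FixtureBundle:
    """Grant one focal protein a domain pair unknown to reference species."""
    if pair is None:
        k = len(bundle.combo_plants)
        pair = (f"PFX{2 * k + 1:04d}", f"PFX{2 * k + 2:04d}")
    if pair[0] == pair[1]:
        raise AnnotationError("a combination needs two distinct families")
    if protein_id is None:
        taken = set(bundle.combo_plants)
        for gene in bundle.annotation:
            gid = gene.gene_id
            if gid in bundle.ssog_kinds or gid in bundle.family_roles:
                continue
            pid = f"{gene.transcripts[0].transcript_id}.p"
            if pid not in taken:
                protein_id = pid
                break
        else:
            raise AnnotationError("no free protein to plant a combination on")
    bundle.combo_plants[protein_id] = pair
    gene_id = protein_id.split(".t1.p")[0]
    bundle.truth.append(TruthRecord(ATYPICAL_COMBINATION, gene_id,
                                    f"{protein_id}:{pair[0]}+{pair[1]}"))
    if _refresh:
        refresh_bundle(bundle)
    return bundle


# ---------------------------------------------------------------------------
# derivation of downstream inputs


def refresh_bundle(bundle: FixtureBundle) -> FixtureBundle:
    """(Re)derive proteome, orthologs, BLAST, domains, coverage, actions.

    Fully deterministic given the structural state: per-gene draws use
    generators keyed by (seed, gene id), so the derivation order never
    matters.
    """
    cfg = bundle.config
    seed = cfg.seed

    proteins: list[ProteinRecord] = []
    for gene in bundle.annotation:
        tx = gene.transcripts[0]
        length = tx.cds_length() // 3
        proteins.append(ProteinRecord(
            f"{tx.transcript_id}.p", gene.gene_id, length,
            _random_protein(seed, gene.gene_id, length)))
    bundle.proteins = proteins
    by_gene = {p.gene_id: p for p in proteins}

    # ortholog table: every non-SSOG gene has a one-to-one reference ortholog
    pairs, ref_proteins = [], []
    for gene in bundle.annotation:
        gid = gene.gene_id
        if gid in bundle.ssog_kinds:
            continue
        ref_id = f"ceg_{gid}"
        if gid in bundle.fused:
            _, _, la, lb = bundle.fused[gid]
            ref_len = min(la, lb)
        else:
            jitter = _tag_rng(seed, "orth:" + gid).uniform(0.92, 1.08)
            ref_len = max(50, int(round(by_gene[gid].length * jitter)))
        pairs.append((gid, ref_id))
        ref_proteins.append(ProteinRecord(f"{ref_id}.p1", ref_id, ref_len))
    bundle.ortholog_pairs = pairs
    bundle.reference_proteins = ref_proteins

    # BLAST: non-SSOG proteins hit every homology set and the ORF set;
    # SSOG proteins get only one insignificant hit (tests the cutoff).
    hits: list[BlastHit] = []
    for p in proteins:
        if p.gene_id in bundle.ssog_kinds:
            hits.append(BlastHit(p.protein_id, f"weak_{p.protein_id}",
                                 HOMOLOGY_SETS[0], evalue=0.01, bitscore=28.0,
                                 query_start=1, query_end=min(30, p.length),
                                 subject_start=1, subject_end=min(30, p.length)))
            continue
        for sset in HOMOLOGY_SETS:
            hits.append(BlastHit(p.protein_id, f"{sset}_{p.protein_id}", sset,
                                 evalue=1e-50, bitscore=250.0,
                                 query_start=1, query_end=p.length,
                                 subject_start=1, subject_end=p.length))
        hits.append(BlastHit(p.protein_id, f"orf_{p.protein_id}",
                             ORF_SUPPORT_SET, evalue=1e-40, bitscore=200.0,
                             query_start=1, query_end=p.length,
                             subject_start=1, subject_end=p.length))
    bundle.blast_hits = hits

    # domain tables
    focal_hits: list[DomainHit] = []
    for gene in bundle.annotation:
        gid = gene.gene_id
        pid = by_gene[gid].protein_id
        plen = by_gene[gid].length
        if gid in bundle.family_roles:
            acc, _ = bundle.family_roles[gid]
            focal_hits.append(DomainHit(pid, acc, 1e-10, 1, min(60, plen)))
        elif pid in bundle.combo_plants:
            for k, fam in enumerate(bundle.combo_plants[pid]):
                start = 1 + 70 * k
                focal_hits.append(DomainHit(pid, fam, 1e-8, start, start + 59))
        elif gid not in bundle.ssog_kinds:
            fam = VOCAB_FAMILIES[zlib.crc32(gid.encode()) % len(VOCAB_FAMILIES)]
            focal_hits.append(DomainHit(pid, fam, 1e-9, 1, min(60, plen)))
    domain_hits = {FOCAL_SPECIES: focal_hits}
    for sp in DOMAIN_REFERENCE_SPECIES:
        sp_hits = []
        for k, fam in enumerate(VOCAB_FAMILIES):
            sp_hits.append(DomainHit(f"{sp}_p{k + 1}", fam, 1e-12, 1, 60))
        # a few ordinary two-domain proteins so reference censuses are non-trivial
        for k in range(len(VOCAB_FAMILIES) - 1):
            pid2 = f"{sp}_pp{k + 1}"
            sp_hits.append(DomainHit(pid2, VOCAB_FAMILIES[k], 1e-12, 1, 60))
            sp_hits.append(DomainHit(pid2, VOCAB_FAMILIES[k + 1], 1e-12, 70, 130))
        domain_hits[sp] = sp_hits
    bundle.domain_hits = domain_hits

    # strand-specific coverage over every real (non-SSOG) gene's exons
    intervals = []
    for gene in bundle.annotation:
        if gene.gene_id in bundle.ssog_kinds:
            continue
        for iv in gene.transcripts[0].exons:
            intervals.append((iv.sequence_id, iv.start, iv.end, iv.strand, 8.0))
    bundle.coverage = CoverageTrack(sorted(intervals))

    # proposed curation actions implied by the truth table
    actions = []
    for rec in sorted(bundle.truth, key=lambda t: (t.defect, t.gene_id)):
        if rec.defect == FUSION:
            ev1, ev2, _, _ = bundle.fused[rec.gene_id]
            actions.append(CurationAction(rec.gene_id, "replace",
                                          [ev1, ev2], provenance=FUSION))
        elif rec.defect in (ANTISENSE_CDS_SSOG, ANTISENSE_UTR_SSOG):
            actions.append(CurationAction(rec.gene_id, "remove",
                                          provenance=rec.defect))
    bundle.actions = actions
    return bundle


# ---------------------------------------------------------------------------
# serialization


def write_bundle(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every emitted file of the bundle; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": aio.write_gff3(bundle.annotation,
                                     outdir / "annotation.gff3"),
        "evidence": aio.write_gff3(bundle.evidence, outdir / "evidence.gff3"),
        "proteins": aio.write_protein_fasta(bundle.proteins,
                                            outdir / "proteins.faa"),
        "reference_proteins": aio.write_protein_fasta(
            bundle.reference_proteins, outdir / "reference_proteins.faa"),
        "orthologs": aio.write_pair_table(bundle.ortholog_pairs,
                                          outdir / "orthologs.tsv"),
        "actions": aio.write_action_table(bundle.actions,
                                          outdir / "actions.tsv"),
    }
    lengths = {p.protein_id: p.length for p in bundle.proteins}
    for sp, hits in sorted(bundle.domain_hits.items()):
        paths[f"domtbl_{sp}"] = aio.write_domtbl(
            hits, outdir / f"domains_{sp}.domtbl",
            protein_lengths=lengths if sp == FOCAL_SPECIES else None)
    by_set: dict[str, list[BlastHit]] = {}
    for hit in bundle.blast_hits:
        by_set.setdefault(hit.subject_set, []).append(hit)
    for sset in (*HOMOLOGY_SETS, ORF_SUPPORT_SET):
        paths[f"blast_{sset}"] = aio.write_blast_tab(
            by_set.get(sset, []), outdir / f"blast_{sset}.tsv")
    bundle.coverage.to_bed(outdir / "coverage.bed")
    paths["coverage"] = outdir / "coverage.bed"
    truth_lines = ["defect\tgene_id\tdetail"] + [
        f"{t.defect}\t{t.gene_id}\t{t.detail}"
        for t in sorted(bundle.truth, key=lambda t: (t.defect, t.gene_id))]
    (outdir / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
    paths["truth"] = outdir / "truth.tsv"
    return paths
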