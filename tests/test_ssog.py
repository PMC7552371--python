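"""Orphan calling, strand-aware classification and the removal policy."""

import random

import pytest

from annotqc.model import AnnotationError, BlastHit, GenomicInterval, ProteinRecord
from annotqc.ssog import (
    ANTISENSE_CDS,
    ANTISENSE_UTR,
    NO_SUPPORT,
    OTHER,
    SOME_EXPRESSION,
    SUPPORTED,
    CoverageTrack,
    SSOGRecord,
    call_ssogs,
    category_summary,
    classify_all,
    classify_ssog,
    removal_policy,
    round_half_away,
)

from conftest import make_annotation, make_gene

HOMOLOGY = ["nem1", "nem2"]
ORF = ["orfs"]


def blast(query, sset, evalue):
    return BlastHit(query, f"s_{query}", sset, evalue, 50.0)


class TestCalling:
    def test_weak_hits_everywhere_still_an_orphan(self):
        records = call_ssogs([ProteinRecord("p1", "g1", 100)],
                             [blast("p1", "nem1", 0.01),
                              blast("p1", "nem2", 0.5)], HOMOLOGY, ORF)
        assert records[0].is_ssog

    def test_one_significant_hit_disqualifies(self):
        records = call_ssogs([ProteinRecord("p1", "g1", 100)],
                             [blast("p1", "nem2", 1e-5)], HOMOLOGY, ORF)
        assert not records[0].is_ssog

    def test_orf_hit_gives_transcriptomic_support_not_homology(self):
        records = call_ssogs([ProteinRecord("p1", "g1", 100)],
                             [blast("p1", "orfs", 1e-9)], HOMOLOGY, ORF)
        assert records[0].is_ssog and records[0].has_orf_support

    def test_unknown_subject_set_is_an_error(self):
        with pytest.raises(AnnotationError, match="subject_set"):
            call_ssogs([ProteinRecord("p1", "g1", 100)],
                       [blast("p1", "mystery", 1e-9)], HOMOLOGY, ORF)

    def test_matches_brute_force_scan(self):
        rng = random.Random(19)
        proteins = [ProteinRecord(f"p{i}", f"g{i}", 100) for i in range(20)]
        hits = []
        for p in proteins:
            for sset in HOMOLOGY + ORF:
                if rng.random() < 0.5:
                    hits.append(blast(p.protein_id, sset,
                                      rng.choice([1e-8, 1e-2])))
        records = {r.gene_id: r for r in call_ssogs(proteins, hits,
                                                    HOMOLOGY, ORF)}
        for p in proteins:
            expected_orphan = not any(
                h.query_id == p.protein_id and h.subject_set in HOMOLOGY
                and h.evalue < 1e-3 for h in hits)
            expected_orf = any(
                h.query_id == p.protein_id and h.subject_set in ORF
                and h.evalue < 1e-3 for h in hits)
            assert records[p.gene_id].is_ssog == expected_orphan
            assert records[p.gene_id].has_orf_support == expected_orf

    def test_lowering_cutoff_never_shrinks_the_orphan_set(self):
        rng = random.Random(23)
        proteins = [ProteinRecord(f"p{i}", f"g{i}", 100) for i in range(40)]
        hits = [blast(p.protein_id, rng.choice(HOMOLOGY),
                      10 ** rng.uniform(-9, 0)) for p in proteins
                for _ in range(rng.randint(0, 3))]
        previous = None
        for cutoff in (1e-1, 1e-3, 1e-5, 1e-8):
            orphans = {r.gene_id for r in
                       call_ssogs(proteins, hits, HOMOLOGY, ORF, cutoff)
                       if r.is_ssog}
            if previous is not None:
                assert previous <= orphans
            previous = orphans


def unsupported(gene_id):
    return SSOGRecord(gene_id, is_ssog=True, has_orf_support=False)


class TestClassification:
    def host_and_ssog(self, host_strand="+", where="cds"):
        host = make_gene("host", "chr1", 1000, host_strand, cds_len=300,
                        u5=60, u3=60)
        tx = host.transcripts[0]
        target = tx.cds[0] if where == "cds" else tx.utr3[0]
        anti = "-" if host_strand == "+" else "+"
        start = target.start + 5
        exon = GenomicInterval("chr1", start, start + 29, anti)
        from annotqc.model import GeneModel, TranscriptModel
        ssog_gene = GeneModel("orphan", [TranscriptModel(
            "orphan.t1", "orphan", exons=[exon], cds=[exon])])
        return host, ssog_gene

    @pytest.mark.parametrize("host_strand", ["+", "-"])
    def test_antisense_within_cds(self, host_strand):
        host, orphan = self.host_and_ssog(host_strand, "cds")
        ann = make_annotation(host, orphan)
        rec = classify_ssog(unsupported("orphan"), ann)
        assert rec.category == ANTISENSE_CDS
        assert rec.triggering_gene == "host"

    @pytest.mark.parametrize("host_strand", ["+", "-"])
    def test_antisense_within_utr_only(self, host_strand):
        host, orphan = self.host_and_ssog(host_strand, "utr")
        ann = make_annotation(host, orphan)
        rec = classify_ssog(unsupported("orphan"), ann)
        assert rec.category == ANTISENSE_UTR
        assert rec.triggering_gene == "host"

    def test_same_strand_overlap_is_other_never_antisense(self):
        host = make_gene("host", "chr1", 1000, "+", cds_len=300)
        orphan = make_gene("orphan", "chr1", 1100, "+", cds_len=60)
        rec = classify_ssog(unsupported("orphan"),
                            make_annotation(host, orphan))
        assert rec.category == OTHER

    def test_isolated_without_coverage_is_no_support(self):
        orphan = make_gene("orphan", "chr1", 1000, "+", cds_len=90)
        rec = classify_ssog(unsupported("orphan"), make_annotation(orphan))
        assert rec.category == NO_SUPPORT

    def test_some_expression_fraction(self):
        # exon spans 150 bp; 90 covered on its own strand = 60% >= 50%
        orphan = make_gene("orphan", "chr1", 1001, "+", cds_len=90)
        exon = orphan.transcripts[0].exons[0]
        assert len(exon) == 150
        cov = CoverageTrack([("chr1", exon.start, exon.start + 89, "+", 5.0)])
        rec = classify_ssog(unsupported("orphan"), make_annotation(orphan),
                            coverage=cov)
        assert rec.category == SOME_EXPRESSION

    def test_antisense_coverage_does_not_count_as_expression(self):
        orphan = make_gene("orphan", "chr1", 1001, "+", cds_len=90)
        exon = orphan.transcripts[0].exons[0]
        cov = CoverageTrack([("chr1", exon.start, exon.end, "-", 5.0)])
        rec = classify_ssog(unsupported("orphan"), make_annotation(orphan),
                            coverage=cov)
        assert rec.category == NO_SUPPORT

    def test_supported_record_is_rejected(self):
        with pytest.raises(AnnotationError):
            classify_ssog(SSOGRecord("g", is_ssog=True, has_orf_support=True),
                          make_annotation())

    def test_partition_on_synthetic_study(self, defect_bundle):
        b = defect_bundle
        from annotqc.simulate import HOMOLOGY_SETS, ORF_SUPPORT_SET
        records = call_ssogs(b.proteins, b.blast_hits, list(HOMOLOGY_SETS),
                             [ORF_SUPPORT_SET])
        classified = classify_all([r for r in records if r.is_ssog],
                                  b.annotation, b.coverage)
        assert all(r.category in (SUPPORTED, NO_SUPPORT, SOME_EXPRESSION,
                                  ANTISENSE_CDS, ANTISENSE_UTR, OTHER)
                   for r in classified)
        summary = category_summary(classified)
        assert sum(v["count"] for v in summary.values()) == len(classified)


class TestPolicyAndSummary:
    def test_one_record_per_removable_category(self):
        records = [SSOGRecord(f"g{i}", True, False, category=c)
                   for i, c in enumerate([NO_SUPPORT, ANTISENSE_CDS,
                                          ANTISENSE_UTR])]
        actions = removal_policy(records)
        assert [a.action for a in actions] == ["remove"] * 3

    def test_expression_and_other_are_kept(self):
        records = [SSOGRecord("g1", True, False, category=SOME_EXPRESSION),
                   SSOGRecord("g2", True, True, category=SUPPORTED),
                   SSOGRecord("g3", True, False, category=OTHER)]
        assert [a.action for a in removal_policy(records)] == ["keep"] * 3

    def test_mixed_table_equals_row_wise_lookup(self):
        rng = random.Random(2)
        cats = [NO_SUPPORT, SOME_EXPRESSION, ANTISENSE_CDS, ANTISENSE_UTR,
                OTHER, SUPPORTED]
        records = [SSOGRecord(f"g{i}", True, False,
                              category=rng.choice(cats)) for i in range(12)]
        lookup = {NO_SUPPORT: "remove", ANTISENSE_CDS: "remove",
                  ANTISENSE_UTR: "remove", SOME_EXPRESSION: "keep",
                  SUPPORTED: "keep", OTHER: "keep"}
        assert [a.action for a in removal_policy(records)] == \
               [lookup[r.category] for r in records]

    def test_printed_share_rounding(self):
        records = ([SSOGRecord(f"a{i}", True, False, category=ANTISENSE_CDS)
                    for i in range(704)] +
                   [SSOGRecord(f"u{i}", True, False, category=ANTISENSE_UTR)
                    for i in range(46)] +
                   [SSOGRecord(f"n{i}", True, False, category=NO_SUPPORT)
                    for i in range(924)])
        summary = category_summary(records)
        assert summary[ANTISENSE_CDS] == {"count": 704, "percent": 42}
        assert summary[ANTISENSE_UTR] == {"count": 46, "percent": 3}

    def test_empty_summary(self):
        assert category_summary([]) == {}

    def test_round_half_away_from_zero(self):
        assert [round_half_away(x) for x in (0.5, 1.5, 2.4, -0.5)] == \
               [1, 2, 2, -1]
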