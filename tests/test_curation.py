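"""Action application, the gene-count conservation law, and statistics."""

import random

import pytest

from annotqc.curation import (
    CurationAction,
    annotation_stats,
    apply_actions,
    assign_alignments,
    rescreen_delta,
    screen_overlap_report,
)
from annotqc.model import (
    AnnotationError,
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)

from conftest import make_annotation, make_gene


def simple_annotation(n=10):
    return make_annotation(*[
        make_gene(f"g{i:02d}", "chr1", 1000 + 2000 * i, "+", cds_len=300)
        for i in range(n)])


def evidence_with(*tids):
    genes = []
    for k, tid in enumerate(tids):
        g = make_gene(f"ev{k}", "chr1", 500 + 1000 * k, "+", cds_len=150)
        tx = g.transcripts[0]
        tx.transcript_id = tid
        genes.append(g)
    return make_annotation(*genes, version="evidence")


class TestApplyActions:
    def test_remove_deletes_one_gene(self):
        out = apply_actions(simple_annotation(10),
                            [CurationAction("g03", "remove")])
        assert len(out) == 9 and "g03" not in out.genes

    def test_replace_splits_a_fused_model(self):
        ev = evidence_with("ta", "tb")
        out = apply_actions(simple_annotation(10),
                            [CurationAction("g03", "replace", ["ta", "tb"])],
                            ev)
        assert len(out) == 11
        assert "g03" not in out.genes
        assert {"g03.split1", "g03.split2"} <= set(out.genes)
        assert out.genes["g03.split1"].attributes["curation_source"] == "g03"

    def test_all_keep_is_the_identity(self):
        ann = simple_annotation(8)
        out = apply_actions(ann, [CurationAction(g, "keep")
                                  for g in ann.genes])
        assert ann.structurally_equal(out)

    def test_conservation_law_on_random_action_sets(self):
        rng = random.Random(6)
        ev = evidence_with(*[f"t{i}" for i in range(12)])
        for _ in range(20):
            ann = simple_annotation(15)
            gene_ids = list(ann.genes)
            rng.shuffle(gene_ids)
            n_remove = rng.randint(0, 5)
            n_replace = rng.randint(0, 4)
            actions, sizes = [], []
            pool = [f"t{i}" for i in range(12)]
            for gid in gene_ids[:n_remove]:
                actions.append(CurationAction(gid, "remove"))
            for gid in gene_ids[n_remove:n_remove + n_replace]:
                size = rng.randint(1, 3)
                sizes.append(size)
                actions.append(CurationAction(gid, "replace",
                                              rng.sample(pool, size)))
            out = apply_actions(ann, actions, ev)
            assert len(out) == 15 - n_remove - n_replace + sum(sizes)

    def test_duplicate_actions_are_an_error(self):
        with pytest.raises(AnnotationError, match="duplicate"):
            apply_actions(simple_annotation(3),
                          [CurationAction("g00", "keep"),
                           CurationAction("g00", "remove")])

    def test_unknown_gene_is_an_error(self):
        with pytest.raises(AnnotationError, match="unknown gene"):
            apply_actions(simple_annotation(3),
                          [CurationAction("ghost", "remove")])

    def test_dangling_replacement_is_an_error(self):
        with pytest.raises(AnnotationError, match="not in evidence"):
            apply_actions(simple_annotation(3),
                          [CurationAction("g00", "replace", ["ghost.t1"])],
                          evidence_with("real.t1"))


class TestStats:
    def test_isoform_cds_union_not_sum(self):
        tx1 = TranscriptModel("t1", "g", exons=[
            GenomicInterval("chr1", 1, 500, "+")],
            cds=[GenomicInterval("chr1", 1, 300, "+")])
        tx2 = TranscriptModel("t2", "g", exons=[
            GenomicInterval("chr1", 1, 500, "+")],
            cds=[GenomicInterval("chr1", 201, 500, "+")])
        ann = make_annotation(GeneModel("g", [tx1, tx2]))
        assert annotation_stats(ann).coding_mb == pytest.approx(500 / 1e6)

    def test_empty_annotation(self):
        stats = annotation_stats(AnnotationSet())
        assert (stats.n_genes, stats.coding_mb) == (0, 0.0)

    def test_disjoint_cds_arithmetic(self):
        # UTR-less genes: the CDS occupies the whole 150 bp exon
        genes = [make_gene(f"g{i:04d}", f"chr{i % 4}", 1000 + 3000 * (i // 4),
                           "+", cds_len=150, u5=0, u3=0)
                 for i in range(1000)]
        ann = make_annotation(*genes)
        stats = annotation_stats(ann)
        assert stats.n_genes == 1000
        assert stats.coding_mb == pytest.approx(0.15)

    def test_splitting_a_cds_interval_preserves_coding_mb(self):
        whole = TranscriptModel("t1", "g1", exons=[
            GenomicInterval("chr1", 1, 600, "+")],
            cds=[GenomicInterval("chr1", 101, 400, "+")])
        split = TranscriptModel("t2", "g2", exons=[
            GenomicInterval("chr2", 1, 600, "+")],
            cds=[GenomicInterval("chr2", 101, 250, "+"),
                 GenomicInterval("chr2", 251, 400, "+")])
        a = make_annotation(GeneModel("g1", [whole]))
        b = make_annotation(GeneModel("g2", [split]))
        assert annotation_stats(a).coding_mb == annotation_stats(b).coding_mb


class TestRescreenDelta:
    def test_printed_candidate_declines(self):
        before = annotation_stats(AnnotationSet(),
                                  {"length": 532, "domains": 1589})
        after = annotation_stats(AnnotationSet(),
                                 {"length": 265, "domains": 1137})
        table = rescreen_delta(before, after)
        assert table["length"]["percent_change"] == pytest.approx(-50.2, abs=0.05)
        assert table["domains"]["percent_change"] == pytest.approx(-28.4, abs=0.05)
        assert table["length"]["direction"] == "down"

    def test_equal_stats_give_zero_deltas(self):
        s = annotation_stats(AnnotationSet(), {"a": 7})
        table = rescreen_delta(s, s)
        assert table["a"]["change"] == 0
        assert table["a"]["percent_change"] == 0.0

    def test_key_mismatch_is_an_error(self):
        a = annotation_stats(AnnotationSet(), {"a": 1})
        b = annotation_stats(AnnotationSet(), {"b": 1})
        with pytest.raises(AnnotationError):
            rescreen_delta(a, b)


class TestAssignability:
    def aln(self, start, end, seq="chr1"):
        return GenomicInterval(seq, start, end, "+")

    def test_all_within_one_gene(self):
        ann = make_annotation(make_gene("g1", "chr1", 1000, "+", cds_len=300))
        alns = [self.aln(1000 + i * 10, 1050 + i * 10) for i in range(5)]
        assert assign_alignments(alns, ann) == 100.0

    def test_spanning_two_genes_is_ambiguous(self):
        g1 = make_gene("g1", "chr1", 1000, "+", cds_len=300)
        g2 = make_gene("g2", "chr1", 1400, "-", cds_len=300)
        ann = make_annotation(g1, g2)
        assert assign_alignments([self.aln(1300, 1450)], ann) == 0.0

    def test_mixed_population_arithmetic(self):
        g1 = make_gene("g1", "chr1", 1000, "+", cds_len=300)
        g2 = make_gene("g2", "chr1", 2000, "+", cds_len=300)
        ann = make_annotation(g1, g2)
        exonic = [self.aln(1010, 1060)] * 50
        intergenic = [self.aln(5000, 5050)] * 30
        ambiguous = [self.aln(1300, 2010)] * 20
        assert assign_alignments(exonic + intergenic + ambiguous, ann) == 50.0

    def test_empty_input_is_an_error(self):
        with pytest.raises(AnnotationError):
            assign_alignments([], AnnotationSet())

    def test_adding_intergenic_alignments_lowers_the_rate(self):
        ann = make_annotation(make_gene("g1", "chr1", 1000, "+", cds_len=300))
        exonic = [self.aln(1010, 1060)] * 10
        with_noise = exonic + [self.aln(9000, 9050)] * 3
        assert assign_alignments(with_noise, ann) < \
               assign_alignments(exonic, ann)


class TestOverlapReport:
    def test_disjoint_sets(self):
        report = screen_overlap_report({"a": {"x", "y", "z"},
                                        "b": {"u", "v", "w", "s", "t"}})
        assert report["specific"] == {"a": 3, "b": 5}
        assert report["union_size"] == 8

    def test_identical_sets_have_no_specific_candidates(self):
        report = screen_overlap_report({"a": {"x", "y"}, "b": {"x", "y"}})
        assert report["specific"] == {"a": 0, "b": 0}
        assert report["patterns"] == {("a", "b"): 2}

    def test_three_random_sets_match_brute_force(self):
        rng = random.Random(44)
        universe = [f"g{i}" for i in range(60)]
        sets = {name: {g for g in universe if rng.random() < 0.4}
                for name in ("s1", "s2", "s3")}
        report = screen_overlap_report(sets)
        for gid in set().union(*sets.values()):
            pattern = tuple(sorted(n for n, ids in sets.items() if gid in ids))
            assert report["patterns"][pattern] >= 1
        assert sum(report["patterns"].values()) == report["union_size"]
        for name in sets:
            expected = sum(1 for g in sets[name]
                           if not any(g in sets[o] for o in sets if o != name))
            assert report["specific"][name] == expected
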