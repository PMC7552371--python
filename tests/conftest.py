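import pytest

from annotqc.model import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)
from annotqc.simulate import FixtureConfig, generate_annotation


def make_gene(gene_id, seqid, start, strand, cds_len, u5=30, u3=30,
              n_transcripts=1):
    """A single-exon gene with explicit UTR and CDS lengths (helper)."""
    exon_len = u5 + cds_len + u3
    transcripts = []
    for k in range(n_transcripts):
        exon = GenomicInterval(seqid, start, start + exon_len - 1, strand)
        if strand == "+":
            cds = GenomicInterval(seqid, start + u5, start + u5 + cds_len - 1,
                                  strand)
        else:
            cds = GenomicInterval(seqid, start + u3, start + u3 + cds_len - 1,
                                  strand)
        transcripts.append(TranscriptModel(f"{gene_id}.t{k + 1}", gene_id,
                                           exons=[exon], cds=[cds]))
    return GeneModel(gene_id, transcripts)


def make_annotation(*genes, version="test"):
    return AnnotationSet(genes={g.gene_id: g for g in genes},
                         version_label=version)


@pytest.fixture(scope="session")
def clean_bundle():
    """A defect-free synthetic study."""
    return generate_annotation(FixtureConfig(seed=5, n_genes=80))


@pytest.fixture(scope="session")
def defect_bundle():
    """A synthetic study with a few defects of every class."""
    cfg = FixtureConfig(seed=11, n_genes=120, n_fusions=2,
                        n_antisense_cds_ssogs=2, n_antisense_utr_ssogs=1,
                        n_family_outliers=2, n_atypical_combinations=2)
    return generate_annotation(cfg)
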