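import pytest

from spliceatlas.annotation_io import ExonInterval, GeneModel, TranscriptModel
from spliceatlas.synthetic_data import (
    SyntheticConfig,
    generate_accession,
    generate_reference,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=42, n_genes=30)


@pytest.fixture(scope="session")
def reference_dataset(small_config):
    """(genomes, genes, truth) for a moderate two-chromosome simulation."""
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def accession_dataset(small_config, reference_dataset):
    genomes, genes, truth = reference_dataset
    return generate_accession(small_config, genomes, genes, truth)


def make_transcript(
    tid="t1",
    gene="g1",
    seqid="chr1",
    strand="+",
    exons=((1, 100), (201, 300)),
    cds=((50, 100), (201, 250)),
    utrs=(),
):
    return TranscriptModel(
        transcript_id=tid,
        parent_gene=gene,
        seqid=seqid,
        strand=strand,
        exons=[ExonInterval(s, e, "exon") for s, e in exons],
        cds_parts=[ExonInterval(s, e, "CDS") for s, e in cds],
        utr_parts=[ExonInterval(s, e, k) for s, e, k in utrs],
    )


def make_gene(gene_id="g1", seqid="chr1", strand="+", transcripts=None, **kw):
    if transcripts is None:
        transcripts = [make_transcript(gene=gene_id, seqid=seqid, strand=strand, **kw)]
    return GeneModel(gene_id, seqid, strand, transcripts)
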