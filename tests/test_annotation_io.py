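"""Format I/O: FASTA normalization, GFF3 hierarchy assembly and round trip,
coordinate conventions for PSL, tabular hit parsing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spliceatlas import annotation_io as aio
from spliceatlas.annotation_io import (
    AnnotationError,
    FormatError,
    GenomeSequence,
    extract_subsequence,
    read_fasta,
    read_gff3,
    read_psl,
    read_tabular_hits,
    reverse_complement,
    write_gff3,
    write_psl,
)

# ---------------------------------------------------------------------------
# FASTA


def test_fasta_normalizes_case_and_iupac(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">chr1 some description\nacgT\n")
    (rec,) = read_fasta(p)
    assert rec.seqid == "chr1"
    assert rec.residues == "ACGT"
    assert rec.length == 4

    p.write_text(">a\nACRT\n")
    (rec,) = read_fasta(p)
    assert rec.residues == "ACNT"  # ambiguity codes collapse to N


def test_fasta_rejects_duplicate_seqid_and_empty_file(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">a\nACGT\n>a\nGGGG\n")
    with pytest.raises(FormatError, match="a"):
        read_fasta(p)
    p.write_text("")
    with pytest.raises(FormatError):
        read_fasta(p)


# ---------------------------------------------------------------------------
# GFF3

TOY_GFF3 = """##gff-version 3
chr1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=g1.1;Parent=g1
chr1\tsrc\texon\t1\t100\t.\t+\t.\tParent=g1.1
chr1\tsrc\texon\t201\t300\t.\t+\t.\tParent=g1.1
chr1\tsrc\tCDS\t50\t100\t.\t+\t0\tParent=g1.1
chr1\tsrc\tCDS\t201\t250\t.\t+\t1\tParent=g1.1
"""


def test_gff3_toy_gene_arithmetic(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(TOY_GFF3)
    (gene,) = read_gff3(p)
    (t,) = gene.transcripts
    assert t.exon_count == 2
    assert t.cds_length == 101  # 51 + 50


def test_gff3_round_trip_on_simulated_annotation(tmp_path, reference_dataset):
    _, genes, _ = reference_dataset
    p = tmp_path / "out.gff3"
    write_gff3(genes, p)
    assert read_gff3(p) == genes


def test_gff3_missing_parent_is_an_error(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=m1;Parent=geneX\n"
    )
    with pytest.raises(AnnotationError, match="geneX"):
        read_gff3(p)


def test_gff3_cds_outside_exon_names_transcript(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1\t300\t.\t+\t.\tID=g1\n"
        "chr1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=g1.1;Parent=g1\n"
        "chr1\tsrc\texon\t1\t100\t.\t+\t.\tParent=g1.1\n"
        "chr1\tsrc\tCDS\t90\t150\t.\t+\t.\tParent=g1.1\n"
    )
    with pytest.raises(AnnotationError, match="g1.1"):
        read_gff3(p)


def test_gff3_unknown_feature_types_are_skipped(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(TOY_GFF3 + "chr1\tsrc\tlnc_RNA\t400\t500\t.\t+\t.\tID=x1\n")
    (gene,) = read_gff3(p)
    assert gene.gene_id == "g1"


def test_write_gff3_empty_and_single_exon(tmp_path, small_config):
    p = tmp_path / "empty.gff3"
    write_gff3([], p)
    assert p.read_text() == "##gff-version 3\n"

    from conftest import make_gene

    gene = make_gene(exons=((10, 90),), cds=((10, 90),))
    p2 = tmp_path / "one.gff3"
    write_gff3([gene], p2)
    rows = [l for l in p2.read_text().splitlines() if not l.startswith("#")]
    assert [r.split("\t")[2] for r in rows] == ["gene", "mRNA", "exon", "CDS"]


# ---------------------------------------------------------------------------
# extract_subsequence


def test_extract_subsequence_examples():
    g = GenomeSequence("s", "AACGTT")
    assert extract_subsequence(g, 2, 4, "+") == "ACG"
    assert extract_subsequence(g, 2, 4, "-") == "CGT"
    with pytest.raises(AnnotationError):
        extract_subsequence(g, 0, 4, "+")
    with pytest.raises(AnnotationError):
        extract_subsequence(g, 3, 7, "+")


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.data())
def test_minus_strand_is_reverse_complement_of_plus(data):
    seq = data.draw(st.text(alphabet="ACGTN", min_size=1, max_size=60))
    g = GenomeSequence("s", seq)
    a = data.draw(st.integers(1, g.length))
    b = data.draw(st.integers(a, g.length))
    assert extract_subsequence(g, a, b, "-") == reverse_complement(
        extract_subsequence(g, a, b, "+")
    )
    assert len(extract_subsequence(g, a, b, "+")) == b - a + 1


# ---------------------------------------------------------------------------
# PSL


def _psl_row(
    matches=50, mismatches=0, strand="+", qname="q1", qsize=50,
    tname="t1", tsize=1000, sizes=(50,), qstarts=(0,), tstarts=(100,),
):
    qstart, qend = qstarts[0], qstarts[-1] + sizes[-1]
    tstart, tend = tstarts[0], tstarts[-1] + sizes[-1]
    return "\t".join(
        str(x)
        for x in [
            matches, mismatches, 0, 0, 0, 0, 0, 0, strand, qname, qsize,
            qstart, qend, tname, tsize, tstart, tend, len(sizes),
            ",".join(map(str, sizes)) + ",",
            ",".join(map(str, qstarts)) + ",",
            ",".join(map(str, tstarts)) + ",",
        ]
    )


def test_psl_zero_based_conversion(tmp_path):
    p = tmp_path / "a.psl"
    p.write_text(_psl_row() + "\n")
    (a,) = read_psl(p)
    assert a.blocks == ((101, 150, 1, 50),)  # tStart 100 size 50 -> [101..150]


def test_psl_tolerates_headers_and_rejects_bad_column_count(tmp_path):
    p = tmp_path / "a.psl"
    p.write_text(
        "psLayout version 3\n\nmatch\tmis-\n---------------\n" + _psl_row() + "\n"
    )
    assert len(read_psl(p)) == 1
    p.write_text("\t".join(["10"] * 11) + "\n")
    with pytest.raises(FormatError, match="line 1"):
        read_psl(p)


def test_psl_round_trip_including_minus_strand(tmp_path, reference_dataset, accession_dataset):
    from spliceatlas.synthetic_data import emit_true_alignments

    genomes, genes, _ = reference_dataset
    acc_genomes, _ = accession_dataset
    alns = emit_true_alignments(genes, genomes, acc_genomes)
    assert {a.strand for a in alns} == {"+", "-"}
    p = tmp_path / "a.psl"
    write_psl(alns, {g.seqid: g.length for g in acc_genomes}, p)
    assert read_psl(p) == alns


# ---------------------------------------------------------------------------
# tabular hits


def test_tabular_hits_parse_and_errors(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("q1\ts1\t97.0\t500\t10\t2\t1\t500\t1\t500\t1e-50\t200\n")
    (h,) = read_tabular_hits(p)
    assert h.bitscore == 200
    assert h.evalue == 1e-50
    assert h.percent_identity == 97.0

    p.write_text("q1\ts1\t97.0\t500\t10\t2\t1\t500\t1\t500\t1e-50\n")
    with pytest.raises(FormatError, match="line 1"):
        read_tabular_hits(p)


def test_tabular_hits_round_trip(tmp_path):
    hits = [
        aio.TabularHit("q1", "s1", 97.0, 500, 10, 2, 1, 500, 1, 500, 1e-50, 200.0),
        aio.TabularHit("q2", "s2", 88.5, 120, 4, 0, 1, 120, 7, 126, 0.0, 55.0),
    ]
    p = tmp_path / "hits.tsv"
    aio.write_tabular_hits(hits, p)
    assert read_tabular_hits(p) == hits
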