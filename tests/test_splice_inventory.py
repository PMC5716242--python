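"""Intron extraction, donor/acceptor classification, inventory counts and
the non-canonical gene summaries."""

import pytest
from conftest import make_gene, make_transcript

from spliceatlas.annotation_io import AnnotationError, GenomeSequence
from spliceatlas.splice_inventory import (
    AMBIGUOUS,
    AT_AC,
    CANONICAL_GT_AG,
    GC_AG,
    OTHER,
    build_inventory,
    classify_splice_pair,
    extract_introns,
    format_class_percentages,
    format_percentage,
    select_representative_transcript,
    summarize_noncanonical_genes,
)
from spliceatlas.synthetic_data import (
    SyntheticConfig,
    expected_class_counts,
    generate_reference,
    reverse_complement_dataset,
)

# ---------------------------------------------------------------------------
# representative transcript


def test_representative_is_longest_cds_with_lexicographic_ties():
    t_short = make_transcript(tid="g1.9", cds=((1, 300),), exons=((1, 400),))
    t_long = make_transcript(tid="g1.5", cds=((1, 450),), exons=((1, 500),))
    gene = make_gene(transcripts=[t_short, t_long])
    assert select_representative_transcript(gene).transcript_id == "g1.5"

    tie_a = make_transcript(tid="g1.2", cds=((1, 450),), exons=((1, 500),))
    tie_b = make_transcript(tid="g1.1", cds=((1, 450),), exons=((1, 500),))
    gene = make_gene(transcripts=[tie_a, tie_b])
    assert select_representative_transcript(gene).transcript_id == "g1.1"

    single = make_gene(transcripts=[t_long])
    assert select_representative_transcript(single) is t_long


def test_representative_requires_a_coding_transcript():
    nc = make_transcript(tid="g1.1", cds=(), exons=((1, 100),))
    gene = make_gene(transcripts=[nc])
    with pytest.raises(AnnotationError, match="g1"):
        select_representative_transcript(gene)


# ---------------------------------------------------------------------------
# intron extraction

# positions 11-12 hold GT, 19-20 hold AG on the forward strand
PLUS_GENOME = GenomeSequence("chr1", "AAAAAAAAAA" + "GTCCCCCCAG" + "AAAAAAAAAA")
# positions 11-12 hold CT, 19-20 hold AC: revcomp gives donor GT, acceptor AG
MINUS_GENOME = GenomeSequence("chr1", "AAAAAAAAAA" + "CTCCCCCCAC" + "AAAAAAAAAA")


def test_extract_introns_plus_strand():
    t = make_transcript(exons=((1, 10), (21, 30)), cds=((1, 10),))
    (intron,) = extract_introns(t, PLUS_GENOME)
    assert (intron.start, intron.end) == (11, 20)
    assert (intron.donor, intron.acceptor) == ("GT", "AG")
    assert intron.ordinal == 1


def test_extract_introns_minus_strand_reads_reverse_complement():
    t = make_transcript(strand="-", exons=((1, 10), (21, 30)), cds=((1, 10),))
    (intron,) = extract_introns(t, MINUS_GENOME)
    assert (intron.donor, intron.acceptor) == ("GT", "AG")


def test_minus_strand_ordinals_count_from_five_prime_end():
    t = make_transcript(
        strand="-",
        exons=((1, 10), (21, 30), (41, 50)),
        cds=((1, 10),),
    )
    genome = GenomeSequence("chr1", "A" * 50)
    introns = extract_introns(t, genome)
    assert [(i.ordinal, i.start) for i in introns] == [(1, 31), (2, 11)]


def test_single_exon_transcript_has_no_introns():
    t = make_transcript(exons=((1, 30),), cds=((1, 30),))
    assert extract_introns(t, PLUS_GENOME) == []


def test_short_inter_exon_gap_is_an_error():
    t = make_transcript(exons=((1, 10), (13, 30)), cds=((1, 10),))
    with pytest.raises(AnnotationError, match="gap"):
        extract_introns(t, PLUS_GENOME)


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize(
    "donor,acceptor,label",
    [
        ("GT", "AG", CANONICAL_GT_AG),
        ("GC", "AG", GC_AG),
        ("AT", "AC", AT_AC),
        ("GA", "AG", OTHER),  # the AGY1/PPI1-style pair
        ("GC", "CT", OTHER),  # the FGT1-style pair
        ("NT", "AG", AMBIGUOUS),
        ("GT", "NN", AMBIGUOUS),
    ],
)
def test_classify_splice_pair(donor, acceptor, label):
    cls = classify_splice_pair(donor, acceptor)
    assert cls.label == label
    assert cls.pair == f"{donor}-{acceptor}"


def test_classify_rejects_bad_dinucleotides():
    with pytest.raises(AnnotationError):
        classify_splice_pair("G", "AG")
    with pytest.raises(AnnotationError):
        classify_splice_pair("GX", "AG")


# ---------------------------------------------------------------------------
# inventory


def _toy_inventory_dataset():
    # one gene on +: introns GT-AG, GT-AG; one gene on +: intron GC-AG
    seq = (
        "A" * 10 + "GT" + "C" * 6 + "AG"  # 11..20
        + "A" * 10 + "GT" + "C" * 6 + "AG"  # 31..40
        + "A" * 10 + "GC" + "C" * 6 + "AG"  # 51..60
        + "A" * 10
    )
    genome = GenomeSequence("chr1", seq)
    g1 = make_gene(
        gene_id="g1",
        exons=((1, 10), (21, 30), (41, 50)),
        cds=((1, 10), (21, 30)),
    )
    g2 = make_gene(gene_id="g2", exons=((41, 50), (61, 70)), cds=((41, 50),))
    return [g1, g2], [genome]


def test_build_inventory_counts_pairs_and_flags_genes():
    genes, genomes = _toy_inventory_dataset()
    inv = build_inventory(genes, genomes)
    assert inv.total_introns == 3
    assert inv.per_pair_counts == {"GT-AG": 2, "GC-AG": 1}
    assert inv.distinct_pair_count == 2
    assert inv.noncanonical_gene_ids == {"g2"}  # GC-AG flags under default policy
    strict = build_inventory(genes, genomes, noncanonical_policy="strict")
    assert strict.noncanonical_gene_ids == set()


def test_inventory_matches_generator_bookkeeping_exactly():
    cfg = SyntheticConfig(
        seed=7,
        n_genes=25,
        class_mix={"canonical_gt_ag": 0.85, "gc_ag": 0.08, "at_ac": 0.04, "other": 0.03},
    )
    genomes, genes, truth = generate_reference(cfg)
    for scope in ("representative_only", "all_isoforms"):
        inv = build_inventory(genes, genomes, scope)
        expected = expected_class_counts(truth, scope)
        observed = {k: v for k, v in inv.class_counts.items() if v}
        assert observed == expected


def test_all_isoforms_scope_never_shrinks_the_inventory(reference_dataset):
    genomes, genes, _ = reference_dataset
    rep = build_inventory(genes, genomes, "representative_only")
    allscope = build_inventory(genes, genomes, "all_isoforms")
    assert allscope.total_introns >= rep.total_introns
    assert allscope.noncanonical_gene_ids >= rep.noncanonical_gene_ids


def test_strand_symmetry_of_inventory(reference_dataset):
    genomes, genes, _ = reference_dataset
    rc_genomes, rc_genes = reverse_complement_dataset(genomes, genes)
    inv = build_inventory(genes, genomes, "all_isoforms")
    rc_inv = build_inventory(rc_genes, rc_genomes, "all_isoforms")
    assert inv.per_pair_counts == rc_inv.per_pair_counts
    assert inv.class_counts == rc_inv.class_counts
    assert inv.noncanonical_gene_ids == rc_inv.noncanonical_gene_ids


def test_isoform_scope_can_flag_extra_genes():
    # representative all GT-AG; the second isoform skips the middle exon,
    # creating a merged GT-AC intron (class "other")
    seq = (
        "A" * 10 + "GT" + "C" * 6 + "AG"  # intron 1: 11..20
        + "A" * 10 + "AT" + "C" * 6 + "AC"  # intron 2: 31..40 (AT-AC)
        + "A" * 10
    )
    genome = GenomeSequence("chr1", seq)
    full = make_transcript(
        tid="g1.1", exons=((1, 10), (21, 30), (41, 50)), cds=((1, 10), (21, 30), (41, 50))
    )
    skipping = make_transcript(tid="g1.2", exons=((1, 10), (41, 50)), cds=((1, 10),))
    gene = make_gene(transcripts=[full, skipping])
    # the full isoform carries the AT-AC intron, so use strict policy off it:
    rep = build_inventory([gene], [genome], "representative_only")
    allscope = build_inventory([gene], [genome], "all_isoforms")
    assert "GT-AC" not in rep.per_pair_counts
    assert allscope.per_pair_counts["GT-AC"] == 1


# ---------------------------------------------------------------------------
# percentages and summaries


@pytest.mark.parametrize(
    "count,total,decimals,expected",
    [
        (117732, 119097, 1, "98.9"),
        (66, 135356, 2, "0.05"),
        (0, 10, 1, "0.0"),
        (1, 800, 1, "0.1"),  # half-up: 0.125 -> 0.1
        (1, 400, 1, "0.3"),  # half-up: 0.25 -> 0.3
    ],
)
def test_format_percentage_half_up(count, total, decimals, expected):
    assert format_percentage(count, total, decimals) == expected


def test_format_class_percentages_requires_introns():
    genes, genomes = _toy_inventory_dataset()
    inv = build_inventory(genes, genomes)
    assert format_class_percentages(inv)[CANONICAL_GT_AG] == "66.7"
    with pytest.raises(AnnotationError):
        format_percentage(1, 0)


def test_noncanonical_summary_orders_exon_counts():
    cfg = SyntheticConfig(
        seed=11,
        n_genes=40,
        class_mix={"canonical_gt_ag": 0.9, "gc_ag": 0.06, "at_ac": 0.02, "other": 0.02},
        noncanonical_in_rich_genes=True,
    )
    genomes, genes, truth = generate_reference(cfg)
    subset, everyone = summarize_noncanonical_genes(genes, genomes)
    assert subset.gene_count < everyone.gene_count
    assert subset.median_exon_count >= everyone.median_exon_count


def test_summary_median_conventions():
    from spliceatlas.splice_inventory import _summary

    t1 = make_transcript(tid="a", exons=((1, 4),), cds=((1, 4),))
    t2 = make_transcript(tid="b", exons=((1, 6),), cds=((1, 6),))
    s = _summary([t1, t2])
    assert s.median_transcript_length == 5  # even count: mean of central pair
    with pytest.raises(AnnotationError):
        _summary([])
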