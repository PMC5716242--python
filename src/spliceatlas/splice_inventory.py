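"""Intron extraction, donor/acceptor classification and inventory building.

An intron is the gap between two consecutive exons of a transcript. Its
donor is the first dinucleotide and its acceptor the last dinucleotide of
the intron, both read 5'->3' in transcript orientation, so on the minus
strand they are reverse complements of the genomic termini. Introns are
derived from exon gaps (not CDS gaps): introns spanning UTRs count, because
they are spliced out of the primary transcript like any other.

Class labels follow the standard U2/U12 terminology: canonical GT-AG, the
minor GC-AG and AT-AC classes, "other" for every remaining N-free pair, and
"ambiguous" when either dinucleotide contains an N (missing evidence, never
counted as non-canonical).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .annotation_io import (
    AnnotationError,
    GeneModel,
    GenomeSequence,
    TranscriptModel,
    extract_subsequence,
)

CANONICAL_GT_AG = "canonical_gt_ag"
GC_AG = "gc_ag"
AT_AC = "at_ac"
OTHER = "other"
AMBIGUOUS = "ambiguous"

CLASS_LABELS = (CANONICAL_GT_AG, GC_AG, AT_AC, OTHER, AMBIGUOUS)

#: which class labels flag a gene as "non-canonical"
NONCANONICAL_POLICIES = {
    "default": frozenset({GC_AG, AT_AC, OTHER}),
    "strict": frozenset({AT_AC, OTHER}),
}

_PAIR_TO_LABEL = {"GT-AG": CANONICAL_GT_AG, "GC-AG": GC_AG, "AT-AC": AT_AC}

MIN_INTRON_LENGTH = 4  # room for two non-overlapping dinucleotides


@dataclass(frozen=True)
class IntronRecord:
    """One intron with genomic interval and transcript-oriented termini."""

    transcript_id: str
    gene_id: str
    seqid: str
    strand: str
    start: int  # first intronic base, genomic orientation
    end: int  # last intronic base, genomic orientation
    donor: str
    acceptor: str
    ordinal: int  # 1-based, counted from the transcript's 5' end

    def __post_init__(self):
        if self.end - self.start + 1 < MIN_INTRON_LENGTH:
            raise AnnotationError(
                f"{self.transcript_id} intron [{self.start}..{self.end}] "
                f"shorter than {MIN_INTRON_LENGTH} bp"
            )
        for name, s in (("donor", self.donor), ("acceptor", self.acceptor)):
            if len(s) != 2 or set(s) - set("ACGTN"):
                raise AnnotationError(f"invalid {name} dinucleotide {s!r}")


@dataclass(frozen=True)
class SpliceSiteClass:
    label: str
    pair: str  # "DD-AA"


@dataclass
class SpliceInventory:
    """Frequency table of donor-acceptor pair classes plus per-gene flags."""

    per_pair_counts: dict[str, int] = field(default_factory=dict)
    class_counts: dict[str, int] = field(
        default_factory=lambda: {lbl: 0 for lbl in CLASS_LABELS}
    )
    total_introns: int = 0
    noncanonical_gene_ids: set[str] = field(default_factory=set)

    @property
    def distinct_pair_count(self) -> int:
        return len(self.per_pair_counts)

    def _check(self):
        assert sum(self.per_pair_counts.values()) == self.total_introns
        assert sum(self.class_counts.values()) == self.total_introns


@dataclass(frozen=True)
class GeneSpliceSummary:
    median_transcript_length: float  # bp, sum of exon lengths
    median_exon_count: float
    gene_count: int


def select_representative_transcript(gene: GeneModel) -> TranscriptModel:
    """The coding isoform with the longest CDS; ties go to the
    lexicographically smallest transcript id."""
    coding = gene.coding_transcripts
    if not coding:
        raise AnnotationError(f"gene {gene.gene_id} has no coding transcript")
    best = max(t.cds_length for t in coding)
    return min(
        (t for t in coding if t.cds_length == best),
        key=lambda t: t.transcript_id,
    )


def extract_introns(
    transcript: TranscriptModel, genome: GenomeSequence
) -> list[IntronRecord]:
    """One IntronRecord per gap between consecutive exons.

    Ordinals count from the transcript's 5' end, i.e. in descending genomic
    coordinate for minus-strand transcripts.
    """
    if transcript.seqid != genome.seqid:
        raise AnnotationError(
            f"transcript {transcript.transcript_id} is on "
            f"{transcript.seqid}, not {genome.seqid}"
        )
    gaps = []
    for prev, nxt in zip(transcript.exons, transcript.exons[1:]):
        start, end = prev.end + 1, nxt.start - 1
        if end - start + 1 < MIN_INTRON_LENGTH:
            raise AnnotationError(
                f"{transcript.transcript_id}: inter-exon gap "
                f"[{start}..{end}] shorter than {MIN_INTRON_LENGTH} bp"
            )
        gaps.append((start, end))
    if transcript.strand == "-":
        gaps = gaps[::-1]
    records = []
    for ordinal, (start, end) in enumerate(gaps, start=1):
        if transcript.strand == "+":
            donor = extract_subsequence(genome, start, start + 1, "+")
            acceptor = extract_subsequence(genome, end - 1, end, "+")
        else:
            donor = extract_subsequence(genome, end - 1, end, "-")
            acceptor = extract_subsequence(genome, start, start + 1, "-")
        records.append(
            IntronRecord(
                transcript_id=transcript.transcript_id,
                gene_id=transcript.parent_gene,
                seqid=transcript.seqid,
                strand=transcript.strand,
                start=start,
                end=end,
                donor=donor,
                acceptor=acceptor,
                ordinal=ordinal,
            )
        )
    return records


def classify_splice_pair(donor: str, acceptor: str) -> SpliceSiteClass:
    for name, s in (("donor", donor), ("acceptor", acceptor)):
        if len(s) != 2 or set(s) - set("ACGTN"):
            raise AnnotationError(f"invalid {name} dinucleotide {s!r}")
    pair = f"{donor}-{acceptor}"
    if "N" in donor or "N" in acceptor:
        return SpliceSiteClass(AMBIGUOUS, pair)
    return SpliceSiteClass(_PAIR_TO_LABEL.get(pair, OTHER), pair)


def _scoped_transcripts(gene: GeneModel, scope: str) -> list[TranscriptModel]:
    if scope == "representative_only":
        return [select_representative_transcript(gene)]
    if scope == "all_isoforms":
        return list(gene.transcripts)
    raise ValueError(f"unknown scope {scope!r}")


def build_inventory(
    genes: list[GeneModel],
    genomes: list[GenomeSequence],
    scope: str = "representative_only",
    noncanonical_policy: str = "default",
) -> SpliceInventory:
    """Aggregate splice-pair classes over the scoped transcripts of all genes.

    Introns identical across isoforms are counted once per transcript they
    occur in (per-transcript intron events, not distinct genomic introns).
    """
    flagging = NONCANONICAL_POLICIES[noncanonical_policy]
    by_seqid = {g.seqid: g for g in genomes}
    inv = SpliceInventory()
    for gene in genes:
        if gene.seqid not in by_seqid:
            raise AnnotationError(
                f"gene {gene.gene_id}: seqid {gene.seqid!r} not in genome set"
            )
        genome = by_seqid[gene.seqid]
        for transcript in _scoped_transcripts(gene, scope):
            for intron in extract_introns(transcript, genome):
                cls = classify_splice_pair(intron.donor, intron.acceptor)
                inv.per_pair_counts[cls.pair] = (
                    inv.per_pair_counts.get(cls.pair, 0) + 1
                )
                inv.class_counts[cls.label] += 1
                inv.total_introns += 1
                if cls.label in flagging:
                    inv.noncanonical_gene_ids.add(gene.gene_id)
    inv._check()
    return inv


def format_percentage(count: int, total: int, decimals: int = 1) -> str:
    """100*count/total as a string, half-up rounded at `decimals` places."""
    if total <= 0:
        raise AnnotationError("cannot format a percentage of a zero total")
    q = Decimal(1).scaleb(-decimals)
    pct = (Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    return f"{pct:.{decimals}f}"


def format_class_percentages(
    inventory: SpliceInventory, decimals: int = 1
) -> dict[str, str]:
    if inventory.total_introns == 0:
        raise AnnotationError("inventory holds no introns")
    return {
        label: format_percentage(count, inventory.total_introns, decimals)
        for label, count in inventory.class_counts.items()
    }


def _summary(transcripts: list[TranscriptModel]) -> GeneSpliceSummary:
    if not transcripts:
        raise AnnotationError("cannot summarize an empty gene set")
    return GeneSpliceSummary(
        median_transcript_length=statistics.median(
            t.exonic_length for t in transcripts
        ),
        median_exon_count=statistics.median(t.exon_count for t in transcripts),
        gene_count=len(transcripts),
    )


def summarize_noncanonical_genes(
    genes: list[GeneModel],
    genomes: list[GenomeSequence],
    scope: str = "representative_only",
    noncanonical_policy: str = "default",
) -> tuple[GeneSpliceSummary, GeneSpliceSummary]:
    """(summary over genes flagged non-canonical, summary over all genes).

    Medians are always taken over each gene's representative transcript;
    the scope only widens which isoforms can flag a gene.
    """
    inv = build_inventory(genes, genomes, scope, noncanonical_policy)
    rep = {g.gene_id: select_representative_transcript(g) for g in genes}
    subset = [rep[gid] for gid in sorted(inv.noncanonical_gene_ids)]
    return _summary(subset), _summary(list(rep.values()))
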