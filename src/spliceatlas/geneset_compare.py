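"""Structural comparison of two gene sets annotated on the same genome.

Loci are paired greedily by same-strand genomic overlap (largest overlap
first, each gene used at most once). A feature of one set "matches" when
the paired gene in the other set has a same-kind feature with identical
coordinates; the match percentage pools both directions,

    100 * (matched_A + matched_B) / (features_A + features_B),

with features of unpaired loci counting in the denominator as unmatched.
The pooled formula is symmetric in A and B by construction. Feature
comparison uses each gene's representative transcript on both sides.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

from .annotation_io import AnnotationError, GeneModel, UTR_KINDS
from .splice_inventory import select_representative_transcript


@dataclass(frozen=True)
class LocusPairing:
    gene_a: GeneModel
    gene_b: GeneModel
    overlap_bp: int

    def __post_init__(self):
        if self.overlap_bp < 1:
            raise AnnotationError("paired loci must overlap by >= 1 bp")
        if (
            self.gene_a.seqid != self.gene_b.seqid
            or self.gene_a.strand != self.gene_b.strand
        ):
            raise AnnotationError("paired loci must share seqid and strand")


@dataclass
class PairingResult:
    pairings: list[LocusPairing]
    unpaired_a: list[GeneModel]
    unpaired_b: list[GeneModel]


@dataclass(frozen=True)
class SetSummary:
    gene_count: int
    median_cds_length: float
    median_exon_count: float


@dataclass(frozen=True)
class ComparisonReport:
    cds_match_percent: float
    utr_match_percent: float | None  # None when neither set annotates UTRs
    gene_count_a: int
    gene_count_b: int
    gene_count_delta: int  # count_b - count_a
    median_cds_length_a: float
    median_cds_length_b: float
    unpaired_a: int
    unpaired_b: int

    def to_dict(self) -> dict:
        return {
            "cds_match_percent": self.cds_match_percent,
            "utr_match_percent": self.utr_match_percent,
            "gene_count_a": self.gene_count_a,
            "gene_count_b": self.gene_count_b,
            "gene_count_delta": self.gene_count_delta,
            "median_cds_length_a": self.median_cds_length_a,
            "median_cds_length_b": self.median_cds_length_b,
            "unpaired_a": self.unpaired_a,
            "unpaired_b": self.unpaired_b,
        }


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0]) + 1


def pair_loci(set_a: list[GeneModel], set_b: list[GeneModel]) -> PairingResult:
    """Greedy maximum-overlap matching of same-strand overlapping gene spans.

    Candidate pairs are accepted in descending overlap, ties broken by the
    smaller gene_a start (then ids, for determinism); each gene is used at
    most once.
    """
    candidates = []
    for ia, ga in enumerate(set_a):
        for ib, gb in enumerate(set_b):
            if ga.seqid != gb.seqid or ga.strand != gb.strand:
                continue
            ov = _overlap(ga.span, gb.span)
            if ov >= 1:
                candidates.append((ov, ga.span[0], ga.gene_id, gb.gene_id, ia, ib))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairings = []
    for ov, _, _, _, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairings.append(LocusPairing(set_a[ia], set_b[ib], ov))
    return PairingResult(
        pairings=pairings,
        unpaired_a=[g for i, g in enumerate(set_a) if i not in used_a],
        unpaired_b=[g for i, g in enumerate(set_b) if i not in used_b],
    )


def _features(gene: GeneModel, feature_kind: str) -> set[tuple]:
    t = select_representative_transcript(gene)
    if feature_kind == "CDS":
        return {(c.start, c.end) for c in t.cds_parts}
    if feature_kind == "UTR":
        return {(u.start, u.end, u.kind) for u in t.utr_parts if u.kind in UTR_KINDS}
    raise ValueError(f"unknown feature kind {feature_kind!r}")


def feature_match_percent(result: PairingResult, feature_kind: str) -> float:
    """Pooled exact-coordinate match percentage for CDS or UTR features."""
    matched = 0
    total = 0
    for p in result.pairings:
        fa = _features(p.gene_a, feature_kind)
        fb = _features(p.gene_b, feature_kind)
        matched += 2 * len(fa & fb)  # each shared feature matches once per side
        total += len(fa) + len(fb)
    for g in result.unpaired_a + result.unpaired_b:
        total += len(_features(g, feature_kind))
    if total == 0:
        raise AnnotationError(f"no {feature_kind} features to compare")
    return 100.0 * matched / total


def summary_stats(genes: list[GeneModel]) -> SetSummary:
    """Gene count and medians over representative transcripts."""
    if not genes:
        raise AnnotationError("cannot summarize an empty gene set")
    reps = [select_representative_transcript(g) for g in genes]
    return SetSummary(
        gene_count=len(genes),
        median_cds_length=statistics.median(t.cds_length for t in reps),
        median_exon_count=statistics.median(t.exon_count for t in reps),
    )


def compare_gene_sets(set_a: list[GeneModel], set_b: list[GeneModel]) -> ComparisonReport:
    result = pair_loci(set_a, set_b)
    stats_a = summary_stats(set_a)
    stats_b = summary_stats(set_b)
    try:
        utr = feature_match_percent(result, "UTR")
    except AnnotationError:
        utr = None
    return ComparisonReport(
        cds_match_percent=feature_match_percent(result, "CDS"),
        utr_match_percent=utr,
        gene_count_a=stats_a.gene_count,
        gene_count_b=stats_b.gene_count,
        gene_count_delta=stats_b.gene_count - stats_a.gene_count,
        median_cds_length_a=stats_a.median_cds_length,
        median_cds_length_b=stats_b.median_cds_length,
        unpaired_a=len(result.unpaired_a),
        unpaired_b=len(result.unpaired_b),
    )
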