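"""Simulation of paired accessions with known splice-site ground truth.

The generator emulates the situation the pipeline is built for: a
well-annotated reference accession (multi-exon protein-coding genes on both
strands, several isoforms, UTRs, a configured mixture of GT-AG / GC-AG /
AT-AC / other intron classes) and a second accession whose genome carries
point substitutions but whose true gene structures are known. Every intron's
class, coordinates and transcript are recorded in a truth table, which is
the oracle the other modules are tested against.

Background sequence is i.i.d. uniform over {A,C,G,T}; each intron's first
and last two bases are then overwritten with its assigned class's
dinucleotides (reverse-complemented on the minus strand). "other"-class
pairs are drawn round-robin from an explicit pool, never sampled, so
expected inventories are exact rather than stochastic. The seed fully
determines all outputs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import (
    ExonInterval,
    GeneModel,
    GenomeSequence,
    SplicedAlignment,
    TabularHit,
    TranscriptModel,
    extract_subsequence,
    reverse_complement,
    write_fasta,
    write_psl,
    write_tabular_hits,
)
from .ortholog_rbh import score_all_pairs
from .splice_inventory import (
    AT_AC,
    CANONICAL_GT_AG,
    GC_AG,
    OTHER,
    classify_splice_pair,
    select_representative_transcript,
)

_CLASS_PAIRS = {CANONICAL_GT_AG: "GT-AG", GC_AG: "GC-AG", AT_AC: "AT-AC"}
_MIX_LABELS = (CANONICAL_GT_AG, GC_AG, AT_AC, OTHER)

RICH_GENE_MIN_EXONS = 8  # "exon-rich" threshold for biased placement


class PackingError(ValueError):
    """The requested genes do not fit the configured chromosomes."""


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 120_000
    n_genes: int = 40
    exon_count_range: tuple[int, int] = (1, 15)
    exon_length_range: tuple[int, int] = (60, 300)
    intron_length_range: tuple[int, int] = (60, 200)
    # Araport11-like composition: ~98.9% GT-AG, ~1% GC-AG, rare AT-AC/other
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            CANONICAL_GT_AG: 0.988,
            GC_AG: 0.010,
            AT_AC: 0.001,
            OTHER: 0.001,
        }
    )
    other_pair_pool: tuple[str, ...] = ("GA-AG", "GC-CT")
    noncanonical_in_rich_genes: bool = False
    isoforms_per_gene: tuple[int, int] = (1, 2)
    divergence: float = 0.01
    utr_length_range: tuple[int, int] = (30, 150)
    intergenic_range: tuple[int, int] = (100, 400)
    strand_pool: tuple[str, ...] = ("+", "-")

    def __post_init__(self):
        if self.intron_length_range[0] < 20:
            raise ValueError("minimum intron length must be >= 20 bp")
        if set(self.class_mix) - set(_MIX_LABELS):
            raise ValueError(f"class_mix keys must be among {_MIX_LABELS}")
        if any(v < 0 for v in self.class_mix.values()):
            raise ValueError("class_mix entries must be non-negative")
        if self.mix_is_fractions and abs(sum(self.class_mix.values()) - 1) > 1e-9:
            raise ValueError("class_mix fractions must sum to 1")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")
        for pair in self.other_pair_pool:
            if len(pair) != 5 or pair[2] != "-":
                raise ValueError(f"malformed other-class pair {pair!r}")
        if not self.strand_pool or set(self.strand_pool) - {"+", "-"}:
            raise ValueError("strand_pool must be a non-empty subset of {+,-}")

    @property
    def mix_is_fractions(self) -> bool:
        return all(v <= 1 for v in self.class_mix.values()) and sum(
            self.class_mix.values()
        ) <= 1 + 1e-9


@dataclass(frozen=True)
class IntronTruth:
    """Ground-truth record for one intron of one transcript."""

    gene_id: str
    transcript_id: str
    seqid: str
    strand: str
    start: int
    end: int
    ordinal: int
    donor: str
    acceptor: str
    label: str
    in_representative: bool


def truth_to_frame(truth: list[IntronTruth]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truth])


def write_truth_table(truth: list[IntronTruth], path):
    truth_to_frame(truth).to_csv(path, sep="\t", index=False)


def expected_class_counts(truth: list[IntronTruth], scope: str) -> dict[str, int]:
    """Class counts the inventory must reproduce, straight from bookkeeping."""
    rows = (
        [t for t in truth if t.in_representative]
        if scope == "representative_only"
        else truth
    )
    counts: dict[str, int] = {}
    for t in rows:
        counts[t.label] = counts.get(t.label, 0) + 1
    return counts


def _rint(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    """Uniform integer on an inclusive range."""
    return int(rng.integers(bounds[0], bounds[1] + 1))


def _apportion(fractions: dict[str, float], total: int) -> dict[str, int]:
    """Largest-remainder apportionment so counts are exact and deterministic."""
    raw = {k: fractions.get(k, 0.0) * total for k in _MIX_LABELS}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(_MIX_LABELS, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _resolve_class_counts(config: SyntheticConfig, exon_counts: list[int]) -> dict[str, int]:
    total = sum(k - 1 for k in exon_counts)
    if config.mix_is_fractions:
        return _apportion(config.class_mix, total)
    counts = {k: int(config.class_mix.get(k, 0)) for k in _MIX_LABELS}
    if sum(counts.values()) != total:
        raise ValueError(
            f"class_mix counts sum to {sum(counts.values())} but the genes "
            f"provide {total} introns"
        )
    return counts


def _plan_exon_counts(config: SyntheticConfig, rng: np.random.Generator) -> list[int]:
    lo, hi = config.exon_count_range
    counts = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_genes)]
    if not config.mix_is_fractions:
        # counts-mode: adjust exon numbers so the intron total matches exactly
        demand = int(sum(config.class_mix.get(k, 0) for k in _MIX_LABELS))
        guard = 0
        while sum(k - 1 for k in counts) != demand:
            diff = demand - sum(k - 1 for k in counts)
            idx = int(rng.integers(0, len(counts)))
            if diff > 0 and counts[idx] < hi:
                counts[idx] += 1
            elif diff < 0 and counts[idx] > max(lo, 1):
                counts[idx] -= 1
            guard += 1
            if guard > 100_000:
                raise ValueError(
                    "cannot reconcile class_mix counts with the exon count range"
                )
    return counts


def _assign_intron_classes(
    config: SyntheticConfig,
    exon_counts: list[int],
    class_counts: dict[str, int],
    rng: np.random.Generator,
) -> list[list[str]]:
    """Per gene, the class label of each of its representative introns."""
    slots = [
        (gi, ii) for gi, k in enumerate(exon_counts) for ii in range(k - 1)
    ]
    n_nc = sum(v for k, v in class_counts.items() if k != CANONICAL_GT_AG)
    if config.noncanonical_in_rich_genes:
        eligible = [
            s for s in slots if exon_counts[s[0]] >= RICH_GENE_MIN_EXONS
        ]
        if len(eligible) < n_nc:
            raise PackingError(
                "not enough intron slots in exon-rich genes for the requested "
                "non-canonical introns; increase n_genes or exon counts"
            )
        nc_slots = [
            eligible[i]
            for i in rng.choice(len(eligible), size=n_nc, replace=False)
        ]
    else:
        nc_slots = [
            slots[i] for i in rng.choice(len(slots), size=n_nc, replace=False)
        ]
    nc_iter = iter(nc_slots)
    assignment: dict[tuple[int, int], str] = {}
    for label in (GC_AG, AT_AC, OTHER):
        for _ in range(class_counts.get(label, 0)):
            assignment[next(nc_iter)] = label
    out = []
    for gi, k in enumerate(exon_counts):
        out.append(
            [assignment.get((gi, ii), CANONICAL_GT_AG) for ii in range(k - 1)]
        )
    return out


def _pair_for(label: str, other_cycle: list) -> tuple[str, str]:
    if label == OTHER:
        pair = other_cycle[0]
        other_cycle.append(other_cycle.pop(0))
    else:
        pair = _CLASS_PAIRS[label]
    donor, acceptor = pair.split("-")
    return donor, acceptor


def generate_reference(
    config: SyntheticConfig,
) -> tuple[list[GenomeSequence], list[GeneModel], list[IntronTruth]]:
    """Simulate the reference accession: genomes, annotation, truth table."""
    rng = np.random.default_rng(config.seed)
    exon_counts = _plan_exon_counts(config, rng)
    class_counts = _resolve_class_counts(config, exon_counts)
    class_plan = _assign_intron_classes(config, exon_counts, class_counts, rng)
    other_cycle = list(config.other_pair_pool)

    chrom_seqs = [
        rng.choice(list("ACGT"), size=config.chromosome_length)
        for _ in range(config.n_chromosomes)
    ]
    cursors = [_rint(rng, config.intergenic_range) for _ in chrom_seqs]

    genes: list[GeneModel] = []
    truth: list[IntronTruth] = []
    for gi, k in enumerate(exon_counts):
        gene_id = f"g{gi + 1:04d}"
        strand = config.strand_pool[int(rng.integers(0, len(config.strand_pool)))]
        exon_lens = [_rint(rng, config.exon_length_range) for _ in range(k)]
        intron_lens = [
            _rint(rng, config.intron_length_range) for _ in range(k - 1)
        ]
        gene_len = sum(exon_lens) + sum(intron_lens)

        chrom = None
        for ci in range(config.n_chromosomes):
            cand = (gi + ci) % config.n_chromosomes
            if cursors[cand] + gene_len < config.chromosome_length:
                chrom = cand
                break
        if chrom is None:
            raise PackingError(
                f"gene {gene_id} ({gene_len} bp) does not fit on any "
                "chromosome; increase chromosome_length"
            )
        seqid = f"chr{chrom + 1}"
        start = cursors[chrom] + 1  # 1-based
        cursors[chrom] += gene_len + _rint(rng, config.intergenic_range)

        # lay out exons/introns left to right in genomic orientation
        exons = []
        pos = start
        for j, elen in enumerate(exon_lens):
            exons.append(ExonInterval(pos, pos + elen - 1, "exon"))
            pos += elen
            if j < k - 1:
                pos += intron_lens[j]

        # intron classes are planned in transcript order; map to genomic order
        plan_tx = class_plan[gi]
        plan_genomic = plan_tx if strand == "+" else plan_tx[::-1]
        intron_pairs_genomic = []
        for j in range(k - 1):
            donor, acceptor = _pair_for(plan_genomic[j], other_cycle)
            intron_pairs_genomic.append((donor, acceptor))
            istart, iend = exons[j].end + 1, exons[j + 1].start - 1
            seq = chrom_seqs[chrom]
            if strand == "+":
                seq[istart - 1 : istart + 1] = list(donor)
                seq[iend - 2 : iend] = list(acceptor)
            else:
                seq[istart - 1 : istart + 1] = list(reverse_complement(acceptor))
                seq[iend - 2 : iend] = list(reverse_complement(donor))

        u5 = _rint(rng, config.utr_length_range)
        u3 = _rint(rng, config.utr_length_range)
        transcripts = [
            _build_transcript(
                f"{gene_id}.1", gene_id, seqid, strand, exons, u5, u3
            )
        ]
        n_iso = _rint(rng, config.isoforms_per_gene) if k >= 3 else 1
        if n_iso >= 2 and k >= 3:
            skip = int(rng.integers(1, k - 1))  # internal exon index
            # sharing the UTR trims keeps isoform .1 the longest-CDS isoform
            iso_exons = exons[:skip] + exons[skip + 1 :]
            transcripts.append(
                _build_transcript(
                    f"{gene_id}.2", gene_id, seqid, strand, iso_exons, u5, u3
                )
            )
        gene = GeneModel(gene_id, seqid, strand, transcripts)
        genes.append(gene)
        truth.extend(
            _truth_for_gene(gene, exons, intron_pairs_genomic)
        )
    genomes = [
        GenomeSequence(f"chr{i + 1}", "".join(s)) for i, s in enumerate(chrom_seqs)
    ]
    return genomes, genes, truth


def _build_transcript(
    tid: str,
    gene_id: str,
    seqid: str,
    strand: str,
    exons: list[ExonInterval],
    u5: int,
    u3: int,
) -> TranscriptModel:
    """Decompose an exon chain into 5'UTR / CDS / 3'UTR in transcript
    orientation. Middle exons are fully coding."""
    first, last = exons[0], exons[-1]
    # keep at least ~30 coding bp in each terminal exon so CDS sequences
    # stay long enough to anchor similarity searches
    if len(exons) == 1:
        u5 = min(u5, max((first.length - 60) // 2, 0))
        u3 = min(u3, max(first.length - 60 - u5, 0))
    else:
        u5 = min(u5, max(first.length - 30, 0))
        u3 = min(u3, max(last.length - 30, 0))
    u5 = max(u5, 0)
    u3 = max(u3, 0)
    # genomic-left trim is the 5'UTR on '+', the 3'UTR on '-'
    left = u5 if strand == "+" else u3
    right = u3 if strand == "+" else u5
    left_kind = "five_prime_UTR" if strand == "+" else "three_prime_UTR"
    right_kind = "three_prime_UTR" if strand == "+" else "five_prime_UTR"

    cds, utrs = [], []
    for i, e in enumerate(exons):
        cstart, cend = e.start, e.end
        if i == 0 and left > 0:
            utrs.append(ExonInterval(e.start, e.start + left - 1, left_kind))
            cstart = e.start + left
        if i == len(exons) - 1 and right > 0:
            utrs.append(ExonInterval(e.end - right + 1, e.end, right_kind))
            cend = e.end - right
        if cstart <= cend:
            cds.append(ExonInterval(cstart, cend, "CDS"))
    return TranscriptModel(
        transcript_id=tid,
        parent_gene=gene_id,
        seqid=seqid,
        strand=strand,
        exons=list(exons),
        cds_parts=cds,
        utr_parts=utrs,
    )


def _truth_for_gene(
    gene: GeneModel,
    ref_exons: list[ExonInterval],
    intron_pairs_genomic: list[tuple[str, str]],
) -> list[IntronTruth]:
    """Truth rows for every intron of every isoform.

    An isoform that skips an exon has a merged intron whose donor comes from
    the left reference intron and whose acceptor comes from the right one;
    its class is whatever that combination classifies as.
    """
    boundary_pair = {}  # (istart, iend) -> (donor, acceptor) in tx orientation
    for j, (donor, acceptor) in enumerate(intron_pairs_genomic):
        istart, iend = ref_exons[j].end + 1, ref_exons[j + 1].start - 1
        boundary_pair[istart] = donor if gene.strand == "+" else acceptor
        boundary_pair[iend] = acceptor if gene.strand == "+" else donor

    rep_id = select_representative_transcript(gene).transcript_id
    truth = []
    for t in gene.transcripts:
        gaps = [
            (prev.end + 1, nxt.start - 1)
            for prev, nxt in zip(t.exons, t.exons[1:])
        ]
        ordered = gaps[::-1] if t.strand == "-" else gaps
        for ordinal, (istart, iend) in enumerate(ordered, start=1):
            if t.strand == "+":
                donor, acceptor = boundary_pair[istart], boundary_pair[iend]
            else:
                donor, acceptor = boundary_pair[iend], boundary_pair[istart]
            truth.append(
                IntronTruth(
                    gene_id=gene.gene_id,
                    transcript_id=t.transcript_id,
                    seqid=t.seqid,
                    strand=t.strand,
                    start=istart,
                    end=iend,
                    ordinal=ordinal,
                    donor=donor,
                    acceptor=acceptor,
                    label=classify_splice_pair(donor, acceptor).label,
                    in_representative=t.transcript_id == rep_id,
                )
            )
    return truth


# ---------------------------------------------------------------------------
# Second accession


def accession_gene_id(gene_id: str) -> str:
    return f"acc_{gene_id}"


def generate_accession(
    config: SyntheticConfig,
    genomes: list[GenomeSequence],
    genes: list[GeneModel],
    truth: list[IntronTruth],
) -> tuple[list[GenomeSequence], list[GeneModel]]:
    """Mutate the reference genome at the configured per-base substitution
    rate, never touching the four intron-terminal bases of any intron, and
    return the true accession gene structures (same coordinates; substitution
    only, no indels)."""
    rng = np.random.default_rng([config.seed, 7919])
    protected: dict[str, set[int]] = {g.seqid: set() for g in genomes}
    for t in truth:
        protected[t.seqid].update(
            (t.start, t.start + 1, t.end - 1, t.end)
        )
    mutated = []
    for g in genomes:
        arr = np.frombuffer(g.residues.encode(), dtype="S1").copy()
        mask = rng.random(g.length) < config.divergence
        if protected[g.seqid]:
            idx = np.fromiter(protected[g.seqid], dtype=int) - 1
            mask[idx] = False
        shift = rng.integers(1, 4, size=g.length)
        order = np.frombuffer(b"ACGT", dtype="S1")
        lookup = {b: i for i, b in enumerate(order)}
        pos = np.nonzero(mask)[0]
        for p in pos:
            base = arr[p]
            if base not in lookup:  # leave N untouched
                continue
            arr[p] = order[(lookup[base] + shift[p]) % 4]
        mutated.append(GenomeSequence(g.seqid, arr.tobytes().decode()))

    acc_genes = []
    for gene in genes:
        clone = copy.deepcopy(gene)
        clone.gene_id = accession_gene_id(gene.gene_id)
        for t in clone.transcripts:
            t.parent_gene = clone.gene_id
            t.transcript_id = accession_gene_id(t.transcript_id)
        acc_genes.append(clone)
    return mutated, acc_genes


# ---------------------------------------------------------------------------
# Emitters feeding the downstream modules without BLAT/BLAST


def transcript_sequence(t: TranscriptModel, genome: GenomeSequence) -> str:
    """Mature transcript: exon concatenation in transcript orientation."""
    concat = "".join(
        extract_subsequence(genome, e.start, e.end, "+") for e in t.exons
    )
    return reverse_complement(concat) if t.strand == "-" else concat


def cds_sequence(t: TranscriptModel, genome: GenomeSequence) -> str:
    concat = "".join(
        extract_subsequence(genome, c.start, c.end, "+") for c in t.cds_parts
    )
    return reverse_complement(concat) if t.strand == "-" else concat


def emit_transcripts(
    genes: list[GeneModel], genomes: list[GenomeSequence], path=None
) -> dict[str, str]:
    """All transcript sequences, optionally written as FASTA."""
    by_seqid = {g.seqid: g for g in genomes}
    seqs = {
        t.transcript_id: transcript_sequence(t, by_seqid[t.seqid])
        for gene in genes
        for t in gene.transcripts
    }
    if path is not None:
        write_fasta(seqs, path)
    return seqs


def emit_true_alignments(
    ref_genes: list[GeneModel],
    ref_genomes: list[GenomeSequence],
    target_genomes: list[GenomeSequence],
    path=None,
) -> list[SplicedAlignment]:
    """The alignments a perfect spliced aligner would report: one alignment
    per representative transcript with one block per exon at the true
    coordinates; match/mismatch counts are computed against the target
    genome base by base."""
    ref_by_id = {g.seqid: g for g in ref_genomes}
    tgt_by_id = {g.seqid: g for g in target_genomes}
    alignments = []
    for gene in ref_genes:
        t = select_representative_transcript(gene)
        ref_genome, tgt_genome = ref_by_id[t.seqid], tgt_by_id[t.seqid]
        total_len = t.exonic_length
        blocks = []
        matches = 0
        cum = 0
        for e in t.exons:
            if t.strand == "+":
                q = (cum + 1, cum + e.length)
            else:
                q = (total_len - cum - e.length + 1, total_len - cum)
            blocks.append((e.start, e.end, q[0], q[1]))
            ref_piece = extract_subsequence(ref_genome, e.start, e.end, "+")
            tgt_piece = extract_subsequence(tgt_genome, e.start, e.end, "+")
            matches += sum(a == b for a, b in zip(ref_piece, tgt_piece))
            cum += e.length
        alignments.append(
            SplicedAlignment(
                query_id=t.transcript_id,
                query_length=total_len,
                strand=t.strand,
                target_seqid=t.seqid,
                blocks=tuple(blocks),
                matches=matches,
                mismatches=total_len - matches,
            )
        )
    if path is not None:
        sizes = {g.seqid: g.length for g in target_genomes}
        write_psl(alignments, sizes, path)
    return alignments


def emit_hit_tables(
    genes_a: list[GeneModel],
    genomes_a: list[GenomeSequence],
    genes_b: list[GeneModel],
    genomes_b: list[GenomeSequence],
    path_ab=None,
    path_ba=None,
) -> tuple[list[TabularHit], list[TabularHit]]:
    """Directed hit tables over representative CDS sequences, scored with
    the built-in exhaustive local aligner."""
    by_a = {g.seqid: g for g in genomes_a}
    by_b = {g.seqid: g for g in genomes_b}
    seqs_a = {
        g.gene_id: cds_sequence(select_representative_transcript(g), by_a[g.seqid])
        for g in genes_a
    }
    seqs_b = {
        g.gene_id: cds_sequence(select_representative_transcript(g), by_b[g.seqid])
        for g in genes_b
    }
    hits_ab, hits_ba = score_all_pairs(seqs_a, seqs_b)
    if path_ab is not None:
        write_tabular_hits(hits_ab, path_ab)
    if path_ba is not None:
        write_tabular_hits(hits_ba, path_ba)
    return hits_ab, hits_ba


# ---------------------------------------------------------------------------
# Controlled structural perturbation (for comparison-statistic tests)


def perturb_cds_boundaries(
    genes: list[GeneModel], fraction: float, seed: int
) -> tuple[list[GeneModel], int, int]:
    """Shift the start of a chosen fraction of representative-transcript CDS
    parts by +1 bp (within their exon). Returns (perturbed copy, n_shifted,
    n_total_parts)."""
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(genes)
    slots = []
    for gi, gene in enumerate(out):
        rep = select_representative_transcript(gene)
        ti = gene.transcripts.index(rep)
        for ci, part in enumerate(rep.cds_parts):
            if part.length >= 2:
                slots.append((gi, ti, ci))
    n_shift = round(fraction * len(slots))
    chosen = (
        [slots[i] for i in rng.choice(len(slots), size=n_shift, replace=False)]
        if n_shift
        else []
    )
    for gi, ti, ci in chosen:
        t = out[gi].transcripts[ti]
        part = t.cds_parts[ci]
        t.cds_parts[ci] = ExonInterval(part.start + 1, part.end, "CDS")
    return out, n_shift, len(slots)


# ---------------------------------------------------------------------------
# Whole-genome reverse complement (for strand-symmetry checks)


def reverse_complement_dataset(
    genomes: list[GenomeSequence], genes: list[GeneModel]
) -> tuple[list[GenomeSequence], list[GeneModel]]:
    """Reverse-complement every chromosome and mirror all annotations; the
    splice inventory of the mirrored dataset must equal the original's."""
    lengths = {g.seqid: g.length for g in genomes}
    rc_genomes = [
        GenomeSequence(g.seqid, reverse_complement(g.residues)) for g in genomes
    ]

    def flip(iv: ExonInterval, L: int) -> ExonInterval:
        return ExonInterval(L - iv.end + 1, L - iv.start + 1, iv.kind)

    rc_genes = []
    for gene in genes:
        L = lengths[gene.seqid]
        strand = "-" if gene.strand == "+" else "+"
        transcripts = [
            TranscriptModel(
                transcript_id=t.transcript_id,
                parent_gene=t.parent_gene,
                seqid=t.seqid,
                strand=strand,
                exons=[flip(e, L) for e in t.exons],
                cds_parts=[flip(c, L) for c in t.cds_parts],
                utr_parts=[flip(u, L) for u in t.utr_parts],
            )
            for t in gene.transcripts
        ]
        rc_genes.append(GeneModel(gene.gene_id, gene.seqid, strand, transcripts))
    return rc_genomes, rc_genes
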