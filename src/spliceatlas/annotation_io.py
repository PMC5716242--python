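"""Readers/writers for the standard formats the pipeline touches, plus the
shared domain types.

All internal coordinates are 1-based inclusive (GFF3 convention). PSL's
0-based half-open block coordinates are converted at the parser boundary so
no other module ever sees them. Sequences are normalized to the {A,C,G,T,N}
alphabet on read: lowercase is uppercased and any other IUPAC ambiguity code
collapses to N (an N is treated downstream as missing evidence, never as
evidence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACGTN")
EXON_KINDS = ("exon", "CDS", "five_prime_UTR", "three_prime_UTR")
UTR_KINDS = ("five_prime_UTR", "three_prime_UTR")


class AnnotationError(ValueError):
    """A file or object violates a structural invariant of the domain model."""


class FormatError(AnnotationError):
    """A file cannot be parsed as the expected format."""


def normalize_residues(raw: str) -> str:
    """Uppercase and collapse non-ACGTN IUPAC codes to N."""
    up = raw.upper()
    return "".join(c if c in VALID_RESIDUES else "N" for c in up)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/contig with normalized residues."""

    seqid: str
    residues: str

    def __post_init__(self):
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise AnnotationError(
                f"{self.seqid}: residues outside A/C/G/T/N: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ExonInterval:
    """A 1-based inclusive interval of a given structural kind."""

    start: int
    end: int
    kind: str = "exon"

    def __post_init__(self):
        if self.kind not in EXON_KINDS:
            raise AnnotationError(f"unknown interval kind {self.kind!r}")
        if self.start < 1:
            raise AnnotationError(f"interval start {self.start} < 1")
        if self.start > self.end:
            raise AnnotationError(
                f"interval start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """One transcript isoform: exon chain plus CDS and UTR decomposition."""

    transcript_id: str
    parent_gene: str
    seqid: str
    strand: str
    exons: list[ExonInterval]
    cds_parts: list[ExonInterval] = field(default_factory=list)
    utr_parts: list[ExonInterval] = field(default_factory=list)
    attributes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(
                f"{self.transcript_id}: strand must be + or -, got {self.strand!r}"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        self.cds_parts = sorted(self.cds_parts, key=lambda e: e.start)
        self.utr_parts = sorted(self.utr_parts, key=lambda e: e.start)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start <= prev.end + 1:
                raise AnnotationError(
                    f"{self.transcript_id}: exons [{prev.start}..{prev.end}] and "
                    f"[{nxt.start}..{nxt.end}] overlap or touch"
                )
        for c in self.cds_parts:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: CDS part "
                    f"[{c.start}..{c.end}] not contained in any exon"
                )

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def cds_length(self) -> int:
        return sum(c.length for c in self.cds_parts)

    @property
    def exonic_length(self) -> int:
        """Mature-transcript length: sum of exon lengths."""
        return sum(e.length for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds_parts)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end


@dataclass
class GeneModel:
    """A gene with one or more transcript structures on one strand."""

    gene_id: str
    seqid: str
    strand: str
    transcripts: list[TranscriptModel]
    attributes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise AnnotationError(f"gene {self.gene_id}: duplicate transcript ids")
        for t in self.transcripts:
            if t.seqid != self.seqid or t.strand != self.strand:
                raise AnnotationError(
                    f"transcript {t.transcript_id} disagrees with gene "
                    f"{self.gene_id} on seqid/strand"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    @property
    def coding_transcripts(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.is_coding]


@dataclass(frozen=True)
class SplicedAlignment:
    """A block-structured spliced alignment of a transcript onto a genome.

    Block coordinates are 1-based inclusive on both query and target; the
    query coordinates are in forward-query orientation regardless of strand.
    """

    query_id: str
    query_length: int
    strand: str
    target_seqid: str
    blocks: tuple[tuple[int, int, int, int], ...]  # (tstart, tend, qstart, qend)
    matches: int
    mismatches: int

    def __post_init__(self):
        if self.matches + self.mismatches > self.query_length:
            raise AnnotationError(
                f"{self.query_id}: matches+mismatches exceed query length"
            )
        for tstart, tend, qstart, qend in self.blocks:
            if tend - tstart != qend - qstart:
                raise AnnotationError(
                    f"{self.query_id}: block target span != query span"
                )
        for prev, nxt in zip(self.blocks, self.blocks[1:]):
            if nxt[0] <= prev[1]:
                raise AnnotationError(
                    f"{self.query_id}: blocks overlap or unsorted on target"
                )


@dataclass(frozen=True)
class TabularHit:
    """One row of a 12-column (outfmt 6) pairwise similarity table."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatch: int = 0
    gapopen: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    evalue: float = 0.0
    bitscore: float = 0.0

    def __post_init__(self):
        if self.bitscore < 0 or self.evalue < 0:
            raise AnnotationError("bitscore and evalue must be non-negative")
        if not 0 <= self.percent_identity <= 100:
            raise AnnotationError("percent identity outside [0, 100]")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeSequence]:
    """Read a multi-record FASTA into normalized GenomeSequences.

    The seqid is the header token before the first whitespace. Duplicate
    seqids and empty files are errors.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate seqid {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, normalize_residues(str(rec.seq))))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: dict[str, str] | list[GenomeSequence], path, width: int = 80):
    if isinstance(seqs, list):
        seqs = {s.seqid: s.residues for s in seqs}
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_RESERVED_ATTRS = ("ID", "Parent")


def read_gff3(path) -> list[GeneModel]:
    """Assemble gene -> mRNA -> {exon, CDS, UTR} rows into GeneModels.

    Feature rows of unrecognized types are skipped (a count is logged).
    An mRNA whose Parent is absent, or a CDS part not contained in any exon
    of its transcript, is an error.
    """
    genes: dict[str, dict] = {}
    mrnas: dict[str, dict] = {}
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            ftype = feat.featuretype
            if ftype == "gene":
                gid = feat.attributes["ID"][0]
                if gid in genes:
                    raise FormatError(f"duplicate gene ID {gid!r}")
                genes[gid] = {"feat": feat, "mrnas": []}
            elif ftype == "mRNA":
                tid = feat.attributes["ID"][0]
                parent = feat.attributes.get("Parent", [None])[0]
                if parent is None or parent not in genes:
                    raise AnnotationError(
                        f"mRNA {tid!r} has missing or unknown Parent {parent!r}"
                    )
                mrnas[tid] = {
                    "feat": feat,
                    "gene": parent,
                    "exon": [],
                    "CDS": [],
                    "utr": [],
                }
                genes[parent]["mrnas"].append(tid)
            elif ftype in ("exon", "CDS") + UTR_KINDS:
                for parent in feat.attributes.get("Parent", []):
                    if parent not in mrnas:
                        raise AnnotationError(
                            f"{ftype} row has unknown Parent {parent!r}"
                        )
                    iv = ExonInterval(feat.start, feat.end, ftype)
                    if ftype == "exon":
                        mrnas[parent]["exon"].append(iv)
                    elif ftype == "CDS":
                        mrnas[parent]["CDS"].append(iv)
                    else:
                        mrnas[parent]["utr"].append(iv)
            else:
                skipped += 1
    if skipped:
        logger.info("read_gff3: skipped %d rows of unrecognized feature types", skipped)

    out = []
    for gid, g in genes.items():
        gfeat = g["feat"]
        transcripts = []
        for tid in g["mrnas"]:
            m = mrnas[tid]
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    parent_gene=gid,
                    seqid=gfeat.seqid,
                    strand=gfeat.strand,
                    exons=m["exon"],
                    cds_parts=m["CDS"],
                    utr_parts=m["utr"],
                    attributes={
                        k: list(v)
                        for k, v in m["feat"].attributes.items()
                        if k not in _RESERVED_ATTRS
                    },
                )
            )
        if not transcripts:
            logger.info("read_gff3: gene %s has no mRNA children; skipped", gid)
            continue
        out.append(
            GeneModel(
                gene_id=gid,
                seqid=gfeat.seqid,
                strand=gfeat.strand,
                transcripts=transcripts,
                attributes={
                    k: list(v)
                    for k, v in gfeat.attributes.items()
                    if k not in _RESERVED_ATTRS
                },
            )
        )
    ids = [g.gene_id for g in out]
    if len(set(ids)) != len(ids):
        raise AnnotationError("duplicate gene ids in annotation set")
    return out


def _fmt_attrs(pairs: list[tuple[str, str]], extra: dict[str, list[str]]) -> str:
    parts = [f"{k}={v}" for k, v in pairs]
    for k, vals in extra.items():
        parts.append(f"{k}={','.join(vals)}")
    return ";".join(parts)


def write_gff3(genes: list[GeneModel], path, source: str = "spliceatlas"):
    """Serialize GeneModels as GFF3: gene, then its mRNAs, then each mRNA's
    sub-features by ascending start. read_gff3 after write_gff3 is the
    identity on the domain model."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            gs, ge = gene.span
            fh.write(
                "\t".join(
                    [
                        gene.seqid, source, "gene", str(gs), str(ge), ".",
                        gene.strand, ".",
                        _fmt_attrs([("ID", gene.gene_id)], gene.attributes),
                    ]
                )
                + "\n"
            )
            for t in gene.transcripts:
                ts, te = t.span
                fh.write(
                    "\t".join(
                        [
                            t.seqid, source, "mRNA", str(ts), str(te), ".",
                            t.strand, ".",
                            _fmt_attrs(
                                [("ID", t.transcript_id), ("Parent", gene.gene_id)],
                                t.attributes,
                            ),
                        ]
                    )
                    + "\n"
                )
                feats = sorted(
                    t.exons + t.cds_parts + t.utr_parts,
                    key=lambda f: (f.start, f.end, EXON_KINDS.index(f.kind)),
                )
                for f in feats:
                    fh.write(
                        "\t".join(
                            [
                                t.seqid, source, f.kind, str(f.start), str(f.end),
                                ".", t.strand, ".",
                                f"Parent={t.transcript_id}",
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Subsequence extraction


def extract_subsequence(genome: GenomeSequence, start: int, end: int, strand: str) -> str:
    """Residues of [start..end] (1-based inclusive); reverse complement on '-'."""
    if strand not in "+-":
        raise AnnotationError(f"strand must be + or -, got {strand!r}")
    if not (1 <= start <= end <= genome.length):
        raise AnnotationError(
            f"coordinates [{start}..{end}] out of range for "
            f"{genome.seqid} (length {genome.length})"
        )
    sub = genome.residues[start - 1 : end]
    return reverse_complement(sub) if strand == "-" else sub


# ---------------------------------------------------------------------------
# PSL

PSL_COLUMNS = 21


def read_psl(path) -> list[SplicedAlignment]:
    """Parse 21-column PSL into SplicedAlignments.

    PSL stores 0-based half-open coordinates; they are converted to 1-based
    inclusive here. For '-' strand rows, qStarts are (per the BLAT
    convention) in reverse-complemented query coordinates and are converted
    to forward-query coordinates.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            first = line.split("\t")[0].split()[0] if line.strip() else ""
            if not first or not first.lstrip("-").isdigit():
                continue  # psLayout header block
            cols = line.split("\t")
            if len(cols) != PSL_COLUMNS:
                raise FormatError(
                    f"{path}: line {lineno}: expected {PSL_COLUMNS} PSL "
                    f"columns, found {len(cols)}"
                )
            matches = int(cols[0])
            mismatches = int(cols[1])
            strand = cols[8][0]
            query_id = cols[9]
            qsize = int(cols[10])
            tname = cols[13]
            nblocks = int(cols[17])
            sizes = [int(x) for x in cols[18].rstrip(",").split(",")]
            qstarts = [int(x) for x in cols[19].rstrip(",").split(",")]
            tstarts = [int(x) for x in cols[20].rstrip(",").split(",")]
            if not (len(sizes) == len(qstarts) == len(tstarts) == nblocks):
                raise FormatError(
                    f"{path}: line {lineno}: block count fields disagree"
                )
            blocks = []
            for size, q0, t0 in zip(sizes, qstarts, tstarts):
                if strand == "-":
                    qf0 = qsize - (q0 + size)  # reverse- to forward-query
                else:
                    qf0 = q0
                blocks.append((t0 + 1, t0 + size, qf0 + 1, qf0 + size))
            out.append(
                SplicedAlignment(
                    query_id=query_id,
                    query_length=qsize,
                    strand=strand,
                    target_seqid=tname,
                    blocks=tuple(blocks),
                    matches=matches,
                    mismatches=mismatches,
                )
            )
    return out


def write_psl(alignments: list[SplicedAlignment], target_sizes: dict[str, int], path):
    """Write SplicedAlignments as 21-column PSL (inverse of read_psl)."""
    with open(path, "w") as fh:
        for a in alignments:
            sizes = [te - ts + 1 for ts, te, _, _ in a.blocks]
            tstarts = [ts - 1 for ts, _, _, _ in a.blocks]
            if a.strand == "-":
                qstarts = [
                    a.query_length - (qs - 1 + size)
                    for (_, _, qs, _), size in zip(a.blocks, sizes)
                ]
            else:
                qstarts = [qs - 1 for _, _, qs, _ in a.blocks]
            qstart0 = min(qs - 1 for _, _, qs, _ in a.blocks)
            qend0 = max(qe for _, _, _, qe in a.blocks)
            tstart0 = a.blocks[0][0] - 1
            tend0 = a.blocks[-1][1]
            qgap_bases = (qend0 - qstart0) - sum(sizes)
            tgap_bases = (tend0 - tstart0) - sum(sizes)
            row = [
                a.matches, a.mismatches, 0, 0,
                max(0, len(a.blocks) - 1) if qgap_bases else 0, qgap_bases,
                max(0, len(a.blocks) - 1) if tgap_bases else 0, tgap_bases,
                a.strand, a.query_id, a.query_length, qstart0, qend0,
                a.target_seqid, target_sizes[a.target_seqid], tstart0, tend0,
                len(a.blocks),
                ",".join(str(s) for s in sizes) + ",",
                ",".join(str(q) for q in qstarts) + ",",
                ",".join(str(t) for t in tstarts) + ",",
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Tabular hits (outfmt 6)

HIT_COLUMNS = 12


def read_tabular_hits(path) -> list[TabularHit]:
    """Parse a 12-column tab-separated hit table (BLAST outfmt 6 order)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != HIT_COLUMNS:
                raise FormatError(
                    f"{path}: line {lineno}: expected {HIT_COLUMNS} columns, "
                    f"found {len(cols)}"
                )
            out.append(
                TabularHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    mismatch=int(cols[4]),
                    gapopen=int(cols[5]),
                    qstart=int(cols[6]),
                    qend=int(cols[7]),
                    sstart=int(cols[8]),
                    send=int(cols[9]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            )
    return out


def write_tabular_hits(hits: list[TabularHit], path):
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                        h.alignment_length, h.mismatch, h.gapopen, h.qstart,
                        h.qend, h.sstart, h.send, f"{h.evalue:.2e}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )
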