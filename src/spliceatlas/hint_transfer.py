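"""Filtering of spliced transcript-to-genome alignments and conversion into
AUGUSTUS-dialect intron/exonpart hints.

This stands in for the classic filterPSL + blat2hints step of hint-guided
gene prediction: transcripts from a well-annotated accession are aligned to
a second genome, poor alignments are discarded, and the surviving block
structure is turned into evidence records. Intron hints carry the exact
intron intervals — including non-canonically spliced ones that ab initio
prediction misses — which is the whole point of the transfer.

Default thresholds: coverage >= 0.90 of the query length and >= 0.95
identity over aligned bases. Target gaps shorter than `min_intron_length`
(default 40 bp) are treated as deletions, not introns; gaps accompanied by
more than `max_query_gap` (default 5 bp) of unaligned query sequence are
treated as missing query coverage, not splicing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation_io import AnnotationError, FormatError, SplicedAlignment

DEFAULT_MIN_INTRON_LENGTH = 40
DEFAULT_MAX_QUERY_GAP = 5
DEFAULT_SOURCE_TOKEN = "spliceatlas"


@dataclass(frozen=True)
class FilterPolicy:
    min_coverage: float = 0.90
    min_identity: float = 0.95
    best_only: bool = True

    def __post_init__(self):
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class Hint:
    """One evidence record in the AUGUSTUS hint dialect."""

    seqid: str
    feature: str  # intron | exonpart
    start: int
    end: int
    strand: str
    source_tag: str = "E"
    priority: int = 4
    group: str = ""
    multiplicity: int = 1

    def __post_init__(self):
        if self.feature not in ("intron", "exonpart"):
            raise ValueError(f"unknown hint feature {self.feature!r}")
        if self.start > self.end:
            raise ValueError(f"hint start {self.start} > end {self.end}")


def alignment_coverage(a: SplicedAlignment) -> float:
    """Fraction of the query covered by aligned bases."""
    if a.query_length <= 0:
        raise AnnotationError(f"{a.query_id}: non-positive query length")
    return (a.matches + a.mismatches) / a.query_length


def alignment_identity(a: SplicedAlignment) -> float:
    """Fraction of aligned bases that match."""
    aligned = a.matches + a.mismatches
    if aligned == 0:
        raise AnnotationError(f"{a.query_id}: no aligned bases, identity undefined")
    return a.matches / aligned


def filter_alignments(
    alignments: list[SplicedAlignment], policy: FilterPolicy = FilterPolicy()
) -> list[SplicedAlignment]:
    """Drop alignments failing coverage/identity; optionally keep only the
    best alignment per query (max matches, then fewest mismatches, then
    smallest target start). Output is stable-sorted by
    (query_id, target_seqid, target_start)."""
    passing = [
        a
        for a in alignments
        if alignment_coverage(a) >= policy.min_coverage
        and alignment_identity(a) >= policy.min_identity
    ]
    if policy.best_only:
        best: dict[str, SplicedAlignment] = {}
        for a in passing:
            cur = best.get(a.query_id)
            if cur is None or _best_key(a) < _best_key(cur):
                best[a.query_id] = a
        passing = list(best.values())
    return sorted(passing, key=lambda a: (a.query_id, a.target_seqid, a.blocks[0][0]))


def _best_key(a: SplicedAlignment):
    return (-a.matches, a.mismatches, a.blocks[0][0])


def alignment_to_hints(
    a: SplicedAlignment,
    min_intron_length: int = DEFAULT_MIN_INTRON_LENGTH,
    max_query_gap: int = DEFAULT_MAX_QUERY_GAP,
    source_tag: str = "E",
    priority: int = 4,
) -> list[Hint]:
    """One exonpart hint per block; one intron hint per inter-block target
    gap that is >= min_intron_length long and has <= max_query_gap of
    unaligned query sequence across it."""
    hints = [
        Hint(
            seqid=a.target_seqid,
            feature="exonpart",
            start=tstart,
            end=tend,
            strand=a.strand,
            source_tag=source_tag,
            priority=priority,
            group=a.query_id,
        )
        for tstart, tend, _, _ in a.blocks
    ]
    for prev, nxt in zip(a.blocks, a.blocks[1:]):
        target_gap = nxt[0] - prev[1] - 1
        # query intervals may run in either direction relative to the target
        lo, hi = sorted([(prev[2], prev[3]), (nxt[2], nxt[3])])
        query_gap = hi[0] - lo[1] - 1
        if target_gap >= min_intron_length and query_gap <= max_query_gap:
            hints.append(
                Hint(
                    seqid=a.target_seqid,
                    feature="intron",
                    start=prev[1] + 1,
                    end=nxt[0] - 1,
                    strand=a.strand,
                    source_tag=source_tag,
                    priority=priority,
                    group=a.query_id,
                )
            )
    return hints


def merge_hints(hints: list[Hint]) -> list[Hint]:
    """Collapse identical (seqid, feature, start, end, strand) hints into one
    record carrying their multiplicity; the group of the first occurrence is
    kept."""
    merged: dict[tuple, Hint] = {}
    for h in hints:
        key = (h.seqid, h.feature, h.start, h.end, h.strand)
        if key in merged:
            cur = merged[key]
            merged[key] = Hint(
                seqid=cur.seqid, feature=cur.feature, start=cur.start,
                end=cur.end, strand=cur.strand, source_tag=cur.source_tag,
                priority=cur.priority, group=cur.group,
                multiplicity=cur.multiplicity + h.multiplicity,
            )
        else:
            merged[key] = h
    return list(merged.values())


def write_hints_gff(hints: list[Hint], path, source_token: str = DEFAULT_SOURCE_TOKEN):
    """9-column hint GFF, sorted by (seqid, start, end).

    Attribute column: grp=<group>;pri=<priority>;src=<source_tag> with a
    mult=<n> field appended for merged hints.
    """
    with open(path, "w") as fh:
        for h in sorted(hints, key=lambda h: (h.seqid, h.start, h.end)):
            attrs = f"grp={h.group};pri={h.priority};src={h.source_tag}"
            if h.multiplicity > 1:
                attrs += f";mult={h.multiplicity}"
            fh.write(
                "\t".join(
                    [
                        h.seqid, source_token, h.feature, str(h.start),
                        str(h.end), ".", h.strand, ".", attrs,
                    ]
                )
                + "\n"
            )


def read_hints_gff(path) -> list[Hint]:
    """Inverse of write_hints_gff."""
    hints = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 columns, found {len(cols)}"
                )
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            hints.append(
                Hint(
                    seqid=cols[0],
                    feature=cols[2],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    source_tag=attrs.get("src", "E"),
                    priority=int(attrs.get("pri", 4)),
                    group=attrs.get("grp", ""),
                    multiplicity=int(attrs.get("mult", 1)),
                )
            )
    return hints
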