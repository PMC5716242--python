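# Methods

## Scope and model

The package operates on four objects: genome sequences over {A,C,G,T,N},
gene models (gene → transcript isoforms → exon/CDS/UTR intervals),
block-structured spliced alignments, and pairwise similarity hit tables.
All internal coordinates are 1-based inclusive (the GFF3 convention); PSL's
0-based half-open block coordinates, and its reversed query coordinates on
minus-strand rows, are converted at the parser boundary so no other module
handles more than one convention. Lowercase residues are uppercased and any
IUPAC ambiguity code outside ACGTN collapses to N on read: downstream, an N
in a splice dinucleotide means "evidence missing", never "non-canonical".

## Splice-site inventory

An intron is the gap between two consecutive exons of a transcript; introns
are derived from exon chains, not CDS chains, so UTR-spanning introns count
(they are spliced out of the primary transcript like any other). The donor
is the intron's first dinucleotide and the acceptor its last, both read
5'→3' in transcript orientation — on the minus strand these are reverse
complements of the genomic termini, and intron ordinals count from the
transcript's 5' end. Gaps shorter than 4 bp cannot hold two dinucleotides
and are treated as annotation errors rather than silently skipped.

Pair classes are `canonical_gt_ag`, `gc_ag`, `at_ac`, `other` (any other
N-free pair) and `ambiguous` (an N anywhere). Two flagging policies decide
which classes mark a gene as "non-canonically spliced": the default counts
everything except GT-AG, a strict variant counts only `{at_ac, other}`;
ambiguous introns never flag a gene. Inventories can be built over each
gene's representative transcript only (the isoform with the longest CDS,
ties to the lexicographically smallest transcript id) or over all isoforms.
Intron events are counted per analyzed transcript, so an intron shared by
two isoforms counts twice under the all-isoforms scope; with the
all-isoforms scope the gene-level medians reported by
`summarize_noncanonical_genes` are still taken over representative
transcripts — the scope only widens which isoforms can flag a gene.
Percentages are rendered with decimal half-up rounding at a caller-chosen
precision, because that is how such inventories are conventionally printed;
medians of even-sized sets are the mean of the central pair, and the median
of an empty set is an error, never a sentinel.

## Hint transfer

Alignment filtering uses coverage = (matches+mismatches)/query_length and
identity = matches/(matches+mismatches), with defaults of 0.90 and 0.95 —
the thresholds conventionally demanded of read evidence in this setting.
With `best_only` (default), one alignment per query survives: maximal
matches, then fewest mismatches, then smallest target start. Conversion
emits one `exonpart` hint per block and one `intron` hint per inter-block
gap that is at least `min_intron_length` (default 40 bp, below which a
target gap is read as a deletion) and spans at most `max_query_gap`
(default 5 bp) of unaligned query sequence (more unaligned query means
missing coverage, not splicing). Hints carry group (query id), priority
(default 4) and source tag (default `E`); identical hints can optionally be
merged with a recorded multiplicity. The hint GFF dialect is bit-stable:
`seqid  spliceatlas  feature  start  end  .  strand  .  grp=..;pri=..;src=..`
sorted by (seqid, start, end), and reading it back is the exact inverse of
writing.

## RBH pairing

Per query, rows are first reduced to the best row per subject, then the
winner maximizes bitscore with ties broken by smaller e-value and then
lexicographically smallest subject id — the published pipelines this
mirrors do not document their tie behavior, so a deterministic rule is
fixed here. A couple requires agreement in both directions, which makes the
result one-to-one by construction. The built-in scorer (exhaustive local
alignment on representative-CDS nucleotide sequences, match +1, mismatch
−1, gap −2, via Biopython's PairwiseAligner) exists so simulated gene sets
can be paired without an external search tool; it is quadratic in the
number of genes and is not a BLAST replacement.

## Structural comparison

Loci are paired greedily: all same-strand overlapping gene-span pairs,
accepted in descending overlap (ties by smaller first-set start, then ids),
each gene used once. A feature "matches" only on exact coordinate identity
of a same-kind feature at the paired locus; the pooled percentage
`100·(matched_A+matched_B)/(features_A+features_B)` counts unpaired loci's
features in the denominator and is symmetric in the two sets. Exact
identity is a deliberately strict reading of annotation agreement — a 1 bp
shift is a mismatch — which makes the statistic conservative and easy to
reason about; sensitivity/specificity-style decompositions per structure
level are out of scope. UTR features are compared as annotated
(`five_prime_UTR`/`three_prime_UTR` rows), not recomputed from exon−CDS
differences.

## Synthetic accessions

The generator is the package's experimental substrate and its oracle.
Defaults describe one simulated study condition: 40 genes on two 120 kb
chromosomes, uniform 1–15 exons per gene, exon lengths 60–300 bp, intron
lengths 60–200 bp, UTRs 30–150 bp, one or two isoforms per gene, both
strands, class mixture 98.8% GT-AG / 1.0% GC-AG / 0.1% AT-AC / 0.1% other
(the composition of a deeply annotated plant reference annotation), second
isoforms skipping one internal exon, and 1% accession divergence. Fractional
mixtures are converted to exact counts by largest-remainder apportionment,
and `other`-class pairs are taken round-robin from an explicit pool
(default `GA-AG`, `GC-CT` — pairs with experimentally confirmed precedents
in plants), so expected inventories are exact, never stochastic.
`noncanonical_in_rich_genes` restricts non-canonical intron placement to
genes with ≥ 8 exons, reproducing the empirical accumulation of
non-canonical splice sites in exon-rich transcripts; it fails loudly when
the rich genes cannot host the requested introns.

Sequence is i.i.d. uniform over ACGT with each intron's terminal
dinucleotides overwritten according to its assigned class
(reverse-complemented on minus-strand genes); terminal exons always retain
roughly 30 coding bp after UTR trimming so CDS sequences stay long enough
to anchor similarity searches. Isoform 2 shares the representative's UTR
trims, which guarantees the full-length isoform remains the longest-CDS
isoform; the merged intron created by skipping an exon takes the left
intron's donor and the right intron's acceptor, and its class is recorded
in the truth table like any other. The accession genome substitutes bases
independently at the configured rate but never touches the four
intron-terminal bases of any annotated intron, so the truth table remains
valid for both accessions; indels are excluded so true coordinates are
shared. True alignments are what a perfect spliced aligner would report
(one block per exon at the annotated coordinates, match counts computed
base-by-base against the target genome); hit tables come from the built-in
scorer. A given seed makes every artifact byte-identical across runs.

What the simulation does **not** model: realistic base composition and
codon structure, splice-site consensus beyond the terminal dinucleotides,
indel or structural divergence, expression levels, and alignment error.
Tests passing on this substrate therefore demonstrate the correctness of
the bookkeeping, classification, conversion and pairing logic under clean
evidence — not robustness to noisy alignments or assembly artifacts.

## Numerical and size choices

Everything in the package is exact integer/string computation except the
local-alignment scores; no tolerances are needed anywhere. Problem sizes
used by the test suite and the acceptance script (12–40 genes, 60–130 kb
chromosomes, 20 simulation replicates, 100 random RBH instances up to
50×50) keep a full run within seconds while leaving every code path —
both strands, multiple isoforms, every splice class, deleted genes,
boundary perturbations — exercised. The controlled perturbation used in
comparison experiments shifts the start of a chosen fraction of
representative CDS parts by +1 bp inside their exon, which changes the
match statistic by a known amount without moving gene spans or changing
which isoform is representative.
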