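# spliceatlas

Most plant introns start with `GT` and end with `AG`, and ab initio gene
predictors all but hard-code that rule. A small but real minority of introns
— minor-class `GC-AG` and `AT-AC` introns, and rarer pairs such as `GA-AG`
or `GC-CT` — therefore go missing when a newly assembled accession genome is
annotated from sequence alone, truncating or splitting otherwise
well-conserved genes. The practical fix is annotation transfer: align the
transcripts of a deeply annotated reference accession to the new assembly
and feed the resulting intron/exon evidence ("hints") into a hint-aware
gene predictor, which can then place non-canonical splice sites exactly
where the evidence says they are.

`spliceatlas` implements the computational spine of that workflow for
*Arabidopsis thaliana*-style accession pairs, plus the simulator needed to
test every step against known ground truth:

* **Splice-site inventory** — extract every intron of every (or every
  representative) transcript, read its donor/acceptor dinucleotides in
  transcript orientation, classify the pair (`GT-AG` / `GC-AG` / `AT-AC` /
  other / ambiguous), and tabulate frequencies and per-gene non-canonical
  flags. The representative transcript of a gene is its isoform with the
  longest CDS.
* **Hint transfer** — filter spliced transcript-to-genome alignments (PSL)
  by coverage ≥ 0.90 and identity ≥ 0.95, then convert surviving block
  structures into AUGUSTUS-dialect `intron`/`exonpart` hint records.
* **RBH orthology** — reciprocal best hits from two directed similarity
  tables (BLAST outfmt-6 dialect): genes *a* and *b* are a couple when each
  is the other's highest-bitscore hit.
* **Gene-set comparison** — pair loci of two annotations greedily by
  same-strand overlap and report the pooled exact-coordinate feature match,
  `100·(matched_A + matched_B)/(features_A + features_B)`, for CDS and UTR
  features, plus gene counts and median CDS lengths.
* **Synthetic accessions** — a deterministic generator producing a
  reference genome + multi-isoform annotation with an exact configured
  splice-class mixture, a point-mutated second accession whose splice sites
  are preserved, transcript FASTA, true spliced alignments and hit tables —
  with a truth table that serves as the oracle for everything above.

## Worked example

```bash
spliceatlas simulate --seed 9 --outdir sim9
spliceatlas inventory --gff3 sim9/reference.gff3 --fasta sim9/reference.fa \
    --scope all --out inv.tsv
spliceatlas hints --psl sim9/true_alignments.psl --merge --out hints.gff
```

prints

```
40 genes on 2 chromosomes, 463 truth introns -> sim9
463 introns, 2 distinct pairs, 4 non-canonical genes -> inv.tsv
40/40 alignments kept, 730 hints -> hints.gff
```

and the head of `inv.tsv` is

```
# pair	count	percent
GT-AG	458	98.9
GC-AG	5	1.1
```

i.e. with the default (Araport11-like) class mixture, 98.9% of the 463
annotated introns are canonical `GT-AG`; the 5 `GC-AG` introns flag 4 genes
as non-canonically spliced. Every one of the 463 true introns reappears as
an exact-coordinate intron hint after aligning the reference transcripts to
the mutated accession genome — that exactness is what lets a downstream
predictor recover splice sites its models would never propose.

The same steps are available as a narrated analysis under `analysis/`
(`01_simulate_accessions.py` … `05_compare_gene_sets.py`), each writing its
tables to `results/`.

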