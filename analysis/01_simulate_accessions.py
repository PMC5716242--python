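"""Simulate the paired accessions and write the raw files other tools would
consume (genome FASTA, GFF3, transcript FASTA, true spliced alignments,
truth table), plus a small summary table of what was generated.

Large sequence files go to scratch/sim/; the summary lands in results/.
"""

import sys
from pathlib import Path

sys.path.append(str(Path(__file__).resolve().parent))
from study_config import RESULTS, SCRATCH, STUDY_CONFIG, load_study_data

from spliceatlas.annotation_io import write_fasta, write_gff3
from spliceatlas.synthetic_data import (
    emit_transcripts,
    emit_true_alignments,
    write_truth_table,
)


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    genomes, genes, truth, acc_genomes, acc_genes = load_study_data()

    write_fasta(genomes, SCRATCH / "reference.fa")
    write_gff3(genes, SCRATCH / "reference.gff3")
    write_fasta(acc_genomes, SCRATCH / "accession.fa")
    write_gff3(acc_genes, SCRATCH / "accession.gff3")
    emit_transcripts(genes, genomes, SCRATCH / "transcripts.fa")
    emit_true_alignments(
        genes, genomes, acc_genomes, SCRATCH / "true_alignments.psl"
    )
    write_truth_table(truth, SCRATCH / "truth_table.tsv")

    n_tx = sum(len(g.transcripts) for g in genes)
    n_rep_introns = sum(t.in_representative for t in truth)
    n_nc = sum(
        t.in_representative and t.label != "canonical_gt_ag" for t in truth
    )
    with open(RESULTS / "simulation_summary.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"seed\t{STUDY_CONFIG.seed}\n")
        fh.write(f"chromosomes\t{len(genomes)}\n")
        fh.write(f"genes\t{len(genes)}\n")
        fh.write(f"transcripts\t{n_tx}\n")
        fh.write(f"representative_introns\t{n_rep_introns}\n")
        fh.write(f"noncanonical_representative_introns\t{n_nc}\n")
        fh.write(f"divergence\t{STUDY_CONFIG.divergence}\n")
    print(
        f"Simulated {len(genes)} genes ({n_tx} transcripts, {n_rep_introns} "
        f"representative introns, {n_nc} non-canonical) on {len(genomes)} "
        f"chromosomes; files in {SCRATCH}, summary in results/simulation_summary.tsv"
    )


if __name__ == "__main__":
    main()
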