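"""Shared study conditions for the numbered analysis drivers.

One reference accession with an Araport11-like splice-class composition,
non-canonical introns biased into exon-rich genes, and a 1%-diverged second
accession. All drivers regenerate the same dataset deterministically from
this config, so they can be run independently and in any order.
"""

from pathlib import Path

from spliceatlas.synthetic_data import (
    SyntheticConfig,
    generate_accession,
    generate_reference,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "sim"

STUDY_CONFIG = SyntheticConfig(
    seed=1,
    n_chromosomes=2,
    chromosome_length=120_000,
    n_genes=40,
    class_mix={
        "canonical_gt_ag": 0.90,
        "gc_ag": 0.06,
        "at_ac": 0.02,
        "other": 0.02,
    },
    noncanonical_in_rich_genes=True,
    divergence=0.01,
)


def load_study_data():
    genomes, genes, truth = generate_reference(STUDY_CONFIG)
    acc_genomes, acc_genes = generate_accession(STUDY_CONFIG, genomes, genes, truth)
    return genomes, genes, truth, acc_genomes, acc_genes
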