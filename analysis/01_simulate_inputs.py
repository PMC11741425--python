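#!/usr/bin/env python
"""Generate every synthetic input for the downstream analyses.

Writes a 5 Mb i.i.d. genome, a de novo trio mutation VCF placed at the
default study-condition rates, a popSTR-style locus/event table pair, and a
kernel-generated pseudo-empirical length distribution, all seeded.
"""

from pathlib import Path

from repeatflux import io as rio
from repeatflux.mutation_kernel import MEDIUM_SCHEDULE
from repeatflux.repeat_catalog import motif_class
from repeatflux.synthetic_data import (DEFAULT_TRUTH, generate_iid_genome,
                                       generate_popstr_table,
                                       generate_pseudo_empirical,
                                       generate_trio_table)

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "inputs"
SEED = 20240901


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    truth = DEFAULT_TRUTH

    genome = {"chr1": generate_iid_genome(5_000_000, p_a=0.3, seed=SEED)}
    rio.write_fasta(genome, SCRATCH / "genome.fa")
    print(f"genome: 5 Mb i.i.d. (A fraction 0.3) -> {SCRATCH/'genome.fa'}")

    records = generate_trio_table(genome, truth, n_offspring=5000,
                                  seed=SEED + 1)
    rio.write_vcf(records, genome, OUT / "trios.vcf")
    n_subs = sum(r.is_substitution for r in records)
    print(f"trios: {len(records)} de novo records "
          f"({n_subs} substitutions) from 5000 offspring -> trios.vcf")

    loci, events, contig = generate_popstr_table(
        truth.scaled(100), n_loci=2000, n_trios=5000, seed=SEED + 2)
    loci.to_csv(SCRATCH / "popstr_loci.tsv", sep="\t", index=False)
    events.to_csv(SCRATCH / "popstr_events.tsv", sep="\t", index=False)
    rio.write_fasta(contig, SCRATCH / "popstr_reference.fa")
    print(f"popSTR: {len(loci)} loci, {len(events)} transmission events")

    emp = generate_pseudo_empirical(truth, MEDIUM_SCHEDULE,
                                    genome_repeat_total=2e6, l_boundary=60,
                                    seed=SEED + 3, noise=True)
    rio.write_distribution_tsv(emp, motif_class("A"), OUT / "empirical.tsv")
    print(f"pseudo-empirical distribution: {emp.total():.3g} repeats, "
          f"longest {emp.max_length()} units -> empirical.tsv")


if __name__ == "__main__":
    main()
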