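"""Simulate the study system: a genome trio with known ground truth.

Builds an ancestral genome (autosome / X / Y contigs carrying interspersed
TEs and ITR-style tandem arrays), an inversion-derived genome, a second
"strain" genome sharing one inversion, male and female read libraries, and
an all-sites haplotype table for two populations. Everything downstream
(02-07) reads the files this writes under results/data/.
"""

import json
from pathlib import Path

import numpy as np

from rearrkit.io_formats import write_fasta, write_fastq, write_repeat_out
from rearrkit.synthetic import (GenomeBlueprint, InversionSpec,
                                RepeatInsertSpec, build_genome, derive_genome,
                                simulate_haplotypes, simulate_sex_reads,
                                write_allsites_vcf)

SEED = 20260922
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def consensus(n):
        return rng.choice(bases, n).tobytes().decode()

    blueprint = GenomeBlueprint(
        contigs=[("chr2", 150_000, "autosome"), ("chr5", 150_000, "autosome"),
                 ("chrX", 120_000, "X"), ("chrY", 100_000, "Y")],
        repeats=[
            # DAIBAM copies spanning each planned inversion boundary, echoing
            # the MITE-at-breakpoints association, plus dispersed copies
            RepeatInsertSpec("DAIBAM", consensus(400), "interspersed",
                             divergence=6.0, subclass="DNA_TIR",
                             fixed_loci=(("chr2", 29_850), ("chr2", 37_850),
                                         ("chr2", 79_850), ("chr2", 109_850))),
            RepeatInsertSpec("DAIBAM", consensus(400), "interspersed",
                             n_loci=8, divergence=6.0, subclass="DNA_TIR"),
            RepeatInsertSpec("Jockey-1", consensus(2_500), "interspersed",
                             n_loci=6, divergence=14.0, subclass="LINE"),
            RepeatInsertSpec("172TR", consensus(180), "tandem_array",
                             n_loci=8, divergence=9.0,
                             array_length_range=(500, 8_000),
                             target_contigs=("chr5",)),
        ],
        gc=0.4, seed=SEED)
    ancestor, hits, truth = build_genome(blueprint)

    shared = InversionSpec("chr2", 30_000, 38_000)       # In(2)a analogue
    private = InversionSpec("chr2", 80_000, 110_000)     # In(2)b analogue
    strain1, t1 = derive_genome(ancestor, [shared, private])
    strain2, t2 = derive_genome(ancestor, [shared])
    truth.breakpoints = t1.breakpoints

    male, female = simulate_sex_reads(ancestor, blueprint.sex_labels,
                                      read_length=100, depth_per_copy=20.0,
                                      error_rate=0.002, seed=SEED + 1)
    table, hap_truth = simulate_haplotypes(100_000, 8, theta=0.01, d_b=0.05,
                                           seed=SEED + 2)
    truth.theta, truth.d_b = hap_truth.theta, hap_truth.d_b

    write_fasta(ancestor, OUT / "ancestor.fasta")
    write_fasta(strain1, OUT / "strain1.fasta")
    write_fasta(strain2, OUT / "strain2.fasta")
    write_repeat_out(hits, OUT / "repeats.out")
    write_fastq(male, OUT / "male.fastq")
    write_fastq(female, OUT / "female.fastq")
    write_allsites_vcf(table, OUT / "allsites.vcf")
    with open(OUT / "populations.tsv", "w") as fh:
        for s in table.samples:
            fh.write(f"{s}\t{s.split('_')[0]}\n")
    truth.to_json(OUT / "truth.json")
    (OUT / "strain_inversions.json").write_text(json.dumps({
        "strain1": [[i.contig, i.start, i.end] for i in (shared, private)],
        "strain2": [[shared.contig, shared.start, shared.end]]}, indent=1))

    print(f"wrote simulated trio to {OUT}")
    print(f"  contigs: {[(r.id, len(r)) for r in ancestor]}")
    print(f"  planted inversions: shared {shared.start}-{shared.end}, "
          f"strain1-private {private.start}-{private.end} on chr2")
    print(f"  repeats: {len(hits)} annotated copies; reads: "
          f"{len(male)} male / {len(female)} female")


if __name__ == "__main__":
    main()
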