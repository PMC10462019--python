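"""Classify contigs as Y / X / autosome from the sexed read libraries.

Single-copy 15-mers of each contig are checked against the female read
k-mer set (quality cutoff 5, count >= 2), and per-contig male/female depth
comes from exact-seed read placement; the two evidence axes drive the call.
"""

from pathlib import Path

from rearrkit.io_formats import read_fasta, read_fastq
from rearrkit.ychrom import KmerParams, build_sex_evidence

DATA = Path("results/data")
OUT = Path("results/ycontigs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(DATA / "ancestor.fasta")
    male = read_fastq(DATA / "male.fastq")
    female = read_fastq(DATA / "female.fastq")
    evidence = build_sex_evidence(genome, male, female,
                                  KmerParams(k=15, min_qual=5))
    with open(OUT / "evidence.tsv", "w") as fh:
        fh.write("contig\tn_single_copy\tpct_unmatched\tmean_male\t"
                 "mean_female\tratio\tcall\n")
        for ev in evidence:
            pct = "NA" if ev.pct_unmatched is None else f"{ev.pct_unmatched:.2f}"
            ratio = "NA" if ev.ratio is None else f"{ev.ratio:.3f}"
            fh.write(f"{ev.contig}\t{ev.n_single_copy}\t{pct}\t"
                     f"{ev.mean_male:.2f}\t{ev.mean_female:.2f}\t{ratio}\t"
                     f"{ev.call}\n")
    for ev in evidence:
        print(f"{ev.contig}: call={ev.call} "
              f"(F/M ratio {ev.ratio:.3f}, {ev.pct_unmatched:.1f}% "
              f"single-copy k-mers unmatched by female reads)")


if __name__ == "__main__":
    main()
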