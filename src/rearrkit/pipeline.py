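"""End-to-end demo pipeline: simulate -> align -> call -> test -> report.

One seeded configuration drives every stage over a synthetic genome trio
(ancestor + inversion-derived genome, sexed read libraries, repeat
annotation, all-sites haplotypes); outputs land in a run directory with a
manifest recording parameters and content hashes, so a rerun with the same
config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path

import numpy as np

from . import alignment, enrichment, landscape, popgen, rearrangements, ychrom
from .io_formats import (read_fasta, write_bed, write_fasta, write_fastq,
                         write_repeat_out, write_segment_table,
                         read_segment_table, read_repeat_out, read_allsites_vcf,
                         read_populations)
from .synthetic import (GenomeBlueprint, InversionSpec, RepeatInsertSpec,
                        build_genome, derive_genome, simulate_haplotypes,
                        simulate_sex_reads, write_allsites_vcf)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    seed: int = 0
    contig_length: int = 80_000
    inversion_lengths: tuple[int, ...] = (5_000, 12_000)
    gc: float = 0.4
    read_length: int = 100
    depth_per_copy: float = 20.0
    read_error: float = 0.002
    min_match_len: int = 100
    min_identity: float = 90.0
    min_span: int = 1000
    anchor_k: int = 31
    kmer_k: int = 15
    min_qual: int = 5
    n_perm: int = 200
    focal_family: str = "MITE1"
    theta: float = 0.01
    d_b: float = 0.05
    n_haplotypes: int = 8
    popgen_window: int = 20_000
    density_window: int = 20_000
    array_merge_gap: int = 500
    hap_length: int = 50_000

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if self.depth_per_copy <= 0 or self.read_length < self.anchor_k:
            raise ValueError("bad read parameters")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "inversion_lengths" in d:
            d = dict(d, inversion_lengths=tuple(d["inversion_lengths"]))
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run every stage into ``outdir``; returns the manifest path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    L = config.contig_length

    # --- simulate ---------------------------------------------------------
    cons_rng = np.random.default_rng(config.seed + 1)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    mite = cons_rng.choice(bases, 400).tobytes().decode()
    line = cons_rng.choice(bases, 2000).tobytes().decode()
    itr = cons_rng.choice(bases, 180).tobytes().decode()
    blueprint = GenomeBlueprint(
        contigs=[("chrA", L, "autosome"), ("chrX", L, "X"), ("chrY", L, "Y")],
        repeats=[
            RepeatInsertSpec("MITE1", mite, "interspersed", n_loci=6,
                             divergence=5.0, subclass="DNA_TIR"),
            RepeatInsertSpec("LINE1", line, "interspersed", n_loci=4,
                             divergence=12.0, subclass="LINE"),
            RepeatInsertSpec("ITR1", itr, "tandem_array", n_loci=5,
                             divergence=8.0, array_length_range=(500, 4000),
                             subclass="ITR"),
        ],
        gc=config.gc, seed=config.seed)
    ancestor, hits, truth = build_genome(blueprint)

    inversions, cursor = [], 5000
    for ln in sorted(config.inversion_lengths):
        start = cursor + int(rng.integers(0, 5000))
        inversions.append(InversionSpec("chrA", start, start + ln))
        cursor = start + ln + 5000
    derived, inv_truth = derive_genome(ancestor, inversions)
    truth.breakpoints = inv_truth.breakpoints

    male, female = simulate_sex_reads(ancestor, blueprint.sex_labels,
                                      config.read_length, config.depth_per_copy,
                                      config.read_error, seed=config.seed + 2)
    table, hap_truth = simulate_haplotypes(config.hap_length, config.n_haplotypes,
                                           config.theta, config.d_b,
                                           seed=config.seed + 3)
    truth.theta, truth.d_b = hap_truth.theta, hap_truth.d_b

    write_fasta(ancestor, out / "ancestor.fasta")
    write_fasta(derived, out / "derived.fasta")
    write_repeat_out(hits, out / "repeats.out")
    write_fastq(male, out / "male.fastq")
    write_fastq(female, out / "female.fastq")
    write_allsites_vcf(table, out / "allsites.vcf")
    with open(out / "populations.tsv", "w") as fh:
        for s in table.samples:
            fh.write(f"{s}\t{s.split('_')[0]}\n")
    truth.to_json(out / "truth.json")

    # --- segments / breakpoints ------------------------------------------
    segments = alignment.find_segments(ancestor, derived,
                                       alignment.AnchorParams(k=config.anchor_k))
    write_segment_table(segments, out / "segments.tsv")
    filtered = alignment.filter_segments(segments, alignment.SegmentFilterParams(
        config.min_match_len, config.min_identity, config.min_span))
    contig_lengths = {r.id: len(r) for r in ancestor}
    calls = rearrangements.detect_rearrangements(filtered, contig_lengths)
    # breakpoint regions for downstream intersection: intervals padded by
    # 100 bp so exact (zero-width) breakpoints still form a region
    pad = 100
    bed_rows = []
    for c in calls:
        for side, (s, e) in (("left", c.left), ("right", c.right)):
            lo = max(0, s - pad)
            hi = min(contig_lengths[c.ref_id], e + pad)
            bed_rows.append((c.ref_id, lo, hi, f"{c.type}_{side}"))
    if bed_rows:
        write_bed(bed_rows, out / "breakpoints.bed")
    with open(out / "calls.json", "w") as fh:
        json.dump([asdict(c) for c in calls], fh, indent=1, default=str)

    # --- enrichment -------------------------------------------------------
    intervals = [(c, s, e) for c, s, e, _name in bed_rows]
    if intervals:
        enr = enrichment.permutation_test(intervals, hits, config.focal_family,
                                          contig_lengths, config.n_perm,
                                          seed=config.seed + 4)
        with open(out / "enrichment.json", "w") as fh:
            json.dump({"observed_bp": enr.observed_bp, "p_value": enr.p_value,
                       "n_perm": enr.n_perm, "subclass_pct": enr.subclass_pct},
                      fh, indent=1)

    # --- Y classification -------------------------------------------------
    evidence = ychrom.build_sex_evidence(
        ancestor, male, female,
        ychrom.KmerParams(config.kmer_k, config.min_qual))
    with open(out / "ycontigs.tsv", "w") as fh:
        fh.write("contig\tn_single_copy\tpct_unmatched\tmean_male\tmean_female"
                 "\tratio\tcall\n")
        for ev in evidence:
            pct = "NA" if ev.pct_unmatched is None else f"{ev.pct_unmatched:.2f}"
            ratio = "NA" if ev.ratio is None else f"{ev.ratio:.3f}"
            fh.write(f"{ev.contig}\t{ev.n_single_copy}\t{pct}\t{ev.mean_male:.2f}"
                     f"\t{ev.mean_female:.2f}\t{ratio}\t{ev.call}\n")

    # --- repeat analytics -------------------------------------------------
    genome_size = sum(contig_lengths.values())
    landscape.landscape(hits, genome_size).to_csv(out / "landscape.tsv",
                                                  sep="\t", index=False)
    landscape.window_density(hits, contig_lengths, config.density_window)\
        .to_csv(out / "windows.tsv", sep="\t", index=False)
    arrays = landscape.call_arrays(hits, config.array_merge_gap,
                                   families=["ITR1"])
    landscape.array_summary(arrays).to_csv(out / "arrays.tsv", sep="\t",
                                           index=False)

    # --- popgen -----------------------------------------------------------
    pops = {"pop0": [s for s in table.samples if s.startswith("pop0")],
            "pop1": [s for s in table.samples if s.startswith("pop1")]}
    pi = popgen.pi_windows(table, pops["pop0"], config.popgen_window,
                           config.hap_length)
    dxy = popgen.dxy_windows(table, pops["pop0"], pops["pop1"],
                             config.popgen_window, config.hap_length)
    with open(out / "popgen.tsv", "w") as fh:
        fh.write("contig\tstart\tend\tstat\tvalue\tn_diffs\tn_comparisons\n")
        for w in pi + dxy:
            v = "NA" if w.value is None else f"{w.value:.6f}"
            fh.write(f"{w.contig}\t{w.start}\t{w.end}\t{w.statistic}\t{v}\t"
                     f"{w.n_diffs:.0f}\t{w.n_comparisons:.0f}\n")

    # --- manifest ---------------------------------------------------------
    outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {"config": asdict(config),
                "outputs": {name: _sha256(out / name) for name in outputs}}
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path
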