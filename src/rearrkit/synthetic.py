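"""Synthetic genomes, reads, annotations and haplotypes with known truth.

The generator emulates the statistical structure the downstream analyses
assume: random-background contigs carrying repeat copies drawn from family
consensus sequences at controlled divergence (interspersed or head-to-tail
tandem arrays), derived genomes differing by inversions with known
breakpoints, sex-specific read libraries with copy-number-correct depth
(female/male expectation 1 on autosomes, 2 on the X, 0 on the Y), and
all-sites haplotype tables with a chosen within-population diversity and
between-population fixed-difference rate.

Mutation is substitution-only (no indels), which keeps divergence and
coordinate bookkeeping exact; every planted feature is echoed in a
:class:`SyntheticTruth` record for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (AllSitesVariantTable, RepeatHit, SequenceRecord,
                         repeat_subclass)

__all__ = [
    "GenomeBlueprint", "RepeatInsertSpec", "InversionSpec", "SyntheticTruth",
    "build_genome", "derive_genome", "simulate_sex_reads",
    "simulate_haplotypes", "write_allsites_vcf", "revcomp",
]

_COMP = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class RepeatInsertSpec:
    """Plan for planting copies of one repeat family.

    ``divergence`` is the target percent divergence of each copy from the
    consensus (i.i.d. substitutions). ``tandem_array`` mode concatenates the
    consensus head-to-tail up to a length drawn uniformly from
    ``array_length_range`` (default the 0.5–10 kb band typical of
    interspersed tandem repeats).
    """

    family: str
    consensus: str
    mode: str = "interspersed"  # or "tandem_array"
    n_loci: int = 1
    divergence: float = 0.0
    array_length_range: tuple[int, int] = (500, 10_000)
    target_contigs: tuple[str, ...] | None = None
    subclass: str | None = None
    #: optional explicit (contig, start) placements; overrides n_loci
    fixed_loci: tuple[tuple[str, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("interspersed", "tandem_array"):
            raise ValueError(f"bad mode {self.mode!r}")
        if not 0 <= self.divergence <= 50:
            raise ValueError("divergence must be in [0, 50] percent")
        if self.subclass is None:
            self.subclass = repeat_subclass(self.family, "")


@dataclass(frozen=True)
class InversionSpec:
    """An inverted block, in ancestor coordinates (0-based half-open)."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start < 2000:
            raise ValueError("inversion blocks must be >= 2 kb to be detectable")


@dataclass
class GenomeBlueprint:
    contigs: list[tuple[str, int, str]]  # (name, length, sex_class)
    repeats: list[RepeatInsertSpec] = field(default_factory=list)
    inversions: list[InversionSpec] = field(default_factory=list)
    gc: float = 0.4
    seed: int = 0
    min_feature_gap: int = 2500  # clear flanks around planted features

    def __post_init__(self) -> None:
        names = [c[0] for c in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        for _, length, sex in self.contigs:
            if length < 1:
                raise ValueError("contig length must be positive")
            if sex not in ("autosome", "X", "Y"):
                raise ValueError(f"bad sex class {sex!r}")
        if not 0 < self.gc < 1:
            raise ValueError("GC fraction must be in (0, 1)")

    @property
    def sex_labels(self) -> dict[str, str]:
        return {name: sex for name, _, sex in self.contigs}


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generator, for parameter-recovery tests."""

    breakpoints: list[tuple[str, int]] = field(default_factory=list)
    sex_labels: dict[str, str] = field(default_factory=dict)
    repeats: list[dict] = field(default_factory=list)
    theta: float | None = None
    d_b: float | None = None
    polymorphic_insertions: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    at, c = (1 - gc) / 2, gc / 2
    return rng.choice(_BASES, size=length, p=[at, c, c, at])


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> tuple[np.ndarray, int]:
    """Apply i.i.d. substitutions at ``rate``; returns (sequence, n_substitutions)."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out, hit.size


def _place_loci(rng: np.random.Generator, contig_len: int, lengths: Sequence[int],
                occupied: list[tuple[int, int]], gap: int) -> list[int]:
    """Choose non-overlapping start positions keeping ``gap`` bp clearance."""
    starts = []
    for ln in lengths:
        hi = contig_len - ln - gap
        if hi <= gap:
            raise ValueError("feature does not fit inside contig")
        for _ in range(2000):
            s = int(rng.integers(gap, hi))
            if all(s + ln + gap <= os or s >= oe + gap for os, oe in occupied):
                occupied.append((s, s + ln))
                starts.append(s)
                break
        else:
            raise ValueError("could not place feature without overlap")
    return starts


def build_genome(blueprint: GenomeBlueprint) -> tuple[list[SequenceRecord], list[RepeatHit], SyntheticTruth]:
    """Emit contigs with planted repeat copies plus their annotation and truth.

    Repeat copies overwrite the random background in place, so planned
    coordinates are exact. Realized per-copy divergence (the substitution
    fraction actually applied) is recorded both in the RepeatHit table and
    in the truth.
    """
    rng = np.random.default_rng(blueprint.seed)
    arrays: dict[str, np.ndarray] = {}
    for name, length, _sex in blueprint.contigs:
        arrays[name] = _random_background(rng, length, blueprint.gc)

    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in arrays}
    hits: list[RepeatHit] = []
    truth = SyntheticTruth(sex_labels=blueprint.sex_labels)

    for spec in blueprint.repeats:
        targets = list(spec.target_contigs or arrays.keys())
        cons = np.frombuffer(spec.consensus.upper().encode(), dtype=np.uint8)
        n_loci = len(spec.fixed_loci) if spec.fixed_loci else spec.n_loci
        for i in range(n_loci):
            if spec.fixed_loci:
                contig, fixed_start = spec.fixed_loci[i]
            else:
                contig = targets[int(rng.integers(len(targets)))]
                fixed_start = None
            if spec.mode == "tandem_array":
                lo, hi = spec.array_length_range
                copy_len = int(rng.integers(lo, hi + 1))
                n_rep = int(np.ceil(copy_len / cons.size))
                copy = np.tile(cons, n_rep)[:copy_len]
            else:
                copy = cons.copy()
            copy, n_sub = _mutate(rng, copy, spec.divergence / 100.0)
            if fixed_start is not None:
                if fixed_start + copy.size > arrays[contig].size:
                    raise ValueError("fixed locus exceeds contig")
                if any(fixed_start < oe and fixed_start + copy.size > os
                       for os, oe in occupied[contig]):
                    raise ValueError("fixed locus overlaps a planned feature")
                occupied[contig].append((fixed_start, fixed_start + copy.size))
                start = fixed_start
            else:
                start = _place_loci(rng, arrays[contig].size, [copy.size],
                                    occupied[contig],
                                    blueprint.min_feature_gap)[0]
            arrays[contig][start:start + copy.size] = copy
            realized = 100.0 * n_sub / copy.size
            strand = "+"
            hits.append(RepeatHit(contig, start, start + copy.size, strand,
                                  spec.family, spec.subclass, realized))
            truth.repeats.append(dict(contig=contig, start=start,
                                      end=start + copy.size, family=spec.family,
                                      mode=spec.mode, divergence=realized))

    records = [SequenceRecord(name, arrays[name].tobytes().decode())
               for name, _l, _s in blueprint.contigs]
    hits.sort(key=lambda h: (h.contig, h.start))
    return records, hits, truth


def derive_genome(ancestor: Sequence[SequenceRecord],
                  inversions: Sequence[InversionSpec]) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Apply inversion blocks (reverse-complement in place) to an ancestor.

    Length and base multiset are conserved per contig; the truth records two
    breakpoints per block (its boundaries in ancestor coordinates). Applying
    the same plan twice restores the ancestor.
    """
    by_contig: dict[str, list[InversionSpec]] = {}
    for inv in inversions:
        by_contig.setdefault(inv.contig, []).append(inv)
    for contig, blocks in by_contig.items():
        blocks.sort(key=lambda b: b.start)
        for a, b in zip(blocks, blocks[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping inversion blocks on {contig}")

    truth = SyntheticTruth()
    derived: list[SequenceRecord] = []
    names = {rec.id for rec in ancestor}
    for inv in inversions:
        if inv.contig not in names:
            raise ValueError(f"unknown contig {inv.contig!r}")
    for rec in ancestor:
        seq = rec.sequence
        for inv in by_contig.get(rec.id, []):
            if inv.end > len(seq):
                raise ValueError(f"inversion exceeds contig {rec.id}")
            seq = seq[:inv.start] + revcomp(seq[inv.start:inv.end]) + seq[inv.end:]
            truth.breakpoints.append((rec.id, inv.start))
            truth.breakpoints.append((rec.id, inv.end))
        derived.append(SequenceRecord(rec.id, seq))
    return derived, truth


# copy numbers per sex per chromosome class
_COPIES = {"female": {"autosome": 2, "X": 2, "Y": 0},
           "male": {"autosome": 2, "X": 1, "Y": 1}}


def simulate_sex_reads(records: Sequence[SequenceRecord], sex_labels: dict[str, str],
                       read_length: int = 100, depth_per_copy: float = 20.0,
                       error_rate: float = 0.002, seed: int = 0,
                       ) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Sample male and female single-end read libraries at copy-correct depth.

    Read counts per contig are Poisson around ``depth_per_copy`` times the
    sex-specific copy number; positions are uniform, strands random, and
    substitution errors are applied at ``error_rate`` per base. Returns
    (male_reads, female_reads) as (id, sequence, quality) tuples.
    """
    if depth_per_copy <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    libraries: dict[str, list[tuple[str, str, str]]] = {"male": [], "female": []}
    for rec in records:
        L = len(rec)
        if L < read_length:
            continue
        arr = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        for sex in ("male", "female"):
            copies = _COPIES[sex][sex_labels[rec.id]]
            if copies == 0:
                continue
            n_reads = int(rng.poisson(depth_per_copy * copies * L / read_length))
            starts = rng.integers(0, L - read_length + 1, size=n_reads)
            flip = rng.random(n_reads) < 0.5
            n_err = rng.binomial(read_length, error_rate, size=n_reads)
            qual = "I" * read_length
            lib = libraries[sex]
            for idx in range(n_reads):
                s = int(starts[idx])
                read = arr[s:s + read_length]
                if n_err[idx]:
                    read = read.copy()
                    for pos in rng.integers(0, read_length, size=n_err[idx]):
                        choices = _BASES[_BASES != read[pos]]
                        read[pos] = rng.choice(choices)
                seq = read.tobytes().decode()
                if flip[idx]:
                    seq = revcomp(seq)
                lib.append((f"{sex[0]}_{rec.id}_{len(lib)}", seq, qual))
    return libraries["male"], libraries["female"]


def _within_poly_rate(theta: float, n: int) -> float:
    """Per-site polymorphism probability giving expected pairwise diversity theta.

    With the derived-allele count drawn uniformly from 1..n-1, the expected
    heterozygosity of a polymorphic site is (n+1)/(3(n-1)); dividing theta by
    that makes E[pi] = theta.
    """
    if n < 2:
        return 0.0
    return theta * 3.0 * (n - 1) / (n + 1)


def simulate_haplotypes(length: int, n_per_pop: int, theta: float,
                        d_b: float = 0.0, n_pops: int = 2, seed: int = 0,
                        contig: str = "sim", ) -> tuple[AllSitesVariantTable, SyntheticTruth]:
    """Infinite-sites-style all-sites haplotype table for one or two populations.

    Each site is independently invariant, polymorphic within one population
    (at the rate that makes expected within-population pairwise diversity
    equal ``theta``), or a fixed difference between populations (probability
    ``d_b``). One category per site, so mutation placements never collide.
    """
    if not (0 <= theta < 0.5 and 0 <= d_b < 0.5):
        raise ValueError("theta and d_b must be in [0, 0.5)")
    if n_pops not in (1, 2):
        raise ValueError("only 1 or 2 populations supported")
    rng = np.random.default_rng(seed)
    q = _within_poly_rate(theta, n_per_pop)
    probs = [d_b if n_pops == 2 else 0.0] + [q] * n_pops
    if sum(probs) >= 1:
        raise ValueError("theta/d_b too large for per-site model")

    n_total = n_per_pop * n_pops
    alleles = np.zeros((length, n_total), dtype=np.int8)
    u = rng.random(length)
    # category per site: 0 = fixed difference, 1+p = polymorphic in pop p,
    # len(probs) = invariant
    cat = np.searchsorted(np.cumsum(probs), u, side="right")
    if n_pops == 2:
        alleles[cat == 0, n_per_pop:] = 1
    for p in range(n_pops):
        cols = slice(p * n_per_pop, (p + 1) * n_per_pop)
        for s in np.flatnonzero(cat == p + 1):
            i = int(rng.integers(1, n_per_pop))
            carriers = rng.permutation(n_per_pop)[:i]
            alleles[s, cols][carriers] = 1

    samples = {}
    col = 0
    for p in range(n_pops):
        for j in range(n_per_pop):
            samples[f"pop{p}_{j}"] = [col]
            col += 1
    table = AllSitesVariantTable(contig, np.arange(1, length + 1), alleles, samples)
    truth = SyntheticTruth(theta=theta, d_b=d_b if n_pops == 2 else None)
    return table, truth


def write_allsites_vcf(table: AllSitesVariantTable, path: str | Path) -> None:
    """Write the allele table as a plain-text all-sites VCF v4.2."""
    length = int(table.positions.max()) if table.n_sites else 0
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={table.contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i, pos in enumerate(table.positions):
            row = table.alleles[i]
            alt = "T" if (row > 0).any() else "."
            gts = []
            for sample in table.samples:
                cols = table.sample_columns[sample]
                gts.append("/".join("." if row[c] < 0 else str(int(row[c]))
                                    for c in cols))
            fh.write(f"{table.contig}\t{int(pos)}\t.\tA\t{alt}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")
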