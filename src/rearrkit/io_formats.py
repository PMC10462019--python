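"""Readers and writers for the external formats the pipeline touches.

Every coordinate inside the package is 0-based, half-open. Conversions to and
from 1-based inclusive conventions (``show-coords``-style tables, RepeatMasker
``.out``, VCF positions) happen here and only here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SequenceRecord",
    "SegmentMatch",
    "RepeatHit",
    "AllSitesVariantTable",
    "FormatError",
    "SUBCLASSES",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_segment_table",
    "write_segment_table",
    "read_repeat_out",
    "write_repeat_out",
    "read_bed",
    "write_bed",
    "read_allsites_vcf",
    "read_populations",
    "repeat_subclass",
]

DNA_ALPHABET = set("ACGTN")

#: closed set of repeat subclasses used throughout the analytics
SUBCLASSES = ("LINE", "LTR", "DNA_TIR", "Helitron_DINE_TR", "ITR", "Unknown", "Simple")


class FormatError(ValueError):
    """A file violated the format contract (bad syntax or invariants)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SegmentMatch:
    """One aligned block between a reference and a query genome.

    Coordinates are 0-based half-open on both sequences; ``strand`` is "+"
    when the query block runs in the same orientation as the reference and
    "-" when it is reverse-complemented. ``pct_identity`` is percent in
    [0, 100]; ``match_len`` is the number of aligned bases.
    """

    ref_id: str
    ref_start: int
    ref_end: int
    qry_id: str
    qry_start: int
    qry_end: int
    strand: str
    pct_identity: float
    match_len: int

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start or self.qry_end <= self.qry_start:
            raise FormatError(f"empty or negative segment span: {self}")
        if self.strand not in "+-":
            raise FormatError(f"bad strand {self.strand!r}")
        if self.match_len > max(self.ref_end - self.ref_start, self.qry_end - self.qry_start):
            raise FormatError(f"match_len exceeds both spans: {self}")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_span(self) -> int:
        return self.qry_end - self.qry_start


@dataclass(frozen=True)
class RepeatHit:
    """A single annotated repeat interval (one RepeatMasker-style record)."""

    contig: str
    start: int
    end: int
    strand: str
    family: str
    subclass: str
    pct_divergence: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"empty repeat hit: {self}")
        if self.subclass not in SUBCLASSES:
            raise FormatError(f"unknown subclass {self.subclass!r}")
        if not np.isfinite(self.pct_divergence):
            raise FormatError("non-finite divergence")

    def __len__(self) -> int:
        return self.end - self.start


class AllSitesVariantTable:
    """Per-site allele matrix over every position of a contig window.

    ``positions`` are 1-based (VCF convention); ``alleles`` is an
    (n_sites, n_allele_columns) int8 matrix with -1 for missing calls.
    Haploid samples contribute one column, diploids two; ``sample_columns``
    maps each sample name to its column indices.
    """

    def __init__(self, contig: str, positions: np.ndarray, alleles: np.ndarray,
                 sample_columns: dict[str, list[int]]):
        positions = np.asarray(positions, dtype=np.int64)
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.shape[0] != positions.shape[0]:
            raise ValueError("positions/alleles length mismatch")
        if positions.size and np.any(np.diff(positions) <= 0):
            raise FormatError("positions not strictly increasing")
        self.contig = contig
        self.positions = positions
        self.alleles = alleles
        self.sample_columns = sample_columns

    @property
    def samples(self) -> list[str]:
        return list(self.sample_columns)

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def columns_for(self, samples: Sequence[str]) -> list[int]:
        cols: list[int] = []
        for s in samples:
            if s not in self.sample_columns:
                raise KeyError(f"unknown sample {s!r}")
            cols.extend(self.sample_columns[s])
        return cols


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file strictly: unique ids, non-empty uppercase ACGTN."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"empty sequence for {name!r}")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(f"illegal characters {sorted(bad)} in {name!r}")
        records.append(SequenceRecord(name, seq))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 and line[1:].split() else ""
                if not name:
                    raise FormatError("record with empty id")
                if name in seen:
                    raise FormatError(f"duplicate id {name!r}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise FormatError("sequence data before first header")
                chunks.append(line.strip())
    flush()
    if not records:
        raise FormatError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTQ as (id, sequence, quality) tuples."""
    out = []
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not head.startswith("@") or not plus.startswith("+"):
                raise FormatError("malformed FASTQ record")
            if len(seq) != len(qual):
                raise FormatError("sequence/quality length mismatch")
            out.append((head[1:].split()[0], seq.upper(), qual))
    return out


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Segment tables

SEGMENT_COLUMNS = ("ref_id", "ref_start", "ref_end", "qry_id", "qry_start",
                   "qry_end", "strand", "pct_identity", "match_len")


def write_segment_table(segments: Iterable[SegmentMatch], path: str | Path) -> None:
    """Write the internal segment TSV (0-based half-open, headered)."""
    with open(path, "w") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for s in segments:
            fh.write(f"{s.ref_id}\t{s.ref_start}\t{s.ref_end}\t{s.qry_id}\t"
                     f"{s.qry_start}\t{s.qry_end}\t{s.strand}\t{s.pct_identity:.4f}\t"
                     f"{s.match_len}\n")


def read_segment_table(path: str | Path, dialect: str = "internal") -> list[SegmentMatch]:
    """Read alignment segments, normalizing coordinates to 0-based half-open.

    Dialects:

    ``internal``
        the TSV written by :func:`write_segment_table` (already normalized).
    ``coords_tsv``
        ``show-coords``-like: 1-based inclusive columns
        ``ref_start ref_end qry_start qry_end pct_identity ref_id qry_id``;
        a query start greater than its end marks the "-" strand.
    ``paf``
        minimal 12-column PAF (query first, 0-based half-open); identity is
        matches / alignment-block-length.
    """
    segments: list[SegmentMatch] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if dialect == "internal":
                    if parts[0] == "ref_id":
                        continue
                    segments.append(SegmentMatch(
                        parts[0], int(parts[1]), int(parts[2]), parts[3],
                        int(parts[4]), int(parts[5]), parts[6],
                        float(parts[7]), int(parts[8])))
                elif dialect in ("coords", "coords_tsv"):
                    rs, re_, qs, qe = (int(x) for x in parts[:4])
                    ident = float(parts[4])
                    ref_id, qry_id = parts[5], parts[6]
                    strand = "+" if qs <= qe else "-"
                    if strand == "-":
                        qs, qe = qe, qs
                    ref_start, ref_end = rs - 1, re_
                    qry_start, qry_end = qs - 1, qe
                    mlen = max(ref_end - ref_start, qry_end - qry_start)
                    segments.append(SegmentMatch(ref_id, ref_start, ref_end,
                                                 qry_id, qry_start, qry_end,
                                                 strand, ident, mlen))
                elif dialect == "paf":
                    qry_id = parts[0]
                    qs, qe = int(parts[2]), int(parts[3])
                    strand = parts[4]
                    ref_id = parts[5]
                    rs, re_ = int(parts[7]), int(parts[8])
                    nmatch, alen = int(parts[9]), int(parts[10])
                    ident = 100.0 * nmatch / alen if alen else 0.0
                    segments.append(SegmentMatch(ref_id, rs, re_, qry_id, qs, qe,
                                                 strand, ident, alen))
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except (IndexError, ValueError, FormatError) as exc:
                if isinstance(exc, ValueError) and "dialect" in str(exc):
                    raise
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return segments


# ---------------------------------------------------------------------------
# RepeatMasker .out

_ITR_FAMILIES = ("PVB370", "172TR")


def repeat_subclass(family: str, rm_class: str) -> str:
    """Map a RepeatMasker family name + class/family string to a subclass.

    The mapping collapses Helitron-derived names (DINE and relatives) into
    one bucket and routes the interspersed-tandem-repeat families (pvB370,
    172TR and variants) to ITR regardless of the class column; anything
    unrecognized lands in Unknown rather than erroring, mirroring how
    unclassified families are retained in repeat inventories.
    """
    fam = family.upper()
    cls = (rm_class or "").upper()
    if any(tag in fam for tag in _ITR_FAMILIES) or cls == "ITR":
        return "ITR"
    if "DINE" in fam or "DINE" in cls:
        return "Helitron_DINE_TR"
    if rm_class in SUBCLASSES:   # already one of our labels (round trip)
        return rm_class
    top = cls.split("/")[0]
    if top == "LINE":
        return "LINE"
    if top == "LTR":
        return "LTR"
    if top == "DNA":
        return "DNA_TIR"
    if top == "RC" or "HELITRON" in cls:
        return "Helitron_DINE_TR"
    if top in ("SIMPLE_REPEAT", "SATELLITE", "LOW_COMPLEXITY"):
        return "Simple"
    return "Unknown"


def read_repeat_out(path: str | Path) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out``-style table (3 header lines, then records)."""
    hits: list[RepeatHit] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, 1):
        if lineno <= 3 or not line.strip():
            continue
        parts = line.split()
        try:
            pct_div = float(parts[1])
            contig = parts[4]
            start1, end1 = int(parts[5]), int(parts[6])
            strand = "-" if parts[8] in ("C", "-") else "+"
            family = parts[9]
            rm_class = parts[10] if len(parts) > 10 else ""
            hits.append(RepeatHit(contig, start1 - 1, end1, strand, family,
                                  repeat_subclass(family, rm_class), pct_div))
        except (IndexError, ValueError, FormatError) as exc:
            raise FormatError(f"{path}:{lineno}: unparseable record ({exc})") from exc
    return hits


def write_repeat_out(hits: Iterable[RepeatHit], path: str | Path) -> None:
    """Write hits back out in RepeatMasker ``.out`` layout (1-based inclusive)."""
    header = ("   SW   perc perc perc  query     position in query     matching"
              "  repeat          position in repeat\n"
              "score   div. del. ins.  sequence  begin end    (left)   repeat"
              "    class/family    begin end (left) ID\n\n")
    with open(path, "w") as fh:
        fh.write(header)
        for i, h in enumerate(hits, 1):
            strand = "C" if h.strand == "-" else "+"
            fh.write(f"1000 {h.pct_divergence:.1f} 0.0 0.0 {h.contig} "
                     f"{h.start + 1} {h.end} (0) {strand} {h.family} "
                     f"{h.subclass} 1 {len(h)} (0) {i}\n")


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write BED3+ rows; extra tuple fields become extra columns."""
    with open(path, "w") as fh:
        for iv in intervals:
            contig, start, end = iv[0], int(iv[1]), int(iv[2])
            if start >= end:
                raise FormatError(f"empty BED interval {iv}")
            fh.write("\t".join(str(x) for x in (contig, start, end) + tuple(iv[3:])) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    out: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: empty interval")
            out.append((parts[0], start, end, *parts[3:]))
    return out


# ---------------------------------------------------------------------------
# All-sites VCF

def read_allsites_vcf(path: str | Path, contig: str | None = None) -> AllSitesVariantTable:
    """Read a VCF that includes invariant-site records into an allele matrix.

    Both haploid and diploid genotypes are accepted; a diploid sample
    contributes two allele columns. Missing calls become -1. Only one contig
    is read (the first seen, or ``contig`` if given).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    positions: list[int] = []
    rows: list[list[int]] = []
    sample_columns: dict[str, list[int]] | None = None
    target = contig
    for rec in vcf:
        if target is None:
            target = rec.CHROM
        if rec.CHROM != target:
            continue
        gts = rec.genotypes  # per sample: [a1, (a2,) phased]
        if sample_columns is None:
            sample_columns = {}
            col = 0
            for name, g in zip(vcf.samples, gts):
                n_alleles = len(g) - 1
                sample_columns[name] = list(range(col, col + n_alleles))
                col += n_alleles
        row: list[int] = []
        for g in gts:
            row.extend(int(a) for a in g[:-1])
        positions.append(rec.POS)
        rows.append(row)
    vcf.close()
    if sample_columns is None:
        raise FormatError(f"no records for contig {target!r} in {path}")
    alleles = np.asarray(rows, dtype=np.int8)
    return AllSitesVariantTable(target, np.asarray(positions), alleles, sample_columns)


def read_populations(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column sample→population TSV into {population: [samples]}."""
    pops: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = re.split(r"\s+", line)[:2]
            pops.setdefault(pop, []).append(sample)
    return pops
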