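"""Y/X/autosome contig classification from k-mer subtraction and depth.

Two independent lines of evidence per contig:

* the fraction of the contig's unique single-copy k-mers (genome-wide
  canonical count exactly one) that are absent from the female read
  library — Y-linked sequence is missing from females, so this fraction is
  high for Y contigs and near zero elsewhere;
* the female/male mean depth ratio, with copy-number expectations 1 for
  autosomes, 2 for the X and ~0 for the Y.

Reads are quality-masked (bases below Q drop their k-mers) and a female
k-mer must be seen at least twice to count, so sequencing-error k-mers do
not rescue Y contigs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _kmers
from .io_formats import SequenceRecord
from .alignment import unique_kmer_index

__all__ = ["KmerParams", "CallThresholds", "ContigSexEvidence",
           "genome_kmer_counts", "contig_single_copy_kmers", "read_kmer_set",
           "pct_unmatched_by_female", "depth_from_reads", "depth_from_tsv",
           "depth_ratio", "classify_contigs", "build_sex_evidence"]

Read = tuple[str, str, str]  # (id, sequence, quality)


@dataclass(frozen=True)
class KmerParams:
    k: int = 15
    min_qual: int = 5          # bases below this Phred score mask their k-mers
    min_female_count: int = 2  # singleton read k-mers treated as errors

    def __post_init__(self) -> None:
        if not (11 <= self.k <= 31 and self.k % 2 == 1):
            raise ValueError("k must be odd and in [11, 31]")


@dataclass(frozen=True)
class CallThresholds:
    """Decision thresholds for the three-way call (config-overridable)."""

    r_y: float = 0.25       # max female/male ratio for a Y call
    u_y: float = 75.0       # min % unmatched single-copy k-mers for Y
    u_a: float = 25.0       # max % unmatched for an X/autosome call
    m_min: int = 500        # min single-copy k-mers for a Y call
    x_ratio: tuple[float, float] = (1.6, 2.4)
    a_ratio: tuple[float, float] = (0.7, 1.3)


@dataclass
class ContigSexEvidence:
    contig: str
    n_single_copy: int
    pct_unmatched: float | None    # None when the contig has no single-copy k-mers
    mean_male: float
    mean_female: float
    ratio: float | None            # None when male depth is zero
    call: str = "ambiguous"


def genome_kmer_counts(records: Sequence[SequenceRecord], k: int,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes (sorted) and their genome-wide counts."""
    parts = [_kmers.sequence_kmers(rec.sequence, k)[0] for rec in records]
    codes = np.concatenate(parts) if parts else np.empty(0, np.uint64)
    return np.unique(codes, return_counts=True)


def contig_single_copy_kmers(record: SequenceRecord, genome_codes: np.ndarray,
                             genome_counts: np.ndarray, k: int) -> np.ndarray:
    """The contig's canonical k-mers with genome-wide count exactly one."""
    codes, _pos, _fwd = _kmers.sequence_kmers(record.sequence, k)
    codes = np.unique(codes)
    idx = np.searchsorted(genome_codes, codes)
    idx = np.clip(idx, 0, genome_codes.size - 1)
    present = genome_codes.size > 0
    if not present:
        return np.empty(0, np.uint64)
    hit = genome_codes[idx] == codes
    single = hit & (genome_counts[idx] == 1)
    return codes[single]


def _mask_by_quality(seq: str, qual: str, min_qual: int) -> str:
    """Replace low-quality bases by N so their k-mers are excluded."""
    q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33
    if np.all(q >= min_qual):
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    arr[q < min_qual] = ord("N")
    return arr.tobytes().decode()


def read_kmer_set(reads: Sequence[Read], params: KmerParams = KmerParams(),
                  ) -> np.ndarray:
    """Sorted canonical k-mer codes occurring >= min_female_count times.

    Low-quality bases (< min_qual) are masked before k-mer extraction.
    """
    joined = "N".join(_mask_by_quality(seq, qual, params.min_qual)
                      for _id, seq, qual in reads)
    codes, _pos, _fwd = _kmers.sequence_kmers(joined, params.k)
    uniq, counts = np.unique(codes, return_counts=True)
    return uniq[counts >= params.min_female_count]


def pct_unmatched_by_female(contig_kmers: np.ndarray,
                            female_kmers: np.ndarray) -> float | None:
    """Percent of the contig's single-copy k-mers absent from female reads.

    Returns None (flagged, not zero) when the contig set is empty.
    """
    if contig_kmers.size == 0:
        return None
    if female_kmers.size == 0:
        return 100.0
    idx = np.searchsorted(female_kmers, contig_kmers)
    idx = np.clip(idx, 0, female_kmers.size - 1)
    matched = female_kmers[idx] == contig_kmers
    return 100.0 * float(np.sum(~matched)) / contig_kmers.size


# ---------------------------------------------------------------------------
# Depth from the internal exact-seed read placer (or an external TSV)

def depth_from_reads(records: Sequence[SequenceRecord], reads: Sequence[Read],
                     seed_k: int = 31) -> dict[str, np.ndarray]:
    """Per-base depth by placing reads via unique genome seed k-mers.

    Each read is placed where one of its seed k-mers (taken at up to three
    offsets, to tolerate substitution errors) matches a k-mer unique in the
    genome; unplaceable reads are dropped.
    """
    codes, contig_idx, pos, fwd = unique_kmer_index(records, seed_k)
    depth = {rec.id: np.zeros(len(rec) + 1, np.int64) for rec in records}
    names = [rec.id for rec in records]
    lengths = [len(rec) for rec in records]

    by_len: dict[int, list[str]] = {}
    for _id, seq, _q in reads:
        if len(seq) >= seed_k:
            by_len.setdefault(len(seq), []).append(seq)
    two = np.uint64(2)
    for L, seqs in by_len.items():
        mat = _kmers.encode("".join(seqs)).reshape(len(seqs), L)
        placed = np.zeros(len(seqs), bool)
        read_start = np.zeros(len(seqs), np.int64)
        read_contig = np.zeros(len(seqs), np.int32)
        for off in sorted({0, (L - seed_k) // 2, L - seed_k}):
            todo = np.flatnonzero(~placed)
            if todo.size == 0 or codes.size == 0:
                break
            sub = mat[todo, off:off + seed_k]
            valid = (sub < 4).all(axis=1)
            code = np.zeros(todo.size, np.uint64)
            for j in range(seed_k):
                code = (code << two) | (sub[:, j].astype(np.uint64) & np.uint64(3))
            canon, isfwd = _kmers.canonical_codes(code, seed_k)
            i = np.clip(np.searchsorted(codes, canon), 0, codes.size - 1)
            hit = valid & (codes[i] == canon)
            if not hit.any():
                continue
            h = todo[hit]
            gi = i[hit]
            same = fwd[gi] == isfwd[hit]
            placed[h] = True
            read_start[h] = np.where(same, pos[gi] - off, pos[gi] + seed_k + off - L)
            read_contig[h] = contig_idx[gi]
        for ci in np.unique(read_contig[placed]):
            m = placed & (read_contig == ci)
            s = np.clip(read_start[m], 0, lengths[ci])
            e = np.clip(read_start[m] + L, 0, lengths[ci])
            d = depth[names[ci]]
            np.add.at(d, s, 1)
            np.add.at(d, e, -1)
    return {name: np.cumsum(d[:-1]) for name, d in depth.items()}


def depth_from_tsv(path: str | Path, records: Sequence[SequenceRecord],
                   ) -> dict[str, np.ndarray]:
    """Read per-base depth from a (contig, pos0, depth) TSV."""
    depth = {rec.id: np.zeros(len(rec), np.int32) for rec in records}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            contig, p, d = line.split("\t")[:3]
            depth[contig][int(p)] = int(d)
    return depth


def depth_ratio(male_depth: np.ndarray, female_depth: np.ndarray,
                ) -> tuple[float, float, float | None]:
    """(mean male, mean female, female/male ratio); ratio None if male is 0."""
    if male_depth.size != female_depth.size:
        raise ValueError("depth vectors must have equal length")
    mean_m = float(np.mean(male_depth))
    mean_f = float(np.mean(female_depth))
    ratio = mean_f / mean_m if mean_m > 0 else None
    return mean_m, mean_f, ratio


def classify_contigs(evidence: Sequence[ContigSexEvidence],
                     thresholds: CallThresholds = CallThresholds(),
                     ) -> list[ContigSexEvidence]:
    """Assign Y/X/autosome/ambiguous calls from the combined evidence."""
    t = thresholds
    for ev in evidence:
        pct = ev.pct_unmatched
        r = ev.ratio
        call = "ambiguous"
        if (r is not None and pct is not None):
            if r <= t.r_y and pct >= t.u_y and ev.n_single_copy >= t.m_min:
                call = "Y"
            elif t.x_ratio[0] <= r <= t.x_ratio[1] and pct <= t.u_a:
                call = "X"
            elif t.a_ratio[0] <= r <= t.a_ratio[1] and pct <= t.u_a:
                call = "autosome"
        ev.call = call
    return list(evidence)


def build_sex_evidence(records: Sequence[SequenceRecord],
                       male_reads: Sequence[Read], female_reads: Sequence[Read],
                       params: KmerParams = KmerParams(),
                       thresholds: CallThresholds = CallThresholds(),
                       seed_k: int = 31) -> list[ContigSexEvidence]:
    """Full evidence pipeline: k-mer subtraction + placed-read depth + calls."""
    g_codes, g_counts = genome_kmer_counts(records, params.k)
    female_set = read_kmer_set(female_reads, params)
    male_depth = depth_from_reads(records, male_reads, seed_k)
    female_depth = depth_from_reads(records, female_reads, seed_k)
    out = []
    for rec in records:
        sc = contig_single_copy_kmers(rec, g_codes, g_counts, params.k)
        pct = pct_unmatched_by_female(sc, female_set)
        mean_m, mean_f, ratio = depth_ratio(male_depth[rec.id], female_depth[rec.id])
        out.append(ContigSexEvidence(rec.id, int(sc.size), pct, mean_m, mean_f, ratio))
    return classify_contigs(out, thresholds)
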