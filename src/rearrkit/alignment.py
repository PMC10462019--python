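"""Pairwise genome alignment into co-linear segment matches.

A desk-scale stand-in for a whole-genome aligner: unique canonical k-mer
seeds shared by both genomes are merged into exact diagonal runs and then
chained into co-linear segments per (reference contig, query contig,
orientation). Seeds occurring more than once in either genome are discarded
before chaining, so repeats cannot seed spurious segments; identity is
matched bases over the chained span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kmers
from .io_formats import SegmentMatch, SequenceRecord

__all__ = ["AnchorParams", "SegmentFilterParams", "find_segments",
           "filter_segments", "unique_kmer_index"]


@dataclass(frozen=True)
class AnchorParams:
    k: int = 31
    min_anchor_len: int = 31
    max_chain_gap: int = 2000

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError("seed length must be >= 11")
        if self.min_anchor_len < self.k:
            raise ValueError("min anchor length must be >= k")


@dataclass(frozen=True)
class SegmentFilterParams:
    """Default thresholds: matches < 100 bp dropped, then segments below
    90% identity or spanning < 1000 bp (in either sequence) dropped."""

    min_match_len: int = 100
    min_identity: float = 90.0
    min_span: int = 1000

    def __post_init__(self) -> None:
        if min(self.min_match_len, self.min_span) <= 0 or self.min_identity <= 0:
            raise ValueError("filter thresholds must be positive")


def unique_kmer_index(records: Sequence[SequenceRecord], k: int):
    """Genome-wide index of canonical k-mers occurring exactly once.

    Returns (sorted codes, contig index, position, forward-is-canonical)
    arrays, one entry per unique k-mer.
    """
    codes_all, contig_all, pos_all, fwd_all = [], [], [], []
    for ci, rec in enumerate(records):
        codes, pos, fwd = _kmers.sequence_kmers(rec.sequence, k, canonical=True)
        codes_all.append(codes)
        pos_all.append(pos)
        fwd_all.append(fwd)
        contig_all.append(np.full(codes.size, ci, dtype=np.int32))
    codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.uint64)
    contig = np.concatenate(contig_all) if contig_all else np.empty(0, np.int32)
    pos = np.concatenate(pos_all) if pos_all else np.empty(0, np.int64)
    fwd = np.concatenate(fwd_all) if fwd_all else np.empty(0, bool)

    order = np.argsort(codes, kind="stable")
    sc = codes[order]
    uniq = np.ones(sc.size, bool)
    if sc.size > 1:
        same = sc[1:] == sc[:-1]
        uniq[1:] &= ~same
        uniq[:-1] &= ~same
    keep = order[uniq]
    return sc[uniq], contig[keep], pos[keep], fwd[keep]


@dataclass
class _Run:
    """A maximal exact diagonal run of shared unique k-mer anchors."""

    refc: int
    qryc: int
    strand: int  # +1 / -1
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    matched: int


def _diag_runs(refc, rpos, qryc, qpos, strand, k, max_gap) -> list[_Run]:
    """Merge anchors sharing a diagonal into exact runs (vectorized)."""
    diag = np.where(strand == 1, qpos - rpos, qpos + rpos)
    order = np.lexsort((rpos, diag, strand, qryc, refc))
    rc, qc, st, rp, qp, dg = (a[order] for a in (refc, qryc, strand, rpos, qpos, diag))
    if rc.size == 0:
        return []
    newgrp = np.ones(rc.size, bool)
    if rc.size > 1:
        same = ((rc[1:] == rc[:-1]) & (qc[1:] == qc[:-1]) & (st[1:] == st[:-1])
                & (dg[1:] == dg[:-1]) & (rp[1:] - rp[:-1] <= max_gap))
        newgrp[1:] = ~same
    gid = np.cumsum(newgrp) - 1
    n_groups = gid[-1] + 1
    runs: list[_Run] = []
    starts = np.flatnonzero(newgrp)
    ends = np.append(starts[1:], rc.size)
    # matched bases: union of k-windows along the run
    step = np.diff(rp)
    cover = np.minimum(step, k)
    cum = np.concatenate(([0], np.cumsum(cover)))
    for a, b in zip(starts, ends):
        r0, r1 = int(rp[a]), int(rp[b - 1]) + k
        matched = int(k + (cum[b - 1] - cum[a]))
        if st[a] == 1:
            q0, q1 = int(qp[a]), int(qp[b - 1]) + k
        else:
            q0, q1 = int(qp[b - 1]), int(qp[a]) + k
        runs.append(_Run(int(rc[a]), int(qc[a]), int(st[a]), r0, r1, q0, q1, matched))
    return runs


def find_segments(reference: Sequence[SequenceRecord], query: Sequence[SequenceRecord],
                  params: AnchorParams = AnchorParams()) -> list[SegmentMatch]:
    """Align two genomes into co-linear segment matches.

    Anchors are canonical k-mers unique in both genomes; same-diagonal
    anchors merge into exact runs, and runs chain greedily when both the
    reference gap and the query gap are at most ``max_chain_gap`` and the
    query order is consistent with the strand. Output is sorted by
    (ref contig, ref start).
    """
    if not reference or not query:
        raise ValueError("both genomes must be non-empty")
    k = params.k
    r_codes, r_contig, r_pos, r_fwd = unique_kmer_index(reference, k)
    q_codes, q_contig, q_pos, q_fwd = unique_kmer_index(query, k)
    _, ia, ib = np.intersect1d(r_codes, q_codes, assume_unique=True,
                               return_indices=True)
    if ia.size == 0:
        return []
    strand = np.where(r_fwd[ia] == q_fwd[ib], 1, -1).astype(np.int8)
    runs = _diag_runs(r_contig[ia], r_pos[ia], q_contig[ib], q_pos[ib],
                      strand, k, params.max_chain_gap)
    runs = [r for r in runs if r.ref_end - r.ref_start >= params.min_anchor_len]
    runs.sort(key=lambda r: (r.refc, r.ref_start, r.ref_end))

    gap = params.max_chain_gap
    chains: list[_Run] = []
    open_chains: list[_Run] = []
    for run in runs:
        best = None
        for ch in open_chains:
            if ch.refc != run.refc or ch.qryc != run.qryc or ch.strand != run.strand:
                continue
            rgap = run.ref_start - ch.ref_end
            if rgap > gap or rgap < -k:
                continue
            if run.strand == 1:
                qgap = run.qry_start - ch.qry_end
            else:
                qgap = ch.qry_start - run.qry_end
            if qgap > gap or qgap < -k:
                continue
            if best is None or ch.matched > best.matched:
                best = ch
        if best is None:
            open_chains.append(run)
            chains.append(run)
        else:
            best.ref_end = max(best.ref_end, run.ref_end)
            best.qry_start = min(best.qry_start, run.qry_start)
            best.qry_end = max(best.qry_end, run.qry_end)
            best.matched += run.matched
        # prune chains that can no longer be extended
        open_chains = [c for c in open_chains
                       if c.refc == run.refc and run.ref_start - c.ref_end <= gap]

    segments = []
    for ch in chains:
        span = max(ch.ref_end - ch.ref_start, ch.qry_end - ch.qry_start)
        matched = min(ch.matched, span)
        ident = 100.0 * matched / span
        segments.append(SegmentMatch(
            reference[ch.refc].id, ch.ref_start, ch.ref_end,
            query[ch.qryc].id, ch.qry_start, ch.qry_end,
            "+" if ch.strand == 1 else "-", ident, matched))
    segments.sort(key=lambda s: (s.ref_id, s.ref_start, s.ref_end))
    return segments


def filter_segments(segments: Sequence[SegmentMatch],
                    params: SegmentFilterParams = SegmentFilterParams()) -> list[SegmentMatch]:
    """Apply the match-length, identity and span gates; order preserved.

    A segment survives only if its match length is at least
    ``min_match_len``, its identity at least ``min_identity``, and its span
    reaches ``min_span`` in *both* the reference and the query (the strict
    reading of the span gate: a short span in either sequence drops it).
    """
    out = []
    for s in segments:
        if s.match_len < params.min_match_len:
            continue
        if s.pct_identity < params.min_identity:
            continue
        if s.ref_span < params.min_span or s.qry_span < params.min_span:
            continue
        out.append(s)
    return out
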