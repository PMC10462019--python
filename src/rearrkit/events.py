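"""Species-unique repeat-family detection and polymorphic-insertion calling.

Cross-genome sequence comparison runs on a small seeded local-search
engine: exact 12-bp seed matches (both strands) are clustered by diagonal,
and each candidate locus is verified by edit-distance alignment (edlib), so
every reported hit carries an identity and is continuous by construction.

The novelty filter applies the gates in order: a singleton consensus is
rejected if any other genome contains a hit of at least 100 bp at <= 20%
divergence, if its own annotated copies total under 5 kb, or if their
bp-weighted mean divergence from the consensus reaches 10%.

The insertion caller excises an eligible tandem-array locus, joins its
100 bp flanks into a 200 bp probe (the intact, insertion-free site) and
requires every other genome to show exactly one continuous match of the
probe at >= 90% identity: a unique intact site everywhere else means the
insertion is private to the donor genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from . import _kmers
from .io_formats import RepeatHit, SequenceRecord
from .landscape import RepeatArray
from .synthetic import revcomp

__all__ = ["NoveltyCriteria", "NoveltyVerdict", "InsertionCall", "LocalHit",
           "Cluster", "pairwise_identity", "cluster_families", "local_hits",
           "probe_matches", "novelty_filter", "eligible_insertion_loci",
           "call_polymorphic_insertions"]


@dataclass(frozen=True)
class NoveltyCriteria:
    min_hit_len: int = 100        # cross-genome hit length gate
    max_hit_divergence: float = 20.0
    min_genomic_bp: int = 5000
    max_mean_divergence: float = 10.0
    cluster_identity: float = 80.0
    cluster_coverage: float = 80.0


@dataclass
class NoveltyVerdict:
    family: str
    novel: bool
    reason: str                   # "novel" | "homolog_found" | "low_abundance" | "old_copies"
    genomic_bp: int = 0
    mean_divergence: float | None = None
    best_hit: "LocalHit | None" = None


@dataclass(frozen=True)
class LocalHit:
    contig: str
    start: int
    end: int
    identity: float               # percent over the aligned query piece
    strand: str


@dataclass
class Cluster:
    representative: tuple[str, SequenceRecord]   # (genome, record)
    members: list[tuple[str, SequenceRecord]] = field(default_factory=list)

    @property
    def genomes(self) -> set[str]:
        return {g for g, _r in self.members}


@dataclass
class InsertionCall:
    donor: str
    contig: str
    start: int
    end: int
    family: str
    length: int
    evidence: dict[str, tuple[float, int]]   # genome -> (identity %, n matches)


# ---------------------------------------------------------------------------
# Alignment helpers

def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of the shorter sequence aligned within the longer.

    The full shorter sequence must align (free end gaps in the longer
    only); both strands are tried and the better one reported.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = min(edlib.align(short, long_, mode="HW")["editDistance"],
               edlib.align(revcomp(short), long_, mode="HW")["editDistance"])
    return 100.0 * (1.0 - best / len(short))


def _seed_index(records: Sequence[SequenceRecord], seed_len: int):
    """Sorted forward seed codes with (contig index, position) per record set."""
    codes_all, contig_all, pos_all = [], [], []
    for ci, rec in enumerate(records):
        codes, valid = _kmers.kmer_codes(_kmers.encode(rec.sequence), seed_len)
        pos = np.flatnonzero(valid)
        codes_all.append(codes[pos])
        pos_all.append(pos)
        contig_all.append(np.full(pos.size, ci, np.int32))
    codes = np.concatenate(codes_all)
    order = np.argsort(codes, kind="stable")
    return (codes[order], np.concatenate(contig_all)[order],
            np.concatenate(pos_all)[order].astype(np.int64))


def _candidate_regions(query: str, index, n_contigs: int, seed_len: int,
                       band: int = 40, max_per_contig: int = 200):
    """Diagonal-clustered candidate alignment offsets per contig.

    Returns {contig index: sorted array of candidate start offsets}, where
    an offset is the implied target position of query position 0.
    """
    codes, contigs, positions = index
    q_codes, q_valid = _kmers.kmer_codes(_kmers.encode(query), seed_len)
    q_pos = np.flatnonzero(q_valid)
    q_codes = q_codes[q_pos]
    lo = np.searchsorted(codes, q_codes, side="left")
    hi = np.searchsorted(codes, q_codes, side="right")
    diag_by_contig: dict[int, list[int]] = {}
    for qp, a, b in zip(q_pos, lo, hi):
        if b - a > 50:   # hyper-repetitive seed, skip
            continue
        for idx in range(a, b):
            diag_by_contig.setdefault(int(contigs[idx]), []).append(
                int(positions[idx]) - int(qp))
    out: dict[int, np.ndarray] = {}
    for ci, diags in diag_by_contig.items():
        diags = np.sort(np.asarray(diags, np.int64))
        # keep one representative per diagonal band
        keep = [diags[0]]
        for d in diags[1:]:
            if d - keep[-1] > band:
                keep.append(d)
        out[ci] = np.asarray(keep[:max_per_contig])
    return out


def local_hits(query: str, targets: Sequence[SequenceRecord],
               min_len: int = 100, max_divergence: float = 20.0,
               seed_len: int = 12) -> list[LocalHit]:
    """Local matches of any >= min_len piece of the query in the targets.

    The query is scanned in min_len windows (half-window step); each window
    with a seeded candidate locus is verified with edit-distance alignment,
    and windows at <= max_divergence are reported as hits.
    """
    index = _seed_index(targets, seed_len)
    hits: list[LocalHit] = []
    step = max(1, min_len // 2)
    starts = list(range(0, max(1, len(query) - min_len + 1), step))
    if starts and starts[-1] + min_len < len(query):
        starts.append(len(query) - min_len)
    for strand, q in (("+", query), ("-", revcomp(query))):
        for ws in starts:
            chunk = q[ws:ws + min_len]
            cands = _candidate_regions(chunk, index, len(targets), seed_len)
            for ci, offsets in cands.items():
                tseq = targets[ci].sequence
                for off in offsets:
                    pad = min_len // 4 + 20
                    a = max(0, int(off) - pad)
                    b = min(len(tseq), int(off) + min_len + pad)
                    if b - a < min_len // 2:
                        continue
                    res = edlib.align(chunk, tseq[a:b], mode="HW",
                                      task="locations")
                    div = 100.0 * res["editDistance"] / len(chunk)
                    if div <= max_divergence:
                        loc = res["locations"][0]
                        hits.append(LocalHit(targets[ci].id, a + loc[0],
                                             a + loc[1] + 1,
                                             100.0 - div, strand))
    return hits


def probe_matches(probe: str, targets: Sequence[SequenceRecord],
                  min_identity: float = 90.0, seed_len: int = 12,
                  ) -> list[LocalHit]:
    """Continuous full-probe matches at >= min_identity, deduped by locus.

    A match must cover the entire probe in one edit-distance alignment, so a
    site split by an intervening insertion cannot qualify.
    """
    index = _seed_index(targets, seed_len)
    max_dist = int(np.floor(len(probe) * (100.0 - min_identity) / 100.0))
    raw: list[LocalHit] = []
    for strand, q in (("+", probe), ("-", revcomp(probe))):
        cands = _candidate_regions(q, index, len(targets), seed_len)
        for ci, offsets in cands.items():
            tseq = targets[ci].sequence
            for off in offsets:
                pad = len(probe) // 4 + 30
                a = max(0, int(off) - pad)
                b = min(len(tseq), int(off) + len(probe) + pad)
                res = edlib.align(q, tseq[a:b], mode="HW", task="locations")
                if res["editDistance"] < 0 or res["editDistance"] > max_dist:
                    continue
                loc = res["locations"][0]
                ident = 100.0 * (1.0 - res["editDistance"] / len(probe))
                raw.append(LocalHit(targets[ci].id, a + loc[0], a + loc[1] + 1,
                                    ident, strand))
    # dedupe overlapping placements of the same locus
    raw.sort(key=lambda h: (h.contig, h.start))
    out: list[LocalHit] = []
    for h in raw:
        if out and h.contig == out[-1].contig and h.start < out[-1].end:
            if h.identity > out[-1].identity:
                out[-1] = h
        else:
            out.append(h)
    return out


# ---------------------------------------------------------------------------
# Family clustering and novelty

def cluster_families(libraries: Sequence[tuple[str, SequenceRecord]],
                     criteria: NoveltyCriteria = NoveltyCriteria(),
                     ) -> tuple[list[Cluster], list[tuple[str, SequenceRecord]]]:
    """Greedy incremental clustering of consensus libraries by identity.

    Sequences are visited longest-first (ties by input order); each joins
    the first cluster whose representative it matches at the identity
    threshold (both strands, full shorter sequence aligned), else founds a
    new cluster. Singletons are size-one clusters whose member comes from a
    single genome.
    """
    for _g, rec in libraries:
        if len(rec) < 50:
            raise ValueError(f"consensus {rec.id} shorter than 50 bp")
    order = sorted(range(len(libraries)),
                   key=lambda i: (-len(libraries[i][1]), i))
    clusters: list[Cluster] = []
    for i in order:
        genome, rec = libraries[i]
        for cl in clusters:
            if pairwise_identity(rec.sequence, cl.representative[1].sequence) \
                    >= criteria.cluster_identity:
                cl.members.append((genome, rec))
                break
        else:
            clusters.append(Cluster((genome, rec), [(genome, rec)]))
    singletons = [cl.members[0] for cl in clusters
                  if len(cl.members) == 1]
    return clusters, singletons


def novelty_filter(consensus: SequenceRecord,
                   other_genomes: dict[str, Sequence[SequenceRecord]],
                   own_hits: Sequence[RepeatHit],
                   criteria: NoveltyCriteria = NoveltyCriteria(),
                   ) -> NoveltyVerdict:
    """Decide whether a singleton family is genuinely unique to its genome."""
    fam_hits = [h for h in own_hits if h.family == consensus.id]
    for _name, records in other_genomes.items():
        found = local_hits(consensus.sequence, list(records),
                           min_len=criteria.min_hit_len,
                           max_divergence=criteria.max_hit_divergence)
        if found:
            best = max(found, key=lambda h: h.identity)
            return NoveltyVerdict(consensus.id, False, "homolog_found",
                                  best_hit=best)
    bp = sum(len(h) for h in fam_hits)
    if bp < criteria.min_genomic_bp:
        return NoveltyVerdict(consensus.id, False, "low_abundance", genomic_bp=bp)
    mean_div = (sum(h.pct_divergence * len(h) for h in fam_hits) / bp) if bp else 0.0
    if mean_div >= criteria.max_mean_divergence:
        return NoveltyVerdict(consensus.id, False, "old_copies",
                              genomic_bp=bp, mean_divergence=mean_div)
    return NoveltyVerdict(consensus.id, True, "novel", genomic_bp=bp,
                          mean_divergence=mean_div)


# ---------------------------------------------------------------------------
# Polymorphic insertions

def eligible_insertion_loci(arrays: Sequence[RepeatArray],
                            hits: Sequence[RepeatHit],
                            contig_lengths: dict[str, int],
                            flank: int = 1000) -> list[RepeatArray]:
    """Keep arrays with repeat-free ``flank`` bp on both sides.

    An array within ``flank`` of a contig end, or with any other annotated
    repeat overlapping either flank window, is excluded.
    """
    out = []
    for arr in arrays:
        clen = contig_lengths[arr.contig]
        if arr.start < flank or arr.end + flank > clen:
            continue
        clean = True
        for h in hits:
            if h.contig != arr.contig:
                continue
            if arr.start <= h.start and h.end <= arr.end:
                continue   # a constituent of the array itself
            if h.end > arr.start - flank and h.start < arr.end + flank:
                clean = False
                break
        if clean:
            out.append(arr)
    return out


def call_polymorphic_insertions(loci: Sequence[RepeatArray],
                                donor_name: str,
                                donor: Sequence[SequenceRecord],
                                other_genomes: dict[str, Sequence[SequenceRecord]],
                                flank: int = 100,
                                min_identity: float = 90.0,
                                ) -> list[InsertionCall]:
    """Call insertions private to the donor via the excised-site probe.

    For each eligible locus the left and right ``flank`` bp are joined into
    a continuous probe representing the intact (insertion-free) site. The
    locus is called a polymorphic insertion only when *every* other genome
    contains exactly one continuous probe match at >= min_identity; zero
    matches (site absent or interrupted, e.g. the insertion is shared) or
    multiple matches (ambiguous placement) veto the call.
    """
    donor_by_id = {rec.id: rec for rec in donor}
    calls: list[InsertionCall] = []
    for locus in loci:
        seq = donor_by_id[locus.contig].sequence
        if locus.start < flank or locus.end + flank > len(seq):
            continue
        probe = seq[locus.start - flank:locus.start] + seq[locus.end:locus.end + flank]
        evidence: dict[str, tuple[float, int]] = {}
        ok = True
        for name, records in other_genomes.items():
            matches = probe_matches(probe, list(records), min_identity)
            best = max((m.identity for m in matches), default=0.0)
            evidence[name] = (best, len(matches))
            if len(matches) != 1:
                ok = False
        if ok:
            calls.append(InsertionCall(donor_name, locus.contig, locus.start,
                                       locus.end, locus.family, locus.length,
                                       evidence))
    return calls
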