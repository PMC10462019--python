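"""Region-matched permutation test for element enrichment at breakpoints.

Breakpoint intervals that intersect an annotated repeat are first extended
to the repeat's full called extent (to a fixed point), then the focal
family's base-pair content of the extended regions is compared against the
same quantity for randomly placed, length-matched regions on the same
contigs. The one-sided p-value uses the add-one correction
p = (#{permuted >= observed} + 1) / (n + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _intervals
from .io_formats import RepeatHit

__all__ = ["EnrichmentResult", "extend_to_elements", "element_content",
           "permutation_test"]

Interval = tuple[str, int, int]


@dataclass
class EnrichmentResult:
    observed_bp: int
    n_perm: int
    n_ge: int                      # permutations reaching observed_bp
    p_value: float
    subclass_pct: dict[str, float] = field(default_factory=dict)
    family_pct: float | None = None
    permuted_bp: np.ndarray | None = None


def _hits_by_contig(hits: Sequence[RepeatHit], family: str | None = None,
                    subclass: str | None = None) -> dict[str, np.ndarray]:
    sel: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        if family is not None and h.family != family:
            continue
        if subclass is not None and h.subclass != subclass:
            continue
        sel.setdefault(h.contig, []).append((h.start, h.end))
    return {c: _intervals.merge(v) for c, v in sel.items()}


def extend_to_elements(intervals: Sequence[Interval],
                       hits: Sequence[RepeatHit]) -> list[Interval]:
    """Extend intervals to the full extent of any repeat they intersect.

    Applied transitively to a fixed point; the result is merged (disjoint)
    per contig.
    """
    merged_hits = _hits_by_contig(hits)
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, s, e in intervals:
        by_contig.setdefault(contig, []).append((s, e))
    out: list[Interval] = []
    for contig, ivs in by_contig.items():
        ext = _intervals.extend_to(np.asarray(ivs), merged_hits.get(
            contig, np.empty((0, 2), np.int64)))
        out.extend((contig, int(s), int(e)) for s, e in ext)
    return out


def element_content(intervals: Sequence[Interval], hits: Sequence[RepeatHit],
                    ) -> tuple[dict[str, float], dict[str, float]]:
    """Percent of interval bp covered per repeat subclass and per family.

    Intervals must be disjoint (e.g. the output of
    :func:`extend_to_elements`); overlapping hits within a category are
    merged first, so coverage is capped at the interval length.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    total = 0
    for contig, s, e in intervals:
        by_contig.setdefault(contig, []).append((s, e))
        total += e - s
    if total == 0:
        raise ValueError("zero total interval length")
    merged_iv = {c: _intervals.merge(v) for c, v in by_contig.items()}

    def pct_for(selector: dict[str, np.ndarray]) -> float:
        bp = sum(_intervals.intersect_length(merged_iv[c], selector[c])
                 for c in merged_iv if c in selector)
        return 100.0 * bp / total

    subclasses = sorted({h.subclass for h in hits})
    sub_pct = {sc: pct_for(_hits_by_contig(hits, subclass=sc)) for sc in subclasses}
    families = sorted({h.family for h in hits})
    fam_pct = {f: pct_for(_hits_by_contig(hits, family=f)) for f in families}
    return sub_pct, fam_pct


def permutation_test(intervals: Sequence[Interval], hits: Sequence[RepeatHit],
                     focal_family: str, contig_lengths: dict[str, int],
                     n_perm: int = 1000, seed: int | None = None,
                     ) -> EnrichmentResult:
    """Length-matched same-contig permutation test for focal-family content.

    Each permutation redraws every breakpoint interval uniformly on its own
    contig at its own length, applies the same repeat-extension step, and
    sums focal-family bp in the extended regions. Permuted regions may
    overlap each other (overlaps are merged before counting, exactly as for
    the observed regions).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    for contig, s, e in intervals:
        if e - s > contig_lengths[contig]:
            raise ValueError(f"interval longer than contig {contig}")
    rng = np.random.default_rng(seed)
    merged_hits = _hits_by_contig(hits)
    focal = _hits_by_contig(hits, family=focal_family)
    empty = np.empty((0, 2), np.int64)

    def focal_bp(regions: Sequence[Interval]) -> int:
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, s, e in regions:
            by_contig.setdefault(contig, []).append((s, e))
        bp = 0
        for contig, ivs in by_contig.items():
            ext = _intervals.extend_to(np.asarray(ivs),
                                       merged_hits.get(contig, empty))
            bp += _intervals.intersect_length(ext, focal.get(contig, empty))
        return bp

    observed = focal_bp(intervals)
    permuted = np.empty(n_perm, np.int64)
    for it in range(n_perm):
        drawn = []
        for contig, s, e in intervals:
            length = e - s
            start = int(rng.integers(0, contig_lengths[contig] - length + 1))
            drawn.append((contig, start, start + length))
        permuted[it] = focal_bp(drawn)
    n_ge = int(np.sum(permuted >= observed))
    p = (n_ge + 1) / (n_perm + 1)

    extended = extend_to_elements(intervals, hits)
    sub_pct, fam_pct = element_content(extended, hits) if hits else ({}, {})
    return EnrichmentResult(observed, n_perm, n_ge, p, sub_pct,
                            fam_pct.get(focal_family, 0.0), permuted)
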