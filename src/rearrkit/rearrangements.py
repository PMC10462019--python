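"""Inversion and translocation calling from filtered segment matches.

Segments are scanned per reference contig in reference order. A maximal run
of consecutive "-" strand segments whose query coordinates are co-linear in
reverse is one inversion; a run whose query contig differs from its
neighbours, or whose query block is displaced without a strand flip, is a
translocation. Breakpoint intervals are the gaps between the run's
outermost segments and their flanking segments — the region where the true
breakpoint must lie.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .io_formats import SegmentMatch

__all__ = ["RearrangementCall", "detect_rearrangements",
           "breakpoint_resolution", "polymorphism_matrix"]


@dataclass
class RearrangementCall:
    type: str                      # "inversion" | "translocation"
    ref_id: str
    left: tuple[int, int]          # breakpoint interval, 0-based half-open coords
    right: tuple[int, int]
    qry_id: str
    qry_span: tuple[int, int]
    n_segments: int
    nested: bool = False
    terminal: bool = False         # a breakpoint fell at a contig edge

    def __post_init__(self) -> None:
        if self.left[0] > self.left[1] or self.right[0] > self.right[1]:
            raise ValueError("breakpoint interval start must be <= end")
        if self.n_segments < 1:
            raise ValueError("a call needs at least one supporting segment")


def breakpoint_resolution(call: RearrangementCall) -> tuple[int, int]:
    """Width in bp of the left and right breakpoint intervals."""
    return (call.left[1] - call.left[0], call.right[1] - call.right[0])


def _runs(segments: list[SegmentMatch], slack: int = 100,
          max_offset: int = 5000) -> list[list[SegmentMatch]]:
    """Group consecutive segments into co-linear runs.

    A segment extends the current run only when it shares the query contig
    and strand *and* its query coordinates continue the run (query gap not
    negative beyond ``slack`` and not diverging from the reference gap by
    more than ``max_offset``); a displaced block therefore starts its own
    run even without a strand flip.
    """
    runs: list[list[SegmentMatch]] = []
    for seg in segments:
        if runs:
            prev = runs[-1][-1]
            if prev.qry_id == seg.qry_id and prev.strand == seg.strand:
                ref_gap = seg.ref_start - prev.ref_end
                if seg.strand == "+":
                    qry_gap = seg.qry_start - prev.qry_end
                else:
                    qry_gap = prev.qry_start - seg.qry_end
                if qry_gap >= -slack and abs(qry_gap - ref_gap) <= max_offset:
                    runs[-1].append(seg)
                    continue
        runs.append([seg])
    return runs


def _reverse_colinear(run: list[SegmentMatch]) -> bool:
    """Query coordinates must decrease as reference coordinates increase."""
    return all(b.qry_end <= a.qry_start + 1 for a, b in zip(run, run[1:]))


def detect_rearrangements(segments: Sequence[SegmentMatch],
                          contig_lengths: dict[str, int] | None = None,
                          nested_slack: int = 1000) -> list[RearrangementCall]:
    """Call inversions and translocations from filtered, sorted segments.

    ``contig_lengths`` (reference contigs) lets terminal breakpoints be
    clipped to the contig end; without it a terminal right breakpoint is a
    zero-width interval at the run edge. ``nested_slack`` is the query-side
    gap (bp) beyond which an inversion is flagged as sitting in a nested /
    complex context rather than a clean co-linear one.
    """
    by_contig: dict[str, list[SegmentMatch]] = {}
    for seg in segments:
        group = by_contig.setdefault(seg.ref_id, [])
        if group and seg.ref_start < group[-1].ref_start:
            raise ValueError("segments must be sorted by (ref_id, ref_start)")
        group.append(seg)

    calls: list[RearrangementCall] = []
    for ref_id, segs in by_contig.items():
        runs = _runs(segs)
        for i, run in enumerate(runs):
            prev_run = runs[i - 1] if i > 0 else None
            next_run = runs[i + 1] if i + 1 < len(runs) else None
            first, last = run[0], run[-1]

            kind = None
            nested = False
            if first.strand == "-" and _reverse_colinear(run):
                # inversion relative to neighbouring co-linear context on the
                # same query contig
                same_qry_prev = prev_run is None or prev_run[0].qry_id == first.qry_id
                same_qry_next = next_run is None or next_run[0].qry_id == first.qry_id
                if same_qry_prev and same_qry_next:
                    kind = "inversion"
                    # a clean inversion abuts its flanks with matching gaps on
                    # both sequences; a query-side gap far exceeding the
                    # reference-side gap means the run sits inside a wider
                    # rearranged (e.g. nested-inversion) context
                    qmin = min(s.qry_start for s in run)
                    qmax = max(s.qry_end for s in run)
                    if prev_run is not None:
                        rgap = first.ref_start - prev_run[-1].ref_end
                        qgap = qmin - prev_run[-1].qry_end
                        nested |= abs(qgap - rgap) > nested_slack
                    if next_run is not None:
                        rgap = next_run[0].ref_start - last.ref_end
                        qgap = next_run[0].qry_start - qmax
                        nested |= abs(qgap - rgap) > nested_slack
            if kind is None and prev_run is not None and next_run is not None:
                if (prev_run[0].qry_id == next_run[0].qry_id != first.qry_id):
                    kind = "translocation"
                elif (prev_run[0].qry_id == first.qry_id == next_run[0].qry_id
                      and first.strand == "+"
                      and prev_run[0].strand == "+" and next_run[0].strand == "+"):
                    # displaced block without strand flip
                    lo = prev_run[-1].qry_end
                    hi = next_run[0].qry_start
                    if not (lo - 1 <= first.qry_start and last.qry_end <= hi + 1):
                        kind = "translocation"
            if kind is None:
                continue

            terminal = False
            if prev_run is not None:
                # the true breakpoint lies in the gap between the flanking
                # segment and the run — or, with junction micro-homology,
                # anywhere in their overlap
                a, b = prev_run[-1].ref_end, first.ref_start
                left = (min(a, b), max(a, b))
            else:
                left = (0, first.ref_start)
                terminal = True
            if next_run is not None:
                a, b = last.ref_end, next_run[0].ref_start
                right = (min(a, b), max(a, b))
            else:
                end = last.ref_end
                if contig_lengths and ref_id in contig_lengths:
                    end = contig_lengths[ref_id]
                right = (last.ref_end, max(end, last.ref_end))
                terminal = True
            calls.append(RearrangementCall(
                kind, ref_id, left, right, first.qry_id,
                (min(s.qry_start for s in run), max(s.qry_end for s in run)),
                len(run), nested=nested, terminal=terminal))
    return calls


def _calls_match(a: RearrangementCall, b: RearrangementCall, slop: int) -> bool:
    def overlap(x, y):
        return x[0] - slop < y[1] and y[0] - slop < x[1]
    return (a.type == b.type and a.ref_id == b.ref_id
            and overlap(a.left, b.left) and overlap(a.right, b.right))


def polymorphism_matrix(calls_by_strain: dict[str, list[RearrangementCall]],
                        slop: int = 100) -> pd.DataFrame:
    """Presence/absence matrix of merged calls across strains.

    Calls from pairwise comparisons against one common reference merge when
    their breakpoint intervals reciprocally overlap (within ``slop`` bp, so
    zero-width intervals can still match). Rows are merged calls, columns
    strains; a row present everywhere is fixed, anything else polymorphic.
    """
    merged: list[tuple[RearrangementCall, set[str]]] = []
    for strain, calls in calls_by_strain.items():
        for call in calls:
            for rep, strains in merged:
                if _calls_match(rep, call, slop):
                    strains.add(strain)
                    break
            else:
                merged.append((call, {strain}))
    rows = []
    strains = list(calls_by_strain)
    for rep, present in merged:
        row = {"type": rep.type, "ref_id": rep.ref_id,
               "left_start": rep.left[0], "left_end": rep.left[1],
               "right_start": rep.right[0], "right_end": rep.right[1]}
        for s in strains:
            row[s] = s in present
        rows.append(row)
    cols = ["type", "ref_id", "left_start", "left_end",
            "right_start", "right_end"] + strains
    return pd.DataFrame(rows, columns=cols)
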