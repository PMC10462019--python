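"""Repeat-landscape, genome-proportion, window-density and tandem-array analytics.

Landscapes weight by base pairs (genomic proportion), not copy count, and
bin each hit's bp at floor(percent divergence) into 1% bins — the standard
age-structure proxy for repeat annotations. Window densities and genome
proportions merge overlapping same-subclass hits first, so every base is
counted once per subclass and the conservation identities hold
(sum of bins = subclass proportion; sum of window bp = merged subclass bp;
sum of array lengths = merged family bp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _intervals
from .io_formats import RepeatHit

__all__ = ["RepeatArray", "genome_proportions", "landscape", "window_density",
           "call_arrays", "array_summary", "abundance_decomposition"]

N_BINS = 50


@dataclass
class RepeatArray:
    """A merged tandem array of same-family hits (one locus)."""

    contig: str
    start: int
    end: int
    family: str
    n_hits: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _merged_by(hits: Sequence[RepeatHit], key) -> dict[str, dict[str, np.ndarray]]:
    """{key value: {contig: merged intervals}}."""
    buckets: dict[str, dict[str, list]] = {}
    for h in hits:
        buckets.setdefault(key(h), {}).setdefault(h.contig, []).append((h.start, h.end))
    return {kv: {c: _intervals.merge(v) for c, v in per.items()}
            for kv, per in buckets.items()}


def genome_proportions(hits: Sequence[RepeatHit], genome_size: int) -> dict[str, float]:
    """Percent of the genome covered per subclass (overlaps merged)."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    out = {}
    for subclass, per in _merged_by(hits, lambda h: h.subclass).items():
        bp = sum(_intervals.total_length(m) for m in per.values())
        out[subclass] = 100.0 * bp / genome_size
    return out


def landscape(hits: Sequence[RepeatHit], genome_size: int) -> pd.DataFrame:
    """Genomic proportion per (subclass, 1% divergence bin).

    Returns a tidy frame (subclass, bin_lo, proportion_pct) with all 50 bins
    present per subclass. Divergences outside [0, 50) are clamped into the
    edge bins with a warning.
    """
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    table: dict[tuple[str, int], float] = {}
    for h in hits:
        d = h.pct_divergence
        if d < 0 or d >= N_BINS:
            warnings.warn(f"divergence {d} outside [0, {N_BINS}) clamped")
            d = min(max(d, 0.0), N_BINS - 1e-9)
        b = int(np.floor(d))
        table[(h.subclass, b)] = table.get((h.subclass, b), 0.0) + len(h)
    subclasses = sorted({h.subclass for h in hits})
    rows = [(sc, b, 100.0 * table.get((sc, b), 0.0) / genome_size)
            for sc in subclasses for b in range(N_BINS)]
    return pd.DataFrame(rows, columns=["subclass", "bin_lo", "proportion_pct"])


def window_density(hits: Sequence[RepeatHit], contig_lengths: dict[str, int],
                   window: int = 100_000) -> pd.DataFrame:
    """Merged repeat bp per (window, subclass), tiling each contig.

    Hit bp straddling a window boundary is apportioned by overlap; the last
    short window of a contig is kept and flagged.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    merged = _merged_by(hits, lambda h: h.subclass)
    subclasses = sorted(merged)
    rows = []
    for contig, clen in contig_lengths.items():
        n_win = max(1, int(np.ceil(clen / window)))
        for w in range(n_win):
            ws, we = w * window, min((w + 1) * window, clen)
            row = {"contig": contig, "start": ws, "end": we,
                   "short": we - ws < window}
            win = np.array([[ws, we]], dtype=np.int64)
            for sc in subclasses:
                per = merged[sc].get(contig)
                row[sc] = (_intervals.intersect_length(win, per)
                           if per is not None else 0)
            rows.append(row)
    return pd.DataFrame(rows, columns=["contig", "start", "end", "short"] + subclasses)


def call_arrays(hits: Sequence[RepeatHit], merge_gap: int = 500,
                families: Sequence[str] | None = None) -> list[RepeatArray]:
    """Merge same-family hits on one contig into tandem-array loci.

    Consecutive hits join an array while the inter-hit gap is at most
    ``merge_gap``; an isolated hit is an array of one.
    """
    sel = [h for h in hits if families is None or h.family in families]
    by_key: dict[tuple[str, str], list[RepeatHit]] = {}
    for h in sel:
        by_key.setdefault((h.contig, h.family), []).append(h)
    arrays: list[RepeatArray] = []
    for (contig, family), group in sorted(by_key.items()):
        group.sort(key=lambda h: (h.start, h.end))
        cur = [group[0]]
        for h in group[1:]:
            if h.start - max(g.end for g in cur) <= merge_gap:
                cur.append(h)
            else:
                arrays.append(RepeatArray(contig, cur[0].start,
                                          max(g.end for g in cur), family, len(cur)))
                cur = [h]
        arrays.append(RepeatArray(contig, cur[0].start,
                                  max(g.end for g in cur), family, len(cur)))
    arrays.sort(key=lambda a: (a.contig, a.start))
    return arrays


def array_summary(arrays: Sequence[RepeatArray]) -> pd.DataFrame:
    """Per-family locus count, mean length and total bp."""
    rows = {}
    for a in arrays:
        r = rows.setdefault(a.family, {"family": a.family, "n_loci": 0,
                                       "total_bp": 0})
        r["n_loci"] += 1
        r["total_bp"] += a.length
    out = pd.DataFrame(list(rows.values()),
                       columns=["family", "n_loci", "total_bp"])
    out["mean_length"] = out["total_bp"] / out["n_loci"]
    return out


def abundance_decomposition(summary_a: pd.DataFrame, summary_b: pd.DataFrame,
                            family: str) -> dict:
    """Factor a family's total-bp fold change into locus-count x mean-length.

    total_b / total_a = (n_b / n_a) x (len_b / len_a); the factor with the
    larger absolute log contribution dominates. A zero-locus denominator is
    flagged instead of dividing.
    """
    ra = summary_a[summary_a.family == family]
    rb = summary_b[summary_b.family == family]
    if ra.empty or int(ra.n_loci.iloc[0]) == 0:
        return {"family": family, "flagged": True, "reason": "no loci in genome A"}
    if rb.empty:
        return {"family": family, "flagged": True, "reason": "no loci in genome B"}
    n_fc = float(rb.n_loci.iloc[0] / ra.n_loci.iloc[0])
    len_fc = float(rb.mean_length.iloc[0] / ra.mean_length.iloc[0])
    total_fc = float(rb.total_bp.iloc[0] / ra.total_bp.iloc[0])
    la, lb = abs(np.log(n_fc)) if n_fc > 0 else np.inf, abs(np.log(len_fc)) if len_fc > 0 else np.inf
    if np.isclose(la, lb):
        dominant = "balanced"
    else:
        dominant = "count-dominated" if la > lb else "length-dominated"
    return {"family": family, "flagged": False, "total_fold": total_fc,
            "count_fold": n_fc, "length_fold": len_fc, "dominant": dominant}
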