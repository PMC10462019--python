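"""Windowed nucleotide diversity (pi) and divergence (D_xy) with invariant sites.

Both statistics are ratios of summed pairwise allele differences to summed
valid pairwise comparisons over *all* sites of a window — variant and
invariant alike, with missing calls excluded pair-wise. Skipping invariant
sites (as a variants-only VCF forces) inflates the denominator-free
estimate; carrying them keeps the estimator an honest per-site average.
Windows are non-overlapping (20 kb by default); a window with no valid
comparisons is flagged rather than reported as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import AllSitesVariantTable

__all__ = ["WindowStat", "RankSumResult", "site_pair_counts",
           "site_cross_counts", "pi_windows", "dxy_windows",
           "chromosome_compare"]


@dataclass
class WindowStat:
    contig: str
    start: int
    end: int
    statistic: str                 # "pi" | "dxy"
    populations: tuple[str, ...]
    n_diffs: float
    n_comparisons: float
    value: float | None            # None when no valid comparisons (flagged)
    short: bool = False

    def __post_init__(self) -> None:
        if self.value is not None and not 0 <= self.value <= 1:
            raise ValueError("per-site statistic must lie in [0, 1]")


@dataclass
class RankSumResult:
    u_statistic: float
    p_value: float
    direction: str                 # "A > B" | "A < B" | "A == B"
    flagged: bool = False


def _max_allele(sub: np.ndarray) -> int:
    return int(sub.max()) if sub.size and sub.max() > 0 else 0


def site_pair_counts(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (differing pairs, total pairs) among the given allele columns.

    ``sub`` is (n_sites, n_alleles) with -1 missing. All pairs of distinct
    alleles count as differences (multiallelic sites are not collapsed).
    """
    nonmiss = sub >= 0
    n = nonmiss.sum(axis=1)
    pairs = n * (n - 1) // 2
    same = np.zeros(sub.shape[0], dtype=np.int64)
    for a in range(_max_allele(sub) + 1):
        c = (sub == a).sum(axis=1)
        same += c * (c - 1) // 2
    return (pairs - same).astype(np.int64), pairs.astype(np.int64)


def site_cross_counts(sub_a: np.ndarray, sub_b: np.ndarray,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (differing pairs, total pairs) across two allele-column sets."""
    na = (sub_a >= 0).sum(axis=1)
    nb = (sub_b >= 0).sum(axis=1)
    pairs = (na * nb).astype(np.int64)
    same = np.zeros(sub_a.shape[0], dtype=np.int64)
    top = max(_max_allele(sub_a), _max_allele(sub_b))
    for a in range(top + 1):
        same += (sub_a == a).sum(axis=1) * (sub_b == a).sum(axis=1)
    return pairs - same, pairs


def _aggregate(table: AllSitesVariantTable, diffs: np.ndarray,
               comps: np.ndarray, statistic: str, pops: tuple[str, ...],
               window: int, contig_length: int | None) -> list[WindowStat]:
    pos0 = table.positions - 1          # back to 0-based
    length = contig_length if contig_length is not None else int(table.positions.max())
    n_win = max(1, int(np.ceil(length / window)))
    widx = pos0 // window
    d = np.bincount(widx, weights=diffs, minlength=n_win)
    c = np.bincount(widx, weights=comps, minlength=n_win)
    out = []
    for w in range(n_win):
        ws, we = w * window, min((w + 1) * window, length)
        value = float(d[w] / c[w]) if c[w] > 0 else None
        out.append(WindowStat(table.contig, ws, we, statistic, pops,
                              float(d[w]), float(c[w]), value,
                              short=we - ws < window))
    return out


def pi_windows(table: AllSitesVariantTable, samples: Sequence[str],
               window: int = 20_000, contig_length: int | None = None,
               population: str = "pop") -> list[WindowStat]:
    """Within-population nucleotide diversity per non-overlapping window."""
    cols = table.columns_for(samples)
    if len(cols) < 2:
        raise ValueError("pi needs at least two alleles")
    diffs, comps = site_pair_counts(table.alleles[:, cols])
    return _aggregate(table, diffs, comps, "pi", (population,), window,
                      contig_length)


def dxy_windows(table: AllSitesVariantTable, samples_a: Sequence[str],
                samples_b: Sequence[str], window: int = 20_000,
                contig_length: int | None = None,
                labels: tuple[str, str] = ("A", "B")) -> list[WindowStat]:
    """Between-population divergence per window (cross-population pairs only)."""
    cols_a = table.columns_for(samples_a)
    cols_b = table.columns_for(samples_b)
    if not cols_a or not cols_b:
        raise ValueError("both populations need at least one allele")
    diffs, comps = site_cross_counts(table.alleles[:, cols_a],
                                     table.alleles[:, cols_b])
    return _aggregate(table, diffs, comps, "dxy", labels, window, contig_length)


def chromosome_compare(windows_a: Sequence[WindowStat | float],
                       windows_b: Sequence[WindowStat | float]) -> RankSumResult:
    """Mann-Whitney U on two groups of window values.

    Exact enumeration when both groups have <= 12 values, otherwise the
    normal approximation with tie correction. All-tied input is flagged
    with p = 1.
    """
    def values(ws):
        out = [w.value if isinstance(w, WindowStat) else float(w) for w in ws]
        return [v for v in out if v is not None]

    a, b = values(windows_a), values(windows_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if len(set(a) | set(b)) == 1:
        return RankSumResult(len(a) * len(b) / 2.0, 1.0, "A == B", flagged=True)
    method = "exact" if max(len(a), len(b)) <= 12 and not (set(a) & set(b)) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med = float(np.median(a) - np.median(b))
    direction = "A > B" if med > 0 else ("A < B" if med < 0 else "A == B")
    return RankSumResult(float(res.statistic), float(res.pvalue), direction)
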