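"""Discretizer comparison utilities.

Three complementary views of discretization quality:

* **Pareto front** -- sort the genomic windows by decreasing read count;
  the cumulative read count as a function of the number of windows is
  the largest amount of signal any set of k windows can capture.  A
  discretization is a single point (number of targets, reads captured)
  on this plane and can never lie above/left of the front.
* **Motif benchmark** -- precision is the fraction of called peaks that
  contain at least one occurrence of the factor's sequence motif,
  recall the fraction of genomic motif occurrences covered by a peak,
  and F1 their harmonic mean.  Overlap means at least one shared base
  pair on half-open intervals.
* **Variance explained** -- the one-way between-group over total sum of
  squares of an external response (e.g. RNA read counts) grouped by the
  discretization labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "ParetoCurve",
    "MotifBenchmark",
    "pareto_front",
    "place_discretization",
    "motif_benchmark",
    "f1_score",
    "variance_explained",
]


@dataclass
class ParetoCurve:
    """Cumulative reads captured by the k highest-count windows."""

    cumulative: np.ndarray   # cumulative[k-1] = sum of the k largest counts
    total: float

    def max_reads(self, k: int) -> float:
        """Largest read total capturable by k windows."""
        if k <= 0:
            return 0.0
        return float(self.cumulative[min(k, self.cumulative.size) - 1])

    def dominates(self, n_targets: int, reads_captured: float, atol=1e-9) -> bool:
        return reads_captured <= self.max_reads(n_targets) + atol


def pareto_front(counts) -> ParetoCurve:
    """Pareto front of a pooled per-window count column."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    cum = np.cumsum(np.sort(c)[::-1])
    return ParetoCurve(cumulative=cum, total=float(c.sum()))


def place_discretization(counts, calls):
    """Coordinates of a discretization on the Pareto plane.

    ``calls`` is a boolean mask or an index array of target windows.
    Returns ``(n_targets, reads_captured, on_front)``.
    """
    c = np.asarray(counts, dtype=float)
    calls = np.asarray(calls)
    idx = np.flatnonzero(calls) if calls.dtype == bool else calls
    k = int(idx.size)
    captured = float(c[idx].sum())
    front = pareto_front(c)
    on_front = abs(captured - front.max_reads(k)) <= 1e-9
    return k, captured, on_front


@dataclass
class MotifBenchmark:
    """Peak-vs-motif overlap counts and the derived metrics."""

    total_peaks: int
    peaks_with_motif: int
    motifs_total: int
    motifs_covered: int
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self):
        self.precision = (
            self.peaks_with_motif / self.total_peaks
            if self.total_peaks > 0
            else math.nan
        )
        self.recall = (
            self.motifs_covered / self.motifs_total if self.motifs_total > 0 else 0.0
        )
        self.f1 = (
            f1_score(self.precision, self.recall)
            if self.total_peaks > 0
            else 0.0
        )

    @classmethod
    def from_counts(cls, total_peaks, peaks_with_motif, motifs_total, motifs_covered):
        return cls(total_peaks, peaks_with_motif, motifs_total, motifs_covered)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall <= 0 or not math.isfinite(precision + recall):
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _build_trees(intervals) -> dict:
    trees: dict = {}
    for chrom, start, end in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    return trees


def motif_benchmark(peaks: Sequence, motifs: Sequence, resize_to: int = None) -> MotifBenchmark:
    """Precision/recall/F1 of peak calls against motif occurrences.

    ``peaks`` and ``motifs`` are iterables of ``(chrom, start, end)``
    half-open intervals; an overlap is at least one shared base pair.
    ``resize_to`` optionally re-centers every peak to a fixed width
    before the comparison.
    """
    peaks = [(c, int(s), int(e)) for c, s, e in peaks]
    motifs = [(c, int(s), int(e)) for c, s, e in motifs]
    if resize_to is not None:
        half = resize_to // 2
        peaks = [
            (c, max(0, (s + e) // 2 - half), (s + e) // 2 - half + resize_to)
            for c, s, e in peaks
        ]
    motif_trees = _build_trees(motifs)
    peak_trees = _build_trees(peaks)
    peaks_with_motif = sum(
        1
        for c, s, e in peaks
        if c in motif_trees and motif_trees[c].overlap(s, e)
    )
    motifs_covered = sum(
        1
        for c, s, e in motifs
        if c in peak_trees and peak_trees[c].overlap(s, e)
    )
    return MotifBenchmark(
        total_peaks=len(peaks),
        peaks_with_motif=peaks_with_motif,
        motifs_total=len(motifs),
        motifs_covered=motifs_covered,
    )


def variance_explained(response, groups) -> float:
    """Between-group over total sum of squares of ``response``.

    Returns 0 when the response has no variance; always lies in [0, 1]
    and is invariant to affine transformations of the response.
    """
    x = np.asarray(response, dtype=float)
    g = np.asarray(groups)
    if x.shape != g.shape:
        raise ValueError("response and groups must align")
    if x.size == 0:
        raise ValueError("need at least one observation")
    grand = x.mean()
    total = ((x - grand) ** 2).sum()
    if total <= 0:
        return 0.0
    between = 0.0
    for label in np.unique(g):
        sel = g == label
        between += sel.sum() * (x[sel].mean() - grand) ** 2
    return float(min(between / total, 1.0))
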