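"""Genomic interval primitives.

All intervals are 0-based, half-open (BED convention).  :class:`IntervalSet`
is a light container over :class:`Interval` with cached per-chromosome numpy
views for fast overlap queries; it is deliberately simpler than a full
interval tree — the query patterns in this package are all "sorted merged set
vs. batch of query intervals", which searchsorted handles in O(log n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class Interval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.start < 0:
            raise ValueError(f"negative interval start: {self.start}")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_sorted(starts: np.ndarray, ends: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/adjacent intervals given start-sorted arrays."""
    if len(starts) == 0:
        return starts, ends
    out_s: List[int] = [int(starts[0])]
    out_e: List[int] = [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            if e > out_e[-1]:
                out_e[-1] = int(e)
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


class IntervalSet:
    """An ordered collection of intervals with fast overlap queries."""

    def __init__(self, intervals: Iterable[Interval] = (), label: str = ""):
        self.label = label
        self.intervals: List[Interval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._by_chrom: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None
        self._merged: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> Interval:
        return self.intervals[i]

    def __repr__(self) -> str:
        return f"IntervalSet(label={self.label!r}, n={len(self)})"

    @property
    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome ``(starts, ends)`` arrays, sorted by start."""
        if self._by_chrom is None:
            out: Dict[str, Tuple[List[int], List[int]]] = {}
            for iv in self.intervals:
                out.setdefault(iv.chrom, ([], []))
                out[iv.chrom][0].append(iv.start)
                out[iv.chrom][1].append(iv.end)
            self._by_chrom = {
                c: (
                    np.asarray(s, dtype=np.int64),
                    np.asarray(e, dtype=np.int64),
                )
                for c, (s, e) in out.items()
            }
        return self._by_chrom

    def merged_by_chrom(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome merged, disjoint ``(starts, ends)`` arrays."""
        if self._merged is None:
            self._merged = {
                c: merge_sorted(s, e) for c, (s, e) in self.by_chrom().items()
            }
        return self._merged

    def overlaps_any(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Boolean mask: does each query ``[start, end)`` hit this set?"""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        merged = self.merged_by_chrom().get(chrom)
        if merged is None or len(merged[0]) == 0:
            return np.zeros(starts.shape, dtype=bool)
        ms, me = merged
        # merged intervals are disjoint & sorted, so both ms and me ascend:
        # a query overlaps iff some merged start < query end with merged end
        # > query start, and only the last such candidate needs checking.
        idx = np.searchsorted(ms, ends, side="left")
        hit = idx > 0
        hit[hit] = me[idx[hit] - 1] > starts[hit]
        return hit

    def count_overlapping(self, other: "IntervalSet") -> int:
        """Number of intervals of *self* that overlap ≥1 interval of *other*."""
        total = 0
        for chrom, (s, e) in self.by_chrom().items():
            total += int(other.overlaps_any(chrom, s, e).sum())
        return total

    def nearest_distance(self, chrom: str, points: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest interval (0 if inside).

        Returns +inf where the set has no interval on ``chrom``.
        """
        points = np.asarray(points, dtype=np.int64)
        merged = self.merged_by_chrom().get(chrom)
        if merged is None or len(merged[0]) == 0:
            return np.full(points.shape, np.inf)
        ms, me = merged
        idx = np.searchsorted(ms, points, side="right")
        dist = np.full(points.shape, np.inf)
        has_left = idx > 0
        left_gap = np.where(
            has_left, points - me[np.minimum(idx - 1, len(me) - 1)] + 1, np.inf
        )
        # inside the interval to the left -> distance 0
        inside = has_left & (left_gap <= 0)
        has_right = idx < len(ms)
        right_gap = np.where(has_right, ms[np.minimum(idx, len(ms) - 1)] - points, np.inf)
        dist = np.minimum(np.maximum(left_gap, 0), np.maximum(right_gap, 0))
        dist[inside] = 0
        return dist.astype(float)


def total_span(intervals: IntervalSet) -> int:
    """Total merged bp covered by the set."""
    return sum(
        int((e - s).sum()) for s, e in intervals.merged_by_chrom().values()
    )
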