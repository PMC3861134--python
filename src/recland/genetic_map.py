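"""Genetic-map handling: hotspot calling, concentration summaries, overlap tests.

A :class:`GeneticMap` is a piecewise-constant recombination-rate track: the
rate recorded at a boundary applies from that boundary up to (not including)
the next one.  Map boundary positions are 1-based (as in rate-track TSVs);
all interval outputs (hotspots, peak sets) are 0-based half-open, and the
conversion happens in exactly one place (:func:`_to_bed_coord`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from recland.errors import EmptyInputError, ParameterError
from recland.intervals import IntervalSet

STRENGTH_CLASSES = ("weak", "intermediate", "strong")


def _to_bed_coord(pos_1based: int) -> int:
    return pos_1based - 1


@dataclass
class GeneticMap:
    """Piecewise-constant recombination-rate track for one chromosome.

    Parameters
    ----------
    chrom
        Chromosome identifier.
    boundaries
        Strictly increasing 1-based positions, length ``n``.
    rates
        Rate (cM/Mb) on each of the ``n - 1`` inter-boundary intervals.
    """

    chrom: str
    boundaries: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.boundaries.ndim != 1 or len(self.boundaries) < 2:
            raise EmptyInputError(
                f"{self.chrom}: a map needs at least two boundary positions"
            )
        if len(self.rates) != len(self.boundaries) - 1:
            raise ValueError(
                f"{self.chrom}: expected {len(self.boundaries) - 1} rates, "
                f"got {len(self.rates)}"
            )
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError(f"{self.chrom}: boundaries must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError(f"{self.chrom}: negative recombination rate")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError(f"{self.chrom}: non-finite recombination rate")

    @property
    def n_intervals(self) -> int:
        return len(self.rates)

    @property
    def spans(self) -> np.ndarray:
        """Interval widths in bp."""
        return np.diff(self.boundaries)

    @property
    def start(self) -> int:
        return int(self.boundaries[0])

    @property
    def end(self) -> int:
        return int(self.boundaries[-1])

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def total_cm(self) -> float:
        """Genetic map length in cM (sum of rate × span)."""
        return float(np.sum(self.rates * self.spans) / 1e6)

    def _cum_cm(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.rates * self.spans) / 1e6])

    def cumulative_cm(self, positions: np.ndarray) -> np.ndarray:
        """Cumulative map length (cM) from the map start to each position."""
        positions = np.clip(np.asarray(positions, dtype=float), self.start, self.end)
        return np.interp(positions, self.boundaries.astype(float), self._cum_cm())

    def mean_rate(self, start, end) -> np.ndarray:
        """bp-weighted mean rate (cM/Mb) over 1-based ``[start, end)``.

        Vectorized over paired start/end arrays.  Regions outside the map
        extent contribute rate 0 via clipping of the cumulative function.
        """
        start = np.asarray(start, dtype=float)
        end = np.asarray(end, dtype=float)
        if np.any(end <= start):
            raise ValueError("mean_rate requires end > start")
        d_cm = self.cumulative_cm(end) - self.cumulative_cm(start)
        return d_cm / ((end - start) / 1e6)

    def rate_at(self, positions) -> np.ndarray:
        """Rate at each 1-based position (0 outside the map extent)."""
        positions = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(self.boundaries, positions, side="right") - 1
        out = np.zeros(positions.shape, dtype=float)
        ok = (idx >= 0) & (idx < self.n_intervals)
        out[ok] = self.rates[idx[ok]]
        return out

    def weighted_median_rate(self, start: Optional[int] = None,
                             end: Optional[int] = None) -> float:
        """bp-weighted median rate over 1-based ``[start, end)``."""
        s = self.start if start is None else max(int(start), self.start)
        e = self.end if end is None else min(int(end), self.end)
        if e <= s:
            return float("nan")
        i0 = int(np.searchsorted(self.boundaries, s, side="right") - 1)
        i1 = int(np.searchsorted(self.boundaries, e, side="left"))
        vals = self.rates[i0:i1]
        cuts = np.clip(self.boundaries[i0 : i1 + 1], s, e)
        weights = np.diff(cuts)
        keep = weights > 0
        return _weighted_median(vals[keep], weights[keep])


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    if len(values) == 0 or weights.sum() == 0:
        return float("nan")
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cw = np.cumsum(w)
    cutoff = 0.5 * cw[-1]
    return float(v[np.searchsorted(cw, cutoff, side="left")])


@dataclass
class Hotspot:
    """A called recombination hotspot (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    peak_rate: float
    background_rate: float
    strength_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("hotspot end must exceed start")
        if self.background_rate < 0:
            raise ValueError("negative background rate")
        if self.peak_rate < self.background_rate:
            raise ValueError("peak rate below background rate")
        if self.strength_class is not None and self.strength_class not in STRENGTH_CLASSES:
            raise ValueError(f"unknown strength class {self.strength_class!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def hotspots_to_intervals(hotspots: Sequence[Hotspot], label: str = "hotspots") -> IntervalSet:
    from recland.intervals import Interval

    return IntervalSet(
        (Interval(h.chrom, h.start, h.end, name=h.strength_class) for h in hotspots),
        label=label,
    )


@dataclass(frozen=True)
class HotspotCallerParams:
    """Tunables for :func:`call_hotspots`.

    ``flank`` must exceed ``max_width`` so the background window cannot be
    dominated by the candidate peak itself.
    """

    fold: float = 5.0
    flank: int = 100_000
    min_width: int = 1_000
    max_width: int = 20_000
    merge_gap: int = 500

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ParameterError("fold threshold must exceed 1")
        if self.flank <= self.max_width:
            raise ParameterError(
                "flank length must exceed max hotspot width "
                "(background would be contaminated by the candidate)"
            )
        if not (0 < self.min_width <= self.max_width):
            raise ParameterError("need 0 < min_width <= max_width")
        if self.merge_gap < 0:
            raise ParameterError("merge_gap must be non-negative")


def _local_background(gmap: GeneticMap, left_end: int, right_start: int,
                      flank: int) -> float:
    """Weighted median rate over ``flank`` bp on each side of an excluded core."""
    vals: List[np.ndarray] = []
    wts: List[np.ndarray] = []
    for s, e in ((left_end - flank, left_end), (right_start, right_start + flank)):
        s = max(s, gmap.start)
        e = min(e, gmap.end)
        if e <= s:
            continue
        i0 = int(np.searchsorted(gmap.boundaries, s, side="right") - 1)
        i1 = int(np.searchsorted(gmap.boundaries, e, side="left"))
        cuts = np.clip(gmap.boundaries[i0 : i1 + 1], s, e)
        w = np.diff(cuts)
        keep = w > 0
        vals.append(gmap.rates[i0:i1][keep])
        wts.append(w[keep])
    if not vals:
        return float("nan")
    return _weighted_median(np.concatenate(vals), np.concatenate(wts))


def call_hotspots(
    gmap: GeneticMap, params: HotspotCallerParams = HotspotCallerParams()
) -> List[Hotspot]:
    """Call hotspot-like peaks in a rate track.

    A map interval is *elevated* when its rate is at least ``fold`` times the
    bp-weighted median rate over the flanking windows (candidate excluded).
    Elevated intervals separated by at most ``merge_gap`` bp are merged, the
    background is then re-estimated around each merged candidate, and
    candidates are kept when they satisfy the width limits and
    ``peak_rate >= fold * background_rate``.

    Returns hotspots in 0-based half-open coordinates, pairwise disjoint.
    """
    n = gmap.n_intervals
    if n == 0:
        raise EmptyInputError("empty genetic map")
    b = gmap.boundaries
    elevated = np.zeros(n, dtype=bool)
    for i in range(n):
        if gmap.rates[i] <= 0:
            continue
        bg = _local_background(gmap, int(b[i]), int(b[i + 1]), params.flank)
        if np.isnan(bg):
            continue
        threshold = params.fold * bg
        if gmap.rates[i] >= threshold and gmap.rates[i] > 0 and threshold > 0:
            elevated[i] = True
        elif bg == 0 and gmap.rates[i] > 0:
            # infinite fold over a silent background
            elevated[i] = True

    # group elevated intervals into runs, merging across small gaps
    runs: List[Tuple[int, int]] = []  # (first interval idx, last interval idx)
    idxs = np.flatnonzero(elevated)
    for i in idxs:
        if runs and int(b[i]) - int(b[runs[-1][1] + 1]) <= params.merge_gap:
            runs[-1] = (runs[-1][0], int(i))
        else:
            runs.append((int(i), int(i)))

    hotspots: List[Hotspot] = []
    for i0, i1 in runs:
        cs, ce = int(b[i0]), int(b[i1 + 1])
        width = ce - cs
        if width < params.min_width or width > params.max_width:
            continue
        bg = _local_background(gmap, cs, ce, params.flank)
        if np.isnan(bg):
            continue
        peak = float(gmap.rates[i0 : i1 + 1].max())
        if bg > 0 and peak < params.fold * bg:
            continue
        hotspots.append(
            Hotspot(
                chrom=gmap.chrom,
                start=_to_bed_coord(cs),
                end=_to_bed_coord(ce),
                peak_rate=peak,
                background_rate=float(bg),
            )
        )
    return hotspots


def classify_strength(
    hotspots: Sequence[Hotspot],
    cutpoints: Optional[Tuple[float, float]] = None,
) -> List[Hotspot]:
    """Partition hotspots into weak/intermediate/strong by peak rate.

    Default cutpoints are the empirical tertiles of the peak rates.  Peaks
    at or below the lower cutpoint are *weak*, at or below the upper one
    *intermediate*, above it *strong*; ties therefore fall in the lower
    class (so a degenerate all-equal input is all-weak).
    """
    if not hotspots:
        return []
    peaks = np.array([h.peak_rate for h in hotspots])
    if cutpoints is None:
        c1, c2 = np.quantile(peaks, [1 / 3, 2 / 3])
    else:
        c1, c2 = cutpoints
        if c2 < c1:
            raise ParameterError("strength cutpoints must be ascending")
    out = []
    for h in hotspots:
        if h.peak_rate <= c1:
            cls = "weak"
        elif h.peak_rate <= c2:
            cls = "intermediate"
        else:
            cls = "strong"
        out.append(replace(h, strength_class=cls))
    return out


def lorenz_curve(
    gmaps: "GeneticMap | Iterable[GeneticMap]",
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Concentration of recombination: cumulative map fraction vs sequence fraction.

    Intervals are sorted by rate descending, so the curve runs from (0, 0)
    to (1, 1) and lies on or above the diagonal.  Returns
    ``(genome_fraction, map_fraction, gini)`` where the Gini coefficient is
    twice the area between the curve and the diagonal.
    """
    if isinstance(gmaps, GeneticMap):
        gmaps = [gmaps]
    rates = np.concatenate([m.rates for m in gmaps])
    spans = np.concatenate([m.spans for m in gmaps]).astype(float)
    total_cm = float(np.sum(rates * spans))
    total_bp = float(spans.sum())
    if total_cm <= 0:
        raise EmptyInputError("zero-length genetic map: Lorenz curve undefined")
    order = np.argsort(-rates, kind="stable")
    x = np.concatenate([[0.0], np.cumsum(spans[order]) / total_bp])
    y = np.concatenate([[0.0], np.cumsum(rates[order] * spans[order]) / total_cm])
    area = float(np.trapezoid(y, x))
    gini = 2.0 * (area - 0.5)
    return x, y, float(np.clip(gini, 0.0, 1.0))


def overlap_randomization_test(
    set_a: IntervalSet,
    set_b: IntervalSet,
    chrom_lengths: Dict[str, int],
    n_rand: int = 10_000,
    seed: Optional[int] = None,
) -> Tuple[int, float]:
    """Randomization test for overlap between two interval sets.

    The observed statistic is the number of ``set_a`` intervals overlapping
    at least one ``set_b`` interval.  Each randomization repositions every
    ``set_a`` interval uniformly within its own chromosome, preserving
    widths and per-chromosome counts.  The empirical p-value is
    ``(1 + #{randomized >= observed}) / (n_rand + 1)``.
    """
    if n_rand < 1:
        raise ParameterError("n_rand must be >= 1")
    rng = np.random.default_rng(seed)
    observed = set_a.count_overlapping(set_b)
    if len(set_a) == 0:
        return 0, 1.0

    per_chrom = []
    for chrom, (s, e) in set_a.by_chrom().items():
        if chrom not in chrom_lengths:
            raise ParameterError(f"no length given for chromosome {chrom}")
        length = int(chrom_lengths[chrom])
        widths = e - s
        if np.any(widths > length):
            raise ParameterError(
                f"interval wider than chromosome {chrom} ({length} bp)"
            )
        per_chrom.append((chrom, widths, length))

    n_ge = 0
    for _ in range(n_rand):
        count = 0
        for chrom, widths, length in per_chrom:
            starts = rng.integers(0, length - widths + 1)
            count += int(set_b.overlaps_any(chrom, starts, starts + widths).sum())
        if count >= observed:
            n_ge += 1
    p = (1 + n_ge) / (n_rand + 1)
    return observed, p


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class PeakComparison:
    n_p: int
    n_q: int
    shared_pairs: int
    unique_p: int
    unique_q: int
    pct_unique_p: int
    pct_unique_q: int


def compare_peak_sets(set_p: IntervalSet, set_q: IntervalSet) -> PeakComparison:
    """Compare two peak sets by ≥1 bp overlap.

    ``shared_pairs`` counts overlapping (p, q) pairs, which is symmetric in
    the two arguments; the unique counts/percentages are per side, with
    percentages relative to each set's own size, rounded half away from zero.
    """
    shared_pairs = 0
    for chrom, (ps, pe) in set_p.by_chrom().items():
        q = set_q.by_chrom().get(chrom)
        if q is None:
            continue
        qs, qe = q
        qe_sorted = np.sort(qe)
        # number of q with start < p.end minus number of q with end <= p.start
        shared_pairs += int(
            (
                np.searchsorted(qs, pe, side="left")
                - np.searchsorted(qe_sorted, ps, side="right")
            ).sum()
        )
    unique_p = len(set_p) - set_p.count_overlapping(set_q)
    unique_q = len(set_q) - set_q.count_overlapping(set_p)
    pct_p = _round_half_away(100.0 * unique_p / len(set_p)) if len(set_p) else 0
    pct_q = _round_half_away(100.0 * unique_q / len(set_q)) if len(set_q) else 0
    return PeakComparison(
        n_p=len(set_p),
        n_q=len(set_q),
        shared_pairs=shared_pairs,
        unique_p=unique_p,
        unique_q=unique_q,
        pct_unique_p=pct_p,
        pct_unique_q=pct_q,
    )


def confirm_hotspots(
    ours: Sequence[Hotspot], theirs: IntervalSet
) -> Tuple[int, float, int]:
    """How many foreign hotspots overlap at least one of our called hotspots.

    Returns ``(n_confirmed, fraction, percent)`` with the percent rounded to
    the nearest integer (half away from zero).
    """
    if len(theirs) == 0:
        raise EmptyInputError("empty foreign hotspot set")
    ours_set = hotspots_to_intervals(ours)
    n_confirmed = theirs.count_overlapping(ours_set)
    fraction = n_confirmed / len(theirs)
    return n_confirmed, fraction, _round_half_away(100.0 * fraction)
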