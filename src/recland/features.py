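"""Feature-centered rate profiles, distance partitions, and composition models.

Anchors are :class:`~recland.intervals.IntervalSet` entries; the anchor
point is the interval midpoint (a 1 bp interval is a point anchor, e.g. a
TSS).  Map coordinates are 1-based internally; interval inputs are 0-based
half-open, converted here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from recland.errors import EmptyInputError, ParameterError
from recland.genetic_map import GeneticMap, Hotspot
from recland.intervals import Interval, IntervalSet
from recland.seqstats import SequenceStats

MapsLike = Union[GeneticMap, Mapping[str, GeneticMap]]


def _as_map_dict(gmaps: MapsLike) -> Mapping[str, GeneticMap]:
    if isinstance(gmaps, GeneticMap):
        return {gmaps.chrom: gmaps}
    return gmaps


@dataclass
class RateProfile:
    """Mean recombination rate by signed distance from an anchor point."""

    label: str
    bin_edges: np.ndarray   # signed bp offsets, length n_bins + 1
    mean_rate: np.ndarray   # cM/Mb per bin (NaN where no anchors contribute)
    n_anchors: np.ndarray   # contributing anchors per bin

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "mean_rate": self.mean_rate,
                "n_anchors": self.n_anchors,
            }
        )


def profile_around(
    gmaps: MapsLike,
    anchors: IntervalSet,
    half_span: int = 25_000,
    bin_width: int = 1_000,
    orient_by_strand: bool = False,
    label: str = "",
) -> RateProfile:
    """Average the rate track in distance bins around anchor midpoints.

    For each anchor, every bin ``[d0, d1)`` is evaluated as the bp-weighted
    mean rate over ``[midpoint + d0, midpoint + d1)``; bins are then
    averaged across anchors.  With ``orient_by_strand`` the distance axis
    of minus-strand anchors is flipped so negative distances are upstream.
    Anchors whose window leaves the map extent are skipped with a warning.
    """
    maps = _as_map_dict(gmaps)
    edges = np.arange(-half_span, half_span + bin_width, bin_width, dtype=np.int64)
    n_bins = len(edges) - 1
    total = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=np.int64)
    n_skipped = 0
    for iv in anchors:
        gmap = maps.get(iv.chrom)
        if gmap is None:
            n_skipped += 1
            continue
        mid = iv.midpoint + 1  # 1-based map coordinate
        lo, hi = mid + edges[0], mid + edges[-1]
        if lo < gmap.start or hi > gmap.end:
            n_skipped += 1
            continue
        rates = gmap.mean_rate(mid + edges[:-1], mid + edges[1:])
        if orient_by_strand and iv.strand == "-":
            rates = rates[::-1]
        total += rates
        count += 1
    if n_skipped:
        warnings.warn(f"{n_skipped} anchors outside map extent skipped")
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return RateProfile(
        label=label or anchors.label, bin_edges=edges, mean_rate=mean, n_anchors=count
    )


def partition_by_distance(
    anchors: IntervalSet,
    references: IntervalSet,
    edges: Sequence[int],
) -> Tuple[np.ndarray, List[IntervalSet]]:
    """Group anchors by distance to the nearest reference interval.

    Group 0 holds anchors overlapping a reference; group ``i`` (1-based over
    ``edges``) holds distances in ``(edges[i-1], edges[i]]`` with an implicit
    lower edge of 0; the final group holds anchors with no reference within
    ``edges[-1]`` (including chromosomes without references).  Returns the
    per-anchor labels and the groups as interval sets (a partition).
    """
    edges = np.asarray(sorted(edges), dtype=float)
    if len(edges) == 0 or edges[0] <= 0:
        raise ParameterError("edges must be positive ascending cutoffs")
    labels = np.zeros(len(anchors), dtype=np.int64)
    points = np.array([iv.midpoint for iv in anchors], dtype=np.int64)
    chroms = np.array([iv.chrom for iv in anchors])
    for chrom in np.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        dist = references.nearest_distance(chrom, points[sel])
        lab = np.where(dist == 0, 0, 1 + np.searchsorted(edges, dist, side="left"))
        lab[np.isinf(dist)] = len(edges) + 1
        labels[sel] = lab
    groups = [
        IntervalSet(
            (anchors[i] for i in np.flatnonzero(labels == g)),
            label=f"{anchors.label}:group{g}",
        )
        for g in range(len(edges) + 2)
    ]
    return labels, groups


@dataclass(frozen=True)
class TssDistanceSummary:
    frac_overlap: float
    median_distance: float
    frac_beyond: float
    threshold: int


def hotspot_tss_distances(
    hotspots: Sequence[Hotspot],
    tss: IntervalSet,
    threshold: int = 100_000,
) -> TssDistanceSummary:
    """Distance from each hotspot to the nearest TSS point.

    Distance is 0 when a TSS lies within the hotspot, otherwise the gap to
    the nearest TSS.  Summarized as the fraction at 0, the median distance,
    and the fraction beyond ``threshold``.
    """
    if len(tss) == 0:
        raise EmptyInputError("empty TSS set")
    if not hotspots:
        raise EmptyInputError("no hotspots")
    tss_by_chrom: Dict[str, np.ndarray] = {
        c: np.sort(np.array([iv.midpoint for iv in tss if iv.chrom == c]))
        for c in {iv.chrom for iv in tss}
    }
    dists = []
    for h in hotspots:
        pts = tss_by_chrom.get(h.chrom)
        if pts is None:
            dists.append(np.inf)
            continue
        j = np.searchsorted(pts, h.start)
        best = np.inf
        for cand in (j - 1, j, j + 1):
            if 0 <= cand < len(pts):
                p = int(pts[cand])
                if h.start <= p < h.end:
                    best = 0.0
                    break
                gap = h.start - p if p < h.start else p - (h.end - 1)
                best = min(best, float(gap))
        dists.append(best)
    d = np.asarray(dists, dtype=float)
    return TssDistanceSummary(
        frac_overlap=float((d == 0).mean()),
        median_distance=float(np.median(d)),
        frac_beyond=float((d > threshold).mean()),
        threshold=threshold,
    )


@dataclass
class WindowTable:
    """Non-overlapping windows with rate and composition covariates."""

    window_size: int
    table: pd.DataFrame  # columns: chrom, start, end, rate, gc, cpg [, gene_density]


def build_window_table(
    gmaps: MapsLike,
    genome: Mapping[str, str],
    window_size: int,
    genes: Optional[IntervalSet] = None,
) -> WindowTable:
    """Tile chromosomes into windows of ``window_size`` (trailing remainder
    dropped) and annotate mean rate, GC, CpG, and optionally gene density
    (fraction of window bp covered by genes)."""
    maps = _as_map_dict(gmaps)
    rows = []
    for chrom, gmap in maps.items():
        seq = genome.get(chrom)
        if seq is None:
            continue
        st = SequenceStats(seq)
        n_windows = st.length // window_size
        if n_windows == 0:
            continue
        starts = np.arange(n_windows, dtype=np.int64) * window_size
        ends = starts + window_size
        rate = gmap.mean_rate(starts + 1, ends + 1)
        gc = st.window_gc(starts, ends)
        cpg = st.window_cpg(starts, ends)
        frame = pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends,
             "rate": rate, "gc": gc, "cpg": cpg}
        )
        if genes is not None:
            merged = genes.merged_by_chrom().get(chrom)
            cover = np.zeros(st.length + 1, dtype=np.int64)
            if merged is not None:
                gs, ge = merged
                np.add.at(cover, np.clip(gs, 0, st.length), 1)
                np.add.at(cover, np.clip(ge, 0, st.length), -1)
            cum = np.concatenate([[0], np.cumsum(np.cumsum(cover)[:-1])])
            frame["gene_density"] = (cum[ends] - cum[starts]) / window_size
        rows.append(frame)
    if not rows:
        raise EmptyInputError("no windows (window size exceeds chromosomes?)")
    return WindowTable(window_size=window_size, table=pd.concat(rows, ignore_index=True))


def windowed_correlation(
    gmaps: MapsLike,
    genome: Mapping[str, str],
    window_sizes: Sequence[int],
) -> Dict[int, Tuple[WindowTable, float, float]]:
    """Per-scale Pearson r of rate vs GC and rate vs CpG.

    Returns ``{window_size: (table, r_gc, r_cpg)}``; a correlation is NaN
    (flagged with a warning) when either column has zero variance.
    """
    out = {}
    for size in window_sizes:
        wt = build_window_table(gmaps, genome, size)
        t = wt.table.dropna(subset=["rate", "gc", "cpg"])
        if len(t) < 3:
            raise ParameterError(f"need >=3 windows at scale {size}")
        r_gc = _pearson_or_nan(t["rate"], t["gc"])
        r_cpg = _pearson_or_nan(t["rate"], t["cpg"])
        out[size] = (wt, r_gc, r_cpg)
    return out


def _pearson_or_nan(x: pd.Series, y: pd.Series) -> float:
    if np.std(x.to_numpy()) == 0 or np.std(y.to_numpy()) == 0:
        warnings.warn("zero-variance column: correlation undefined")
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class RegressionResult:
    coef: Dict[str, float]       # standardized OLS coefficients
    ci_low: Dict[str, float]     # 95% CI bounds
    ci_high: Dict[str, float]
    signs: Dict[str, int]
    r_squared: float


def composition_regression(
    window_table: Union[WindowTable, pd.DataFrame],
    predictors: Sequence[str] = ("gc", "cpg"),
) -> RegressionResult:
    """OLS of rate on standardized composition predictors.

    Raises on near-collinear predictors (|pairwise r| > 0.999).  CIs are
    t-based 95% intervals.
    """
    t = window_table.table if isinstance(window_table, WindowTable) else window_table
    t = t.dropna(subset=["rate", *predictors])
    n = len(t)
    if n < len(predictors) + 2:
        raise ParameterError("too few windows for regression")
    X = np.column_stack(
        [(t[p] - t[p].mean()) / t[p].std(ddof=0) for p in predictors]
    )
    for i in range(len(predictors)):
        for j in range(i + 1, len(predictors)):
            r = np.corrcoef(X[:, i], X[:, j])[0, 1]
            if abs(r) > 0.999:
                raise ParameterError(
                    f"collinear predictors {predictors[i]}/{predictors[j]} (r={r:.4f})"
                )
    y = t["rate"].to_numpy(dtype=float)
    design = np.column_stack([np.ones(n), X])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    dof = n - design.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    tcrit = sps.t.ppf(0.975, dof)
    coef, lo, hi, signs = {}, {}, {}, {}
    for i, p in enumerate(predictors, start=1):
        coef[p] = float(beta[i])
        lo[p] = float(beta[i] - tcrit * se[i])
        hi[p] = float(beta[i] + tcrit * se[i])
        signs[p] = int(np.sign(beta[i]))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    return RegressionResult(coef=coef, ci_low=lo, ci_high=hi, signs=signs, r_squared=r2)


def flanking_composition_compare(
    set_a: IntervalSet,
    set_b: IntervalSet,
    genome: Mapping[str, str],
    flank: int = 50_000,
    measure: str = "cpg",
) -> Tuple[float, float, float]:
    """Compare flanking composition of two interval sets.

    Per interval, the ``measure`` ("cpg" or "gc") is computed over the
    ``flank`` bp on each side (truncated at chromosome ends with a warning);
    groups are compared with a two-sided Mann-Whitney U test.  Returns
    ``(mean_a, mean_b, p)``.
    """
    stats_cache: Dict[str, SequenceStats] = {}

    def flank_values(ivset: IntervalSet) -> np.ndarray:
        vals = []
        truncated = 0
        for iv in ivset:
            if iv.chrom not in stats_cache:
                stats_cache[iv.chrom] = SequenceStats(genome[iv.chrom])
            st = stats_cache[iv.chrom]
            lo = iv.start - flank
            hi = iv.end + flank
            if lo < 0 or hi > st.length:
                truncated += 1
                lo, hi = max(lo, 0), min(hi, st.length)
            segs = [(lo, iv.start), (iv.end, hi)]
            num = den = 0.0
            for s, e in segs:
                if e <= s:
                    continue
                if measure == "cpg":
                    frac = st.window_cpg([s], [e])[0]
                    w = max(e - s - 1, 1)
                else:
                    frac = st.window_gc([s], [e])[0]
                    w = e - s
                if not np.isnan(frac):
                    num += frac * w
                    den += w
            vals.append(num / den if den else np.nan)
        if truncated:
            warnings.warn(f"{truncated} flanks truncated at chromosome ends")
        return np.asarray(vals, dtype=float)

    va = flank_values(set_a)
    vb = flank_values(set_b)
    va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
    if len(va) == 0 or len(vb) == 0:
        raise EmptyInputError("no measurable flanks in one of the sets")
    if np.array_equal(va, vb) and np.std(va) == 0:
        p = 1.0
    else:
        p = float(sps.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
    return float(va.mean()), float(vb.mean()), p


def thin_intervals(intervals: IntervalSet, min_separation: int) -> IntervalSet:
    """Greedy left-to-right thinning so no two kept midpoints are within
    ``min_separation`` bp (used for repeat-centered profiles)."""
    kept: List[Interval] = []
    last_mid: Dict[str, int] = {}
    for iv in intervals:
        prev = last_mid.get(iv.chrom)
        if prev is None or iv.midpoint - prev >= min_separation:
            kept.append(iv)
            last_mid[iv.chrom] = iv.midpoint
    return IntervalSet(kept, label=f"{intervals.label}:thinned")
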