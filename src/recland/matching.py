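"""Matched hotspot/coldspot construction for motif case/control analysis.

Coldspot candidates for a hotspot are same-width windows on the same
chromosome laid on a non-overlapping grid (step = window width), restricted
to windows with

* no overlap with any called hotspot,
* no local rate elevation (max rate <= ``elevation_fold`` x the chromosome's
  bp-weighted median rate),
* missing-sequence fraction within ``max_missing``,
* GC content within 0.5 percentage points and CpG content within 0.1
  percentage points of the hotspot.

Among qualifying windows the one closest in SNP density is chosen (ties
broken by leftmost coordinate).  Hotspots are processed in descending
peak-rate order and each coldspot window is usable once, so returned
coldspots never overlap each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from recland.errors import EmptyInputError
from recland.genetic_map import GeneticMap, Hotspot, hotspots_to_intervals
from recland.intervals import Interval, IntervalSet, merge_sorted
from recland.seqstats import SequenceStats, sequence_composition

__all__ = [
    "MatchedPair",
    "MatchTolerances",
    "sequence_composition",
    "select_candidates",
    "match_coldspots",
]


@dataclass(frozen=True)
class MatchTolerances:
    gc_pp: float = 0.5   # percentage points
    cpg_pp: float = 0.1  # percentage points


@dataclass(frozen=True)
class MatchedPair:
    """A hotspot and its composition-matched control window."""

    hotspot: Hotspot
    coldspot: Interval
    delta_gc: float          # coldspot - hotspot, percentage points
    delta_cpg: float         # coldspot - hotspot, percentage points
    delta_snp_density: float  # coldspot - hotspot, SNPs per kb


def _hotspot_seq(genome: Mapping[str, str], h: Hotspot) -> str:
    seq = genome.get(h.chrom)
    if seq is None or h.end > len(seq) or h.start < 0:
        raise ValueError(f"hotspot {h.chrom}:{h.start}-{h.end} outside genome bounds")
    return seq[h.start : h.end]


def select_candidates(
    hotspots: Sequence[Hotspot],
    genome: Mapping[str, str],
    max_missing: float = 0.0,
) -> List[Hotspot]:
    """Keep hotspots whose sequence N-fraction is at most ``max_missing``."""
    kept = []
    for h in hotspots:
        seq = _hotspot_seq(genome, h)
        _, _, n_frac = sequence_composition(seq)
        if n_frac <= max_missing:
            kept.append(h)
    return kept


def _elevated_regions(gmap: GeneticMap, elevation_fold: float) -> Tuple[np.ndarray, np.ndarray]:
    """0-based merged regions where the rate exceeds fold x chromosome median."""
    median = gmap.weighted_median_rate()
    mask = gmap.rates > elevation_fold * median
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts = gmap.boundaries[idx] - 1
    ends = gmap.boundaries[idx + 1] - 1
    return merge_sorted(starts, ends)


def _merge_excluded(*pairs: Tuple[np.ndarray, np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    starts = np.concatenate([p[0] for p in pairs]) if pairs else np.empty(0, np.int64)
    ends = np.concatenate([p[1] for p in pairs]) if pairs else np.empty(0, np.int64)
    order = np.argsort(starts, kind="stable")
    return merge_sorted(starts[order], ends[order])


def _overlaps(starts: np.ndarray, ends: np.ndarray,
              ex_s: np.ndarray, ex_e: np.ndarray) -> np.ndarray:
    if len(ex_s) == 0:
        return np.zeros(starts.shape, dtype=bool)
    idx = np.searchsorted(ex_s, ends, side="left")
    hit = idx > 0
    hit[hit] = ex_e[idx[hit] - 1] > starts[hit]
    return hit


def match_coldspots(
    hotspots: Sequence[Hotspot],
    gmaps: Mapping[str, GeneticMap],
    genome: Mapping[str, str],
    snp_positions: Optional[Mapping[str, np.ndarray]] = None,
    tolerances: MatchTolerances = MatchTolerances(),
    elevation_fold: float = 2.0,
    max_missing: float = 0.0,
) -> Tuple[List[MatchedPair], List[Hotspot]]:
    """Match each hotspot to a composition-matched coldspot window.

    Parameters
    ----------
    snp_positions
        Per-chromosome sorted 0-based SNP positions used for the
        SNP-density tie-break; when omitted density is treated as 0
        everywhere and the leftmost in-tolerance window wins.

    Returns ``(matched_pairs, unmatched_hotspots)``.
    """
    if not hotspots:
        raise EmptyInputError("no hotspots to match")
    stats = {c: SequenceStats(s) for c, s in genome.items() if any(
        h.chrom == c for h in hotspots)}
    hot_ivs = hotspots_to_intervals(hotspots)
    excluded: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in stats:
        parts = []
        merged_hot = hot_ivs.merged_by_chrom().get(chrom)
        if merged_hot is not None:
            parts.append(merged_hot)
        if chrom in gmaps:
            parts.append(_elevated_regions(gmaps[chrom], elevation_fold))
        excluded[chrom] = _merge_excluded(*parts)

    snp_positions = snp_positions or {}
    pairs: List[MatchedPair] = []
    unmatched: List[Hotspot] = []

    order = sorted(range(len(hotspots)),
                   key=lambda i: -hotspots[i].peak_rate)
    for i in order:
        h = hotspots[i]
        chrom_stats = stats[h.chrom]
        w = h.width
        seq_len = chrom_stats.length
        if w > seq_len:
            unmatched.append(h)
            continue
        hot_gc = float(chrom_stats.window_gc([h.start], [h.end])[0])
        hot_cpg = float(chrom_stats.window_cpg([h.start], [h.end])[0])
        starts = np.arange(0, seq_len - w + 1, w, dtype=np.int64)
        ends = starts + w
        ex_s, ex_e = excluded[h.chrom]
        ok = ~_overlaps(starts, ends, ex_s, ex_e)
        ok &= chrom_stats.window_n_fraction(starts, ends) <= max_missing
        with np.errstate(invalid="ignore"):
            d_gc = (chrom_stats.window_gc(starts, ends) - hot_gc) * 100.0
            d_cpg = (chrom_stats.window_cpg(starts, ends) - hot_cpg) * 100.0
        ok &= np.abs(d_gc) <= tolerances.gc_pp
        ok &= np.abs(d_cpg) <= tolerances.cpg_pp
        cand = np.flatnonzero(ok)
        if len(cand) == 0:
            unmatched.append(h)
            continue
        pos = snp_positions.get(h.chrom, np.empty(0, dtype=np.int64))
        pos = np.asarray(pos)
        per_kb = 1000.0 / w
        dens = (
            np.searchsorted(pos, ends[cand]) - np.searchsorted(pos, starts[cand])
        ) * per_kb
        hot_dens = (
            np.searchsorted(pos, h.end) - np.searchsorted(pos, h.start)
        ) * per_kb
        best_i = int(np.argmin(np.abs(dens - hot_dens)))
        best = int(cand[best_i])
        cold = Interval(h.chrom, int(starts[best]), int(ends[best]), name="coldspot")
        pairs.append(
            MatchedPair(
                hotspot=h,
                coldspot=cold,
                delta_gc=float(d_gc[best]),
                delta_cpg=float(d_cpg[best]),
                delta_snp_density=float(dens[best_i] - hot_dens),
            )
        )
        # a coldspot window is consumed once
        excluded[h.chrom] = _merge_excluded(
            excluded[h.chrom], (starts[best : best + 1], ends[best : best + 1])
        )
    return pairs, unmatched
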