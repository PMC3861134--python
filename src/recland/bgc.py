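"""Outgroup polarization and GC-biased gene-conversion skew statistics.

Polymorphisms are polarized by parsimony against a single outgroup allele
(the shared allele is taken as ancestral), classified as weak-to-strong
(AT->GC), strong-to-weak (GC->AT) or neutral (W->W / S->S), and the skew
statistic — the per-distance-bin ratio of AT->GC to GC->AT derived counts
around hotspot centers — is computed with a hotspot-level bootstrap for
confidence bands.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from recland.errors import EmptyInputError, ParameterError
from recland.genetic_map import Hotspot

WEAK = frozenset("AT")
STRONG = frozenset("CG")

CLASS_WS = "AT->GC"
CLASS_SW = "GC->AT"
CLASS_NEUTRAL = "neutral"


@dataclass(frozen=True)
class PolarizedSnp:
    """A biallelic site with ancestral/derived call (0-based position)."""

    chrom: str
    pos: int
    ancestral: str
    derived: str
    lineage: str = "ingroup"
    mutation_class: str = ""
    creates_cpg: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived alleles must differ")


def classify_mutation(ancestral: str, derived: str) -> str:
    """Mutation class from allele identities alone (W={A,T}, S={C,G})."""
    anc_w, der_w = ancestral in WEAK, derived in WEAK
    if anc_w and not der_w:
        return CLASS_WS
    if not anc_w and der_w:
        return CLASS_SW
    return CLASS_NEUTRAL


def polarize(
    chrom: str,
    pos: int,
    alleles: Tuple[str, str],
    outgroup: str,
    lineage: str = "ingroup",
) -> Optional[PolarizedSnp]:
    """Polarize one biallelic site; ``None`` when no high-confidence polarity.

    The outgroup allele must equal exactly one of the two ingroup alleles;
    that allele is called ancestral and the other derived.
    """
    a1, a2 = (a.upper() for a in alleles)
    outgroup = outgroup.upper()
    if a1 == a2 or a1 not in "ACGT" or a2 not in "ACGT":
        return None
    if outgroup == a1 and outgroup != a2:
        anc, der = a1, a2
    elif outgroup == a2 and outgroup != a1:
        anc, der = a2, a1
    else:
        return None  # no shared allele (or outgroup matches both/neither)
    return PolarizedSnp(
        chrom=chrom,
        pos=pos,
        ancestral=anc,
        derived=der,
        lineage=lineage,
        mutation_class=classify_mutation(anc, der),
    )


def flag_cpg_creating(
    left: str, alleles: Tuple[str, str], right: str
) -> Optional[bool]:
    """Would either allele create a CpG dinucleotide in context?

    True iff the left flank is C and either allele is G, or the right flank
    is G and either allele is C.  Returns ``None`` (undeterminable) when a
    flank is not an unambiguous base; such sites are excluded conservatively
    by downstream filters.
    """
    left, right = left.upper(), right.upper()
    a = {x.upper() for x in alleles}
    if left not in "ACGT" or right not in "ACGT":
        return None
    return (left == "C" and "G" in a) or (right == "G" and "C" in a)


def polarize_frame(df: pd.DataFrame, lineage: str = "ingroup") -> pd.DataFrame:
    """Vectorized polarization of a SNP table.

    Expects columns ``chrom, pos, allele1, allele2, outgroup`` and optional
    ``left, right`` flanks; returns the accepted rows with ``ancestral``,
    ``derived``, ``mutation_class`` and (when flanks are present)
    ``creates_cpg`` columns added.  Rejected sites (outgroup matching
    neither or both alleles) are dropped.
    """
    a1 = df["allele1"].str.upper().to_numpy(dtype="U1")
    a2 = df["allele2"].str.upper().to_numpy(dtype="U1")
    out = df["outgroup"].str.upper().to_numpy(dtype="U1")
    match1 = (out == a1) & (out != a2)
    match2 = (out == a2) & (out != a1)
    accepted = (match1 | match2) & (a1 != a2)
    anc = np.where(match1, a1, a2)
    der = np.where(match1, a2, a1)
    res = df.loc[accepted, ["chrom", "pos"]].copy()
    anc, der = anc[accepted], der[accepted]
    res["ancestral"] = anc
    res["derived"] = der
    anc_w = np.isin(anc, list(WEAK))
    der_w = np.isin(der, list(WEAK))
    cls = np.full(len(res), CLASS_NEUTRAL, dtype=object)
    cls[anc_w & ~der_w] = CLASS_WS
    cls[~anc_w & der_w] = CLASS_SW
    res["mutation_class"] = cls
    res["lineage"] = lineage
    if "left" in df.columns and "right" in df.columns:
        left = df["left"].astype(str).str.upper().to_numpy(dtype="U1")[accepted]
        right = df["right"].astype(str).str.upper().to_numpy(dtype="U1")[accepted]
        has_g = (anc == "G") | (der == "G")
        has_c = (anc == "C") | (der == "C")
        flag = ((left == "C") & has_g) | ((right == "G") & has_c)
        determinable = np.isin(left, list("ACGT")) & np.isin(right, list("ACGT"))
        res["creates_cpg"] = pd.array(
            np.where(determinable, flag, None), dtype="boolean"
        )
    return res.reset_index(drop=True)


@dataclass
class SkewProfile:
    """Distance-binned AT->GC vs GC->AT counts around hotspot centers."""

    bin_edges: np.ndarray       # signed distance, length n_bins + 1
    n_ws: np.ndarray            # AT->GC count per bin
    n_sw: np.ndarray            # GC->AT count per bin
    ratio: np.ndarray           # n_ws / n_sw; NaN where n_sw == 0
    ci_low: np.ndarray          # bootstrap 2.5% (NaN where undefined)
    ci_high: np.ndarray         # bootstrap 97.5%
    n_hotspots: int
    n_boot: int

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "n_WS": self.n_ws,
                "n_SW": self.n_sw,
                "ratio": self.ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _snps_to_frame(
    snps: Union[pd.DataFrame, Sequence[PolarizedSnp]]
) -> pd.DataFrame:
    if isinstance(snps, pd.DataFrame):
        return snps
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos for s in snps],
            "mutation_class": [s.mutation_class for s in snps],
            "creates_cpg": pd.array(
                [s.creates_cpg for s in snps], dtype="boolean"
            ),
        }
    )


def _assign_to_hotspots(
    df: pd.DataFrame, hotspots: Sequence[Hotspot]
) -> Tuple[np.ndarray, np.ndarray]:
    """(hotspot index, signed distance to that hotspot's center) per SNP.

    Each SNP is attached to the nearest hotspot center on its chromosome;
    SNPs on chromosomes without hotspots get index -1.
    """
    centers_by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {h.chrom for h in hotspots}:
        idx = np.array([i for i, h in enumerate(hotspots) if h.chrom == chrom])
        cent = np.array([hotspots[i].center for i in idx])
        order = np.argsort(cent)
        centers_by_chrom[chrom] = (cent[order], idx[order])
    hot_idx = np.full(len(df), -1, dtype=np.int64)
    dist = np.zeros(len(df), dtype=np.int64)
    pos_all = df["pos"].to_numpy(dtype=np.int64)
    chrom_all = df["chrom"].to_numpy()
    for chrom, (cent, idx) in centers_by_chrom.items():
        sel = np.flatnonzero(chrom_all == chrom)
        if len(sel) == 0:
            continue
        pos = pos_all[sel]
        j = np.searchsorted(cent, pos)
        j_left = np.clip(j - 1, 0, len(cent) - 1)
        j_right = np.clip(j, 0, len(cent) - 1)
        use_right = np.abs(cent[j_right] - pos) < np.abs(pos - cent[j_left])
        nearest = np.where(use_right, j_right, j_left)
        hot_idx[sel] = idx[nearest]
        dist[sel] = pos - cent[nearest]
    return hot_idx, dist


def skew_profile(
    snps: Union[pd.DataFrame, Sequence[PolarizedSnp]],
    hotspots: Sequence[Hotspot],
    bin_width: int = 1_000,
    max_dist: int = 25_000,
    n_boot: int = 200,
    seed: Optional[int] = None,
    exclude_cpg: bool = False,
    max_hotspot_width: Optional[int] = 5_000,
    exact_bootstrap: bool = False,
    ci_method: str = "basic",
) -> SkewProfile:
    """Skew ratio profile around hotspot centers with bootstrap CI.

    Each polarized SNP is binned by signed distance to the nearest (width-
    filtered) hotspot center; the per-bin ratio is ``n_WS / n_SW``.  The
    bootstrap resamples *hotspots* with replacement, carrying each hotspot's
    attached SNPs, and takes the 2.5/97.5 percentiles of the resampled
    ratios.  With ``exclude_cpg`` any site whose ``creates_cpg`` flag is
    True or undeterminable is dropped first.  ``exact_bootstrap``
    enumerates all ``H**H`` resamples (tiny H only) instead of sampling.

    ``ci_method`` selects the interval construction from the resampled
    ratios: ``"basic"`` (default) reflects the 2.5/97.5 percentiles around
    the point estimate, which restores nominal coverage for this
    ratio-of-sums statistic; ``"percentile"`` reports the raw percentiles.
    """
    if ci_method not in ("basic", "percentile"):
        raise ParameterError("ci_method must be 'basic' or 'percentile'")
    if max_hotspot_width is not None:
        hotspots = [h for h in hotspots if h.width <= max_hotspot_width]
    if not hotspots:
        raise EmptyInputError("no (localized) hotspots for skew profile")
    df = _snps_to_frame(snps)
    keep = df["mutation_class"].isin([CLASS_WS, CLASS_SW]).to_numpy()
    if exclude_cpg:
        if "creates_cpg" not in df.columns:
            raise ParameterError("exclude_cpg requires a creates_cpg column")
        flag = df["creates_cpg"]
        keep &= (flag == False).fillna(False).to_numpy()  # noqa: E712
    df = df.loc[keep]

    edges = np.arange(-max_dist, max_dist + bin_width, bin_width, dtype=np.int64)
    n_bins = len(edges) - 1
    hot_idx, dist = _assign_to_hotspots(df, hotspots)
    in_range = (hot_idx >= 0) & (dist >= edges[0]) & (dist < edges[-1])
    bins = np.searchsorted(edges, dist[in_range], side="right") - 1
    h_of_snp = hot_idx[in_range]
    is_ws = (df["mutation_class"].to_numpy() == CLASS_WS)[in_range]

    n_hot = len(hotspots)
    ws_mat = np.zeros((n_hot, n_bins), dtype=np.int64)
    sw_mat = np.zeros((n_hot, n_bins), dtype=np.int64)
    np.add.at(ws_mat, (h_of_snp[is_ws], bins[is_ws]), 1)
    np.add.at(sw_mat, (h_of_snp[~is_ws], bins[~is_ws]), 1)

    n_ws = ws_mat.sum(axis=0)
    n_sw = sw_mat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(n_sw > 0, n_ws / np.maximum(n_sw, 1), np.nan)

    if exact_bootstrap:
        if n_hot ** n_hot > 200_000:
            raise ParameterError("exact bootstrap only feasible for tiny n")
        ratios = []
        for resample in itertools.product(range(n_hot), repeat=n_hot):
            idx = np.asarray(resample)
            ws_b = ws_mat[idx].sum(axis=0)
            sw_b = sw_mat[idx].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                ratios.append(np.where(sw_b > 0, ws_b / np.maximum(sw_b, 1), np.nan))
        boot = np.asarray(ratios)
        n_boot_done = len(ratios)
    else:
        rng = np.random.default_rng(seed)
        weights = rng.multinomial(n_hot, np.full(n_hot, 1.0 / n_hot), size=n_boot)
        ws_b = weights @ ws_mat
        sw_b = weights @ sw_mat
        with np.errstate(invalid="ignore", divide="ignore"):
            boot = np.where(sw_b > 0, ws_b / np.maximum(sw_b, 1), np.nan)
        n_boot_done = n_boot

    ci_low = np.full(n_bins, np.nan)
    ci_high = np.full(n_bins, np.nan)
    defined = n_sw > 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        q_low = np.nanpercentile(boot[:, defined], 2.5, axis=0)
        q_high = np.nanpercentile(boot[:, defined], 97.5, axis=0)
    if ci_method == "basic":
        ci_low[defined] = np.maximum(2 * ratio[defined] - q_high, 0.0)
        ci_high[defined] = 2 * ratio[defined] - q_low
    else:
        ci_low[defined] = q_low
        ci_high[defined] = q_high
    return SkewProfile(
        bin_edges=edges,
        n_ws=n_ws,
        n_sw=n_sw,
        ratio=ratio,
        ci_low=ci_low,
        ci_high=ci_high,
        n_hotspots=n_hot,
        n_boot=n_boot_done,
    )


def stratified_skew(
    snps: Union[pd.DataFrame, Sequence[PolarizedSnp]],
    hotspots: Sequence[Hotspot],
    **kwargs,
) -> Dict[str, SkewProfile]:
    """One skew profile per hotspot strength class (classes must be set)."""
    by_class: Dict[str, List[Hotspot]] = {}
    for h in hotspots:
        if h.strength_class is None:
            raise ParameterError(
                "stratified_skew needs strength classes (run classify_strength)"
            )
        by_class.setdefault(h.strength_class, []).append(h)
    out: Dict[str, SkewProfile] = {}
    for cls, group in sorted(by_class.items()):
        try:
            out[cls] = skew_profile(snps, group, **kwargs)
        except EmptyInputError:
            warnings.warn(f"strength class {cls!r} empty after filtering; omitted")
    return out
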