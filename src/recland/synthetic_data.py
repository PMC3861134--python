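"""Ground-truth simulator: genomes, annotations, rate maps, two-lineage SNPs.

The generator is deliberately coalescent-free: two lineages diverge from a
common ancestral sequence (the emitted genome), each acquiring independent
single-base polymorphisms at a configurable rate, and the ingroup lineage
optionally experiences a weak-to-strong transmission bias inside a kernel
around hotspot centers.  Every statistic computed by the analysis modules
is a function of marginal site counts, so no linkage structure is needed.

Draw order (one :class:`numpy.random.Generator` per run, seeded from the
config): genome background, islands, genes, repeats — per chromosome in
order; then map hotspots; then ingroup SNPs, then outgroup SNPs; then peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from recland.errors import ParameterError
from recland.genetic_map import GeneticMap, Hotspot
from recland.intervals import Interval, IntervalSet, merge_sorted

_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_WEAK_CODES = np.array([True, False, False, True])  # A, C, G, T


@dataclass
class SimConfig:
    """All knobs of the simulator; ``b = 0.5`` means no transmission bias."""

    # genome
    chrom_length: int = 2_000_000
    n_chroms: int = 1
    base_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # CpG islands (per chromosome)
    n_islands: int = 40
    island_length: int = 1_500
    island_cpg_multiplier: float = 10.0
    # genes (per chromosome)
    n_genes: int = 30
    gene_length: int = 10_000
    tss_island_frac: float = 0.8
    # repeats (per chromosome)
    n_repeats: int = 30
    repeat_length: int = 500
    # recombination map
    background_rate: float = 1.0
    n_hotspots: int = 20
    hotspot_fold: float = 10.0
    hotspot_width: int = 4_000
    hotspot_island_frac: float = 0.5
    hotspot_shape: str = "rect"  # "rect" or "triangle"
    hotspot_fold_jitter: float = 0.0  # relative uniform jitter on the fold
    # polymorphisms
    mutation_rate: float = 0.002
    outgroup_mutation_rate: Optional[float] = None
    divergence: float = 0.002
    bias_b: float = 0.5
    bias_halfwidth: int = 5_000
    bias_kernel: str = "rect"  # "rect" or "triangle"
    # H3K4me3-like peaks
    n_peaks_stage1: int = 100
    n_peaks_stage2: int = 100
    peak_sharing: float = 0.6
    peak_width: int = 1_000
    peak_island_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length <= 0 or self.n_chroms <= 0:
            raise ParameterError("genome dimensions must be positive")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or not np.isclose(comp.sum(), 1.0):
            raise ParameterError("base_composition must be 4 non-negative freqs summing to 1")
        if not (0.5 <= self.bias_b < 1.0):
            raise ParameterError("transmission bias b must lie in [0.5, 1)")
        for name in ("background_rate", "mutation_rate", "divergence",
                     "island_cpg_multiplier", "hotspot_fold"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.hotspot_shape not in ("rect", "triangle"):
            raise ParameterError("hotspot_shape must be 'rect' or 'triangle'")
        if self.bias_kernel not in ("rect", "triangle"):
            raise ParameterError("bias_kernel must be 'rect' or 'triangle'")
        if not (0.0 <= self.peak_sharing <= 1.0):
            raise ParameterError("peak_sharing must be in [0, 1]")

    @property
    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimulatedGenome:
    """Genome arrays plus annotation interval sets."""

    arrays: Dict[str, np.ndarray]  # ASCII uint8 per chromosome
    islands: IntervalSet
    genes: IntervalSet
    tss: IntervalSet
    repeats: IntervalSet

    @property
    def sequences(self) -> Dict[str, str]:
        return {c: a.tobytes().decode("ascii") for c, a in self.arrays.items()}

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: len(a) for c, a in self.arrays.items()}


def _island_cg_prob(config: SimConfig) -> float:
    _, f_c, f_g, _ = config.base_composition
    background_cpg = f_c * f_g
    target_extra = (config.island_cpg_multiplier - 1.0) * background_cpg
    if target_extra <= 0:
        return 0.0
    q = target_extra / max(1.0 - target_extra, 1e-9)
    return float(np.clip(q, 0.0, 0.9))


def _island_sequence(length: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """CpG-enriched segment: CG dinucleotides interleaved with background bases."""
    q = _island_cg_prob(config)
    plant = rng.random(length) < q
    bases = _LUT[rng.choice(4, size=length, p=config.base_composition)]
    out = np.empty(length, dtype=np.uint8)
    i = block = 0
    while i < length:
        if plant[block] and i + 1 < length:
            out[i] = ord("C")
            out[i + 1] = ord("G")
            i += 2
        else:
            out[i] = bases[block]
            i += 1
        block += 1
    return out


def simulate_genome(config: SimConfig,
                    rng: Optional[np.random.Generator] = None) -> SimulatedGenome:
    """Generate per-chromosome sequence plus island/gene/TSS/repeat annotations.

    The background is i.i.d. at ``base_composition``; islands are
    CpG-enriched segments planted on a spaced grid; a ``tss_island_frac``
    fraction of TSS sit inside islands; repeats are labeled low-complexity
    ("LC") or background-content ("TE") segments avoiding islands.
    """
    rng = rng or config.rng()
    L = config.chrom_length
    arrays: Dict[str, np.ndarray] = {}
    islands: List[Interval] = []
    genes: List[Interval] = []
    tss: List[Interval] = []
    repeats: List[Interval] = []
    for chrom in config.chrom_names:
        arr = _LUT[rng.choice(4, size=L, p=config.base_composition)]
        # --- islands on a spaced grid ---
        slot = config.island_length * 3
        n_slots = max(L // slot - 1, 0)
        if config.n_islands > n_slots:
            raise ParameterError(
                f"island density infeasible: {config.n_islands} islands need "
                f"more than {L} bp at length {config.island_length}"
            )
        chrom_islands: List[Interval] = []
        if config.n_islands > 0:
            picks = np.sort(rng.choice(n_slots, size=config.n_islands, replace=False))
            for p in picks:
                s = int(p) * slot + config.island_length
                e = s + config.island_length
                arr[s:e] = _island_sequence(config.island_length, config, rng)
                chrom_islands.append(Interval(chrom, s, e, name="island"))
        islands.extend(chrom_islands)
        # --- genes / TSS ---
        if config.n_genes > 0:
            n_on_island = int(round(config.tss_island_frac * config.n_genes))
            n_on_island = min(n_on_island, len(chrom_islands))
            tss_pos: List[int] = []
            if n_on_island:
                isl_idx = rng.choice(len(chrom_islands), size=n_on_island, replace=False)
                for j in isl_idx:
                    tss_pos.append(chrom_islands[int(j)].midpoint)
            n_rest = config.n_genes - n_on_island
            margin = config.gene_length + 1
            tss_pos.extend(
                int(x) for x in rng.integers(margin, L - margin, size=n_rest)
            )
            for p in tss_pos:
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    g0, g1 = p, min(p + config.gene_length, L)
                else:
                    g0, g1 = max(p - config.gene_length + 1, 0), p + 1
                genes.append(Interval(chrom, g0, g1, name="gene", strand=strand))
                tss.append(Interval(chrom, p, p + 1, name="tss", strand=strand))
        # --- repeats ---
        island_set = IntervalSet(chrom_islands)
        placed = 0
        attempts = 0
        while placed < config.n_repeats and attempts < config.n_repeats * 20:
            attempts += 1
            s = int(rng.integers(0, L - config.repeat_length))
            e = s + config.repeat_length
            if island_set.overlaps_any(chrom, np.array([s]), np.array([e]))[0]:
                continue
            family = "LC" if placed % 2 == 0 else "TE"
            if family == "LC":
                duo = _LUT[rng.choice(4, size=2, replace=False)]
                arr[s:e] = np.tile(duo, config.repeat_length // 2 + 1)[: e - s]
            repeats.append(Interval(chrom, s, e, name=family))
            placed += 1
        arrays[chrom] = arr
    return SimulatedGenome(
        arrays=arrays,
        islands=IntervalSet(islands, label="islands"),
        genes=IntervalSet(genes, label="genes"),
        tss=IntervalSet(tss, label="tss"),
        repeats=IntervalSet(repeats, label="repeats"),
    )


def simulate_map(
    config: SimConfig,
    islands: IntervalSet,
    rng: Optional[np.random.Generator] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> Tuple[Dict[str, GeneticMap], List[Hotspot]]:
    """Constant background rate plus peaked elevations, a fraction on islands.

    Returns the per-chromosome maps and the merged true hotspot list (with
    peak rates read back from the constructed track).
    """
    rng = rng or config.rng()
    lengths = dict(chrom_lengths) if chrom_lengths else {
        c: config.chrom_length for c in config.chrom_names
    }
    bg = config.background_rate
    maps: Dict[str, GeneticMap] = {}
    hotspots: List[Hotspot] = []
    for chrom in config.chrom_names:
        L = lengths[chrom]
        isl = [iv for iv in islands if iv.chrom == chrom]
        n_on_island = int(round(config.hotspot_island_frac * config.n_hotspots))
        n_on_island = min(n_on_island, len(isl))
        centers: List[int] = []
        if n_on_island:
            for j in rng.choice(len(isl), size=n_on_island, replace=False):
                centers.append(isl[int(j)].midpoint)
        margin = config.hotspot_width
        n_rest = config.n_hotspots - n_on_island
        centers.extend(
            int(x) for x in rng.integers(margin, L - margin, size=n_rest)
        )
        folds = np.full(len(centers), config.hotspot_fold)
        if config.hotspot_fold_jitter > 0:
            folds *= 1.0 + rng.uniform(
                -config.hotspot_fold_jitter, config.hotspot_fold_jitter, len(centers)
            )
        # piecewise-constant additive bumps via an event sweep (1-based coords)
        events: Dict[int, float] = {}
        spans: List[Tuple[int, int]] = []
        half = config.hotspot_width // 2
        for c, fold in zip(centers, folds):
            s0, e0 = max(c - half, 0), min(c + half, L)  # 0-based
            spans.append((s0, e0))
            add = bg * (fold - 1.0)
            if config.hotspot_shape == "rect":
                segs = [(s0, e0, add)]
            else:  # triangle, 8-step staircase
                n_steps = 8
                cuts = np.linspace(s0, e0, n_steps + 1).astype(int)
                mids = (cuts[:-1] + cuts[1:]) / 2.0
                height = add * np.maximum(0.0, 1.0 - np.abs(mids - c) / half)
                segs = [
                    (int(a), int(b), float(h))
                    for a, b, h in zip(cuts[:-1], cuts[1:], height)
                    if b > a
                ]
            for a, b, h in segs:
                events[a + 1] = events.get(a + 1, 0.0) + h
                events[b + 1] = events.get(b + 1, 0.0) - h
        cuts = sorted(set([1, L + 1]) | set(events))
        boundaries = np.array(cuts, dtype=np.int64)
        rates = np.empty(len(boundaries) - 1)
        level = 0.0
        for i, pos in enumerate(boundaries[:-1]):
            level += events.get(int(pos), 0.0)
            rates[i] = bg + level
        gmap = GeneticMap(chrom, boundaries, np.maximum(rates, 0.0))
        maps[chrom] = gmap
        # merged truth intervals
        if spans:
            spans.sort()
            ms, me = merge_sorted(
                np.array([s for s, _ in spans]), np.array([e for _, e in spans])
            )
            for s, e in zip(ms, me):
                peak = float(
                    gmap.rates[
                        np.searchsorted(gmap.boundaries, s + 1, side="right") - 1 :
                        np.searchsorted(gmap.boundaries, e + 1, side="left")
                    ].max()
                )
                hotspots.append(
                    Hotspot(chrom, int(s), int(e), peak_rate=peak, background_rate=bg)
                )
    return maps, hotspots


@dataclass
class PolymorphismSet:
    """Simulated SNPs for both lineages plus per-site truth."""

    ingroup: pd.DataFrame   # chrom, pos (0-based), allele1, allele2, outgroup, left, right
    outgroup: pd.DataFrame  # same columns; 'outgroup' holds the ingroup allele
    truth: pd.DataFrame     # chrom, pos, lineage, ancestral, derived, mutation_class, bias_applied


def _bias_weight(dist: np.ndarray, config: SimConfig) -> np.ndarray:
    ad = np.abs(dist).astype(float)
    if config.bias_kernel == "rect":
        return (ad <= config.bias_halfwidth).astype(float)
    return np.maximum(0.0, 1.0 - ad / config.bias_halfwidth)


def _nearest_center_dist(pos: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Unsigned distance from each position to its nearest hotspot center."""
    if len(centers) == 0:
        return np.full(pos.shape, np.iinfo(np.int64).max)
    centers = np.sort(centers)
    j = np.searchsorted(centers, pos)
    jl = np.clip(j - 1, 0, len(centers) - 1)
    jr = np.clip(j, 0, len(centers) - 1)
    return np.minimum(np.abs(pos - centers[jl]), np.abs(centers[jr] - pos))


def simulate_polymorphisms(
    config: SimConfig,
    genome: SimulatedGenome,
    hotspots: Sequence[Hotspot],
    rng: Optional[np.random.Generator] = None,
) -> PolymorphismSet:
    """Place two-lineage polymorphisms with optional transmission bias.

    Candidate mutations arise i.i.d. at ``mutation_rate`` per bp per lineage
    on the ancestral (emitted) sequence; the derived base is uniform over
    the three alternatives.  Every candidate survives to be observed with
    probability 1/2 except ingroup W<->S candidates inside the bias kernel,
    whose survival probability is ``b`` when the derived allele is strong
    (C/G) and ``1 - b`` when weak — so ``b = 0.5`` reproduces neutrality
    exactly and the local observed W->S : S->W ratio tends to ``b/(1-b)``
    times its background value.  The outgroup lineage is never biased.  The
    allele recorded for the *other* species at each SNP starts from the
    ancestral base and is substituted with probability ``divergence``.
    """
    rng = rng or config.rng()
    frames_in: List[pd.DataFrame] = []
    frames_out: List[pd.DataFrame] = []
    truth_rows: List[pd.DataFrame] = []
    centers_by_chrom: Dict[str, np.ndarray] = {}
    for h in hotspots:
        centers_by_chrom.setdefault(h.chrom, [])
    for h in hotspots:
        centers_by_chrom[h.chrom].append(h.center)
    centers_by_chrom = {c: np.array(v) for c, v in centers_by_chrom.items()}

    out_rate = (
        config.outgroup_mutation_rate
        if config.outgroup_mutation_rate is not None
        else config.mutation_rate
    )

    for chrom, arr in genome.arrays.items():
        L = len(arr)
        centers = centers_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        for lineage, rate, biased in (
            ("ingroup", config.mutation_rate, True),
            ("outgroup", out_rate, False),
        ):
            n = rng.poisson(L * rate)
            if n == 0:
                continue
            pos = np.unique(rng.integers(1, L - 1, size=n))
            anc_code = _CODE[arr[pos]]
            der_code = (anc_code + rng.integers(1, 4, size=len(pos))) % 4
            anc_w = _WEAK_CODES[anc_code]
            der_w = _WEAK_CODES[der_code]
            is_ws = anc_w & ~der_w
            is_sw = ~anc_w & der_w
            p_keep = np.full(len(pos), 0.5)
            bias_applied = np.zeros(len(pos), dtype=bool)
            if biased and config.bias_b > 0.5 and len(centers):
                dist = _nearest_center_dist(pos, centers)
                w = _bias_weight(dist, config)
                delta = w * (config.bias_b - 0.5)
                p_keep = np.where(is_ws, 0.5 + delta, p_keep)
                p_keep = np.where(is_sw, 0.5 - delta, p_keep)
                bias_applied = (w > 0) & (is_ws | is_sw)
            keep = rng.random(len(pos)) < p_keep
            pos, anc_code, der_code = pos[keep], anc_code[keep], der_code[keep]
            is_ws, is_sw = is_ws[keep], is_sw[keep]
            bias_applied = bias_applied[keep]
            # allele of the other species: ancestral base +/- divergence subs
            other = anc_code.copy()
            div = rng.random(len(pos)) < config.divergence
            other[div] = (other[div] + rng.integers(1, 4, size=int(div.sum()))) % 4
            # shuffle allele order so polarity is not encoded in the columns
            swap = rng.random(len(pos)) < 0.5
            a1 = np.where(swap, der_code, anc_code)
            a2 = np.where(swap, anc_code, der_code)
            base = lambda codes: _LUT[codes].tobytes().decode("ascii")  # noqa: E731
            frame = pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "allele1": list(base(a1)),
                    "allele2": list(base(a2)),
                    "outgroup": list(base(other)),
                    "left": list(arr[pos - 1].tobytes().decode("ascii")),
                    "right": list(arr[pos + 1].tobytes().decode("ascii")),
                }
            )
            (frames_in if lineage == "ingroup" else frames_out).append(frame)
            cls = np.full(len(pos), "neutral", dtype=object)
            cls[is_ws] = "AT->GC"
            cls[is_sw] = "GC->AT"
            truth_rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "lineage": lineage,
                        "ancestral": list(base(anc_code)),
                        "derived": list(base(der_code)),
                        "mutation_class": cls,
                        "bias_applied": bias_applied,
                    }
                )
            )

    empty = pd.DataFrame(
        columns=["chrom", "pos", "allele1", "allele2", "outgroup", "left", "right"]
    )
    empty_truth = pd.DataFrame(
        columns=["chrom", "pos", "lineage", "ancestral", "derived",
                 "mutation_class", "bias_applied"]
    )
    return PolymorphismSet(
        ingroup=pd.concat(frames_in, ignore_index=True) if frames_in else empty,
        outgroup=pd.concat(frames_out, ignore_index=True) if frames_out else empty.copy(),
        truth=pd.concat(truth_rows, ignore_index=True) if truth_rows else empty_truth,
    )


def simulate_peaks(
    config: SimConfig,
    islands: IntervalSet,
    tss: IntervalSet,
    rng: Optional[np.random.Generator] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> Tuple[IntervalSet, IntervalSet]:
    """Two peak sets (two cell stages) with controlled sharing and island overlap.

    All peak locations are drawn without replacement from a pool of disjoint
    candidate sites (island centers and off-island grid slots), so shared
    peaks are identical intervals and unique peaks never touch the other set.
    """
    rng = rng or config.rng()
    lengths = dict(chrom_lengths) if chrom_lengths else {
        c: config.chrom_length for c in config.chrom_names
    }
    w = config.peak_width
    n1, n2 = config.n_peaks_stage1, config.n_peaks_stage2
    n_shared = int(round(config.peak_sharing * min(n1, n2)))
    need = n1 + n2 - n_shared

    island_sites: List[Tuple[str, int]] = []
    for iv in islands:
        island_sites.append((iv.chrom, iv.midpoint))
    grid_sites: List[Tuple[str, int]] = []
    for chrom, L in lengths.items():
        step = 2 * w
        for s in range(w, L - w, step):
            grid_sites.append((chrom, s))
    # drop grid sites colliding with islands
    grid_sites = [
        (c, p)
        for c, p in grid_sites
        if not islands.overlaps_any(c, np.array([p - w // 2]), np.array([p + w // 2]))[0]
    ]
    rng.shuffle(island_sites)
    rng.shuffle(grid_sites)
    if need > len(island_sites) + len(grid_sites):
        raise ParameterError("not enough candidate sites for the requested peaks")

    sites: List[Tuple[str, int]] = []
    for _ in range(need):
        want_island = rng.random() < config.peak_island_frac
        if want_island and island_sites:
            sites.append(island_sites.pop())
        elif grid_sites:
            sites.append(grid_sites.pop())
        else:
            sites.append(island_sites.pop())

    def to_iv(c: str, p: int, name: str) -> Interval:
        return Interval(c, max(p - w // 2, 0), p + w // 2, name=name)

    shared = [to_iv(c, p, "shared") for c, p in sites[:n_shared]]
    rest = sites[n_shared:]
    uniq1 = [to_iv(c, p, "stage1") for c, p in rest[: n1 - n_shared]]
    uniq2 = [to_iv(c, p, "stage2") for c, p in rest[n1 - n_shared :]]
    stage1 = IntervalSet(shared + uniq1, label="stage1")
    stage2 = IntervalSet(shared + uniq2, label="stage2")
    return stage1, stage2


@dataclass
class SimTruth:
    """Everything the generator knows that the pipeline must recover."""

    hotspots: List[Hotspot]
    islands: IntervalSet
    snps: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class SimulationResult:
    config: SimConfig
    genome: SimulatedGenome
    maps: Dict[str, GeneticMap]
    polymorphisms: PolymorphismSet
    peaks_stage1: IntervalSet
    peaks_stage2: IntervalSet
    truth: SimTruth


def simulate_all(config: SimConfig) -> SimulationResult:
    """Run every generator stage with a single seeded random stream."""
    rng = config.rng()
    genome = simulate_genome(config, rng)
    maps, hotspots = simulate_map(
        config, genome.islands, rng, genome.chrom_lengths
    )
    poly = simulate_polymorphisms(config, genome, hotspots, rng)
    stage1, stage2 = simulate_peaks(
        config, genome.islands, genome.tss, rng, genome.chrom_lengths
    )
    return SimulationResult(
        config=config,
        genome=genome,
        maps=maps,
        polymorphisms=poly,
        peaks_stage1=stage1,
        peaks_stage2=stage2,
        truth=SimTruth(hotspots=hotspots, islands=genome.islands, snps=poly.truth),
    )


def write_simulation(result: SimulationResult, outdir) -> None:
    """Emit FASTA / BED / map TSV / SNP TSVs for a simulation run."""
    from recland import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(result.genome.sequences, outdir / "genome.fa")
    io.write_bed(result.genome.islands, outdir / "islands.bed")
    io.write_bed(result.genome.genes, outdir / "genes.bed")
    io.write_bed(result.genome.tss, outdir / "tss.bed")
    io.write_bed(result.genome.repeats, outdir / "repeats.bed")
    io.write_bed(result.peaks_stage1, outdir / "peaks_stage1.bed")
    io.write_bed(result.peaks_stage2, outdir / "peaks_stage2.bed")
    io.write_genetic_map(result.maps, outdir / "map.tsv")
    io.write_chrom_lengths(result.genome.chrom_lengths, outdir / "chrom_lengths.tsv")
    io.write_hotspots_bed(result.truth.hotspots, outdir / "true_hotspots.bed")
    io.write_snp_table(result.polymorphisms.ingroup, outdir / "snps_ingroup.tsv")
    io.write_snp_table(result.polymorphisms.outgroup, outdir / "snps_outgroup.tsv")
    truth = result.truth.snps.copy()
    if len(truth):
        truth["pos"] = truth["pos"] + 1
    truth.to_csv(outdir / "snp_truth.tsv", sep="\t", index=False)
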