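import numpy as np
import pytest

from recland.genetic_map import GeneticMap, Hotspot
from recland.intervals import Interval, IntervalSet
from recland.synthetic_data import SimConfig, simulate_all


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_map():
    """20 Mb chromosome at a constant 1 cM/Mb."""
    return GeneticMap("chr1", np.array([1, 20_000_001]), np.array([1.0]))


def make_map_with_bumps(length, bumps, background=1.0, chrom="chr1"):
    """Piecewise-constant map with additive rectangular bumps.

    ``bumps`` is a list of (start0, end0, extra_rate) in 0-based coords.
    """
    events = {}
    for s, e, extra in bumps:
        events[s + 1] = events.get(s + 1, 0.0) + extra
        events[e + 1] = events.get(e + 1, 0.0) - extra
    cuts = sorted({1, length + 1} | set(events))
    boundaries = np.array(cuts, dtype=np.int64)
    rates = []
    level = 0.0
    for pos in boundaries[:-1]:
        level += events.get(int(pos), 0.0)
        rates.append(background + level)
    return GeneticMap(chrom, boundaries, np.array(rates))


@pytest.fixture
def small_sim():
    """A small but complete simulation shared by several test modules."""
    cfg = SimConfig(
        chrom_length=2_000_000,
        n_islands=40,
        n_genes=25,
        n_hotspots=12,
        hotspot_fold=10.0,
        mutation_rate=0.002,
        seed=42,
    )
    return simulate_all(cfg)


def intervals(label, triples):
    return IntervalSet(
        (Interval(c, s, e) for c, s, e in triples), label=label
    )


def hotspot(chrom, start, end, peak=10.0, bg=1.0, cls=None):
    return Hotspot(chrom, start, end, peak_rate=peak, background_rate=bg,
                   strength_class=cls)
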