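import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recland import io
from recland.errors import EmptyInputError, MapFormatError, ParameterError
from recland.genetic_map import (
    GeneticMap,
    Hotspot,
    HotspotCallerParams,
    call_hotspots,
    classify_strength,
    compare_peak_sets,
    confirm_hotspots,
    hotspots_to_intervals,
    lorenz_curve,
    overlap_randomization_test,
)
from recland.intervals import Interval, IntervalSet

from conftest import hotspot, intervals, make_map_with_bumps


# ---------------------------------------------------------------------------
# map I/O
# ---------------------------------------------------------------------------

class TestMapIO:
    def test_three_row_map_arithmetic(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text(
            "chromosome\tposition\trate\nchr1\t1\t1.0\nchr1\t1001\t5.0\nchr1\t2001\t0\n"
        )
        maps = io.read_genetic_map(path)
        m = maps["chr1"]
        assert m.n_intervals == 2
        # 1000 bp at 1 cM/Mb + 1000 bp at 5 cM/Mb
        assert m.total_cm == pytest.approx(0.001 + 0.005)

    def test_non_ascending_positions_is_format_error(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text(
            "chromosome\tposition\trate\nchr1\t1000\t1.0\nchr1\t500\t2.0\nchr1\t2000\t0\n"
        )
        with pytest.raises(MapFormatError):
            io.read_genetic_map(path)

    def test_negative_rate_is_value_error(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text(
            "chromosome\tposition\trate\nchr1\t1\t-1.0\nchr1\t1000\t0\n"
        )
        with pytest.raises(ValueError):
            io.read_genetic_map(path)

    def test_single_row_chromosome_is_error(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("chromosome\tposition\trate\nchr1\t1\t1.0\n")
        with pytest.raises(MapFormatError):
            io.read_genetic_map(path)

    def test_empty_file_is_error(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("chromosome\tposition\trate\n")
        with pytest.raises(MapFormatError):
            io.read_genetic_map(path)

    def test_round_trip(self, tmp_path):
        m = make_map_with_bumps(100_000, [(10_000, 14_000, 9.0)])
        path = tmp_path / "map.tsv"
        io.write_genetic_map({"chr1": m}, path)
        back = io.read_genetic_map(path)["chr1"]
        np.testing.assert_array_equal(back.boundaries, m.boundaries)
        np.testing.assert_allclose(back.rates, m.rates)


class TestGeneticMapInvariants:
    def test_rejects_decreasing_boundaries(self):
        with pytest.raises(ValueError):
            GeneticMap("chr1", np.array([1, 1000, 999]), np.array([1.0, 1.0]))

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            GeneticMap("chr1", np.array([1, 1000]), np.array([-0.1]))

    def test_mean_rate_matches_hand_computation(self):
        m = GeneticMap("chr1", np.array([1, 1001, 2001]), np.array([1.0, 5.0]))
        # mean over [501, 1501): 500 bp at 1 + 500 bp at 5 = 3 cM/Mb
        assert m.mean_rate(501, 1501) == pytest.approx(3.0)

    def test_rate_at(self):
        m = GeneticMap("chr1", np.array([1, 1001, 2001]), np.array([1.0, 5.0]))
        np.testing.assert_allclose(
            m.rate_at([1, 1000, 1001, 2000]), [1.0, 1.0, 5.0, 5.0]
        )
        np.testing.assert_allclose(m.rate_at([2001, 50_000]), [0.0, 0.0])


# ---------------------------------------------------------------------------
# hotspot calling
# ---------------------------------------------------------------------------

class TestCallHotspots:
    def test_single_planted_segment(self):
        m = make_map_with_bumps(2_000_000, [(1_000_000, 1_004_000, 19.0)])
        hs = call_hotspots(m, HotspotCallerParams(fold=5.0, flank=100_000))
        assert len(hs) == 1
        h = hs[0]
        assert h.start <= 1_000_000 and h.end >= 1_004_000
        assert h.peak_rate == pytest.approx(20.0)
        assert h.background_rate == pytest.approx(1.0)

    def test_flat_map_yields_nothing(self, flat_map):
        assert call_hotspots(flat_map) == []

    def test_flank_must_exceed_max_width(self):
        with pytest.raises(ParameterError):
            HotspotCallerParams(flank=10_000, max_width=20_000)

    def test_width_limits_respected(self):
        # 50 kb-wide elevation exceeds max_width and must be dropped
        m = make_map_with_bumps(2_000_000, [(500_000, 550_000, 19.0)])
        assert call_hotspots(m, HotspotCallerParams(flank=100_000)) == []

    def test_merge_gap(self):
        bumps = [(1_000_000, 1_002_000, 19.0), (1_002_300, 1_004_000, 19.0)]
        m = make_map_with_bumps(2_000_000, bumps)
        hs = call_hotspots(m, HotspotCallerParams(merge_gap=500))
        assert len(hs) == 1

    def test_outputs_disjoint_and_fold_satisfied(self):
        bumps = [(i * 200_000 + 50_000, i * 200_000 + 53_000, 9.0) for i in range(8)]
        m = make_map_with_bumps(2_000_000, bumps)
        params = HotspotCallerParams(fold=5.0)
        hs = call_hotspots(m, params)
        assert len(hs) == 8
        for a, b in itertools.combinations(hs, 2):
            assert a.end <= b.start or b.end <= a.start
        for h in hs:
            assert h.peak_rate >= params.fold * h.background_rate


class TestClassifyStrength:
    def test_tertile_split(self):
        hs = [hotspot("chr1", i * 10, i * 10 + 5, peak=p)
              for i, p in enumerate([1, 2, 3, 10, 20, 30, 100, 200, 300])]
        classified = classify_strength(hs)
        counts = {c: sum(h.strength_class == c for h in classified)
                  for c in ("weak", "intermediate", "strong")}
        assert counts == {"weak": 3, "intermediate": 3, "strong": 3}

    def test_all_equal_peaks_all_lowest_class(self):
        hs = [hotspot("chr1", i * 10, i * 10 + 5, peak=7.0) for i in range(5)]
        assert all(h.strength_class == "weak" for h in classify_strength(hs))

    def test_explicit_cutpoints(self):
        hs = [hotspot("chr1", i * 10, i * 10 + 5, peak=p)
              for i, p in enumerate([1, 10, 100])]
        classified = classify_strength(hs, cutpoints=(5, 50))
        assert [h.strength_class for h in classified] == [
            "weak", "intermediate", "strong"
        ]


# ---------------------------------------------------------------------------
# Lorenz / Gini
# ---------------------------------------------------------------------------

class TestLorenz:
    def test_uniform_map_diagonal(self, flat_map):
        x, y, gini = lorenz_curve(flat_map)
        np.testing.assert_allclose(x, y)
        assert gini == pytest.approx(0.0, abs=1e-12)

    def test_extreme_concentration(self):
        # all recombination in 1% of the sequence
        m = GeneticMap(
            "chr1", np.array([1, 10_001, 1_000_001]), np.array([100.0, 0.0])
        )
        x, y, gini = lorenz_curve(m)
        i = np.searchsorted(x, 0.01)
        assert y[i] == pytest.approx(1.0)
        assert gini == pytest.approx(0.99, abs=1e-9)

    def test_two_interval_hand_computation(self):
        # 90% of cM in 10% of bp: 81 cM/Mb over 100 kb, 1 cM/Mb over 900 kb
        m = GeneticMap(
            "chr1", np.array([1, 100_001, 1_000_001]), np.array([81.0, 1.0])
        )
        x, y, gini = lorenz_curve(m)
        assert x[1] == pytest.approx(0.1)
        assert y[1] == pytest.approx(0.9)
        # trapezoid area: 0.1*0.45 + 0.9*0.95 = 0.9 -> gini 0.8
        assert gini == pytest.approx(0.8)

    def test_zero_map_is_error(self):
        m = GeneticMap("chr1", np.array([1, 1001]), np.array([0.0]))
        with pytest.raises(EmptyInputError):
            lorenz_curve(m)

    def test_monotone_curve(self, rng):
        m = GeneticMap(
            "chr1",
            np.cumsum(rng.integers(100, 5000, 50)).astype(np.int64),
            rng.random(49) * 10,
        )
        x, y, _ = lorenz_curve(m)
        assert np.all(np.diff(x) >= 0)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all(y >= x - 1e-12)  # concave from above

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_gini_scale_invariant(self, scale):
        boundaries = np.array([1, 1000, 5000, 20_000, 100_000])
        rates = np.array([5.0, 0.5, 12.0, 1.0])
        _, _, g1 = lorenz_curve(GeneticMap("c", boundaries, rates))
        _, _, g2 = lorenz_curve(GeneticMap("c", boundaries, rates * scale))
        assert g1 == pytest.approx(g2, rel=1e-9)


# ---------------------------------------------------------------------------
# randomization test
# ---------------------------------------------------------------------------

class TestOverlapRandomization:
    def test_identical_sparse_sets_minimal_p(self):
        ivs = intervals("a", [("chr1", i * 1_000_000, i * 1_000_000 + 100)
                              for i in range(5)])
        observed, p = overlap_randomization_test(
            ivs, ivs, {"chr1": 100_000_000}, n_rand=999, seed=0
        )
        assert observed == 5
        assert p == pytest.approx(1 / 1000)

    def test_empty_set_a(self):
        a = IntervalSet([], label="a")
        b = intervals("b", [("chr1", 10, 20)])
        observed, p = overlap_randomization_test(a, b, {"chr1": 100}, n_rand=99)
        assert observed == 0
        assert p == 1.0

    def test_interval_wider_than_chromosome_errors(self):
        a = intervals("a", [("chr1", 0, 50)])
        b = intervals("b", [("chr1", 0, 10)])
        with pytest.raises(ParameterError):
            overlap_randomization_test(a, b, {"chr1": 30}, n_rand=9)

    def test_exhaustive_enumeration_oracle(self):
        """On a 10-position chromosome the null distribution is enumerable."""
        length = 10
        a = intervals("a", [("chr1", 5, 8)])   # width 3, overlaps b
        b = intervals("b", [("chr1", 6, 8)])
        observed = a.count_overlapping(b)
        assert observed == 1
        # enumerate all placements of the width-3 interval: starts 0..7
        overlaps = [
            1 if (s < 8 and 6 < s + 3) else 0 for s in range(length - 3 + 1)
        ]
        exact = sum(o >= observed for o in overlaps) / len(overlaps)
        assert exact == 0.5  # hand check of the oracle itself
        n_rand = 4000
        _, p = overlap_randomization_test(
            a, b, {"chr1": length}, n_rand=n_rand, seed=7
        )
        se = np.sqrt(exact * (1 - exact) / n_rand)
        assert abs(p - (exact * n_rand + 1) / (n_rand + 1)) < 4 * se

    def test_certain_overlap_exact(self):
        # set B covers the whole chromosome: every placement overlaps
        a = intervals("a", [("chr1", 2, 5)])
        b = intervals("b", [("chr1", 0, 10)])
        observed, p = overlap_randomization_test(a, b, {"chr1": 10}, n_rand=99, seed=0)
        assert observed == 1
        assert p == 1.0


# ---------------------------------------------------------------------------
# peak-set comparison / confirmation
# ---------------------------------------------------------------------------

class TestComparePeaks:
    def test_disjoint_sets_fully_unique(self):
        p = intervals("p", [("chr1", 0, 10), ("chr1", 100, 110)])
        q = intervals("q", [("chr1", 50, 60)])
        res = compare_peak_sets(p, q)
        assert res.pct_unique_p == 100
        assert res.pct_unique_q == 100
        assert res.shared_pairs == 0

    def test_shared_count_symmetric(self, rng):
        def random_set(label, n):
            starts = rng.integers(0, 100_000, n)
            return IntervalSet(
                (Interval("chr1", int(s), int(s) + int(rng.integers(50, 500)))
                 for s in starts),
                label=label,
            )

        p, q = random_set("p", 200), random_set("q", 150)
        assert compare_peak_sets(p, q).shared_pairs == compare_peak_sets(q, p).shared_pairs

    def test_pair_count_matches_quadratic_oracle(self, rng):
        p = IntervalSet(
            (Interval("chr1", int(s), int(s) + 80) for s in rng.integers(0, 20_000, 60)),
            label="p",
        )
        q = IntervalSet(
            (Interval("chr1", int(s), int(s) + 120) for s in rng.integers(0, 20_000, 40)),
            label="q",
        )
        brute = sum(a.overlaps(b) for a in p for b in q)
        assert compare_peak_sets(p, q).shared_pairs == brute

    def test_reported_unique_percentages(self):
        """Engineered counts: 8,721 of 28,349 unique -> 31%; 13,613 of 32,830 -> 41%."""
        n_p, uniq_p = 28_349, 8_721
        n_q, uniq_q = 32_830, 13_613
        shared_p = n_p - uniq_p  # 19,628 p-peaks hit q
        shared_q = n_q - uniq_q  # 19,217 q-peaks hit p
        ivs_p, ivs_q = [], []
        step = 1000
        # one wide q peak per slot; the first (shared_p - shared_q) slots get
        # a second, disjoint p peak so more p-peaks than q-peaks are shared
        for i in range(shared_q):
            ivs_q.append(Interval("chr1", i * step, i * step + 200))
            ivs_p.append(Interval("chr1", i * step, i * step + 80))
        for i in range(shared_p - shared_q):
            ivs_p.append(Interval("chr1", i * step + 100, i * step + 180))
        base = (shared_q + 1) * step
        for i in range(uniq_p):
            ivs_p.append(Interval("chr1", base + i * step, base + i * step + 100))
        base2 = base + (uniq_p + 1) * step
        for i in range(uniq_q):
            ivs_q.append(Interval("chr1", base2 + i * step, base2 + i * step + 100))
        res = compare_peak_sets(IntervalSet(ivs_p, "p"), IntervalSet(ivs_q, "q"))
        assert (res.n_p, res.unique_p, res.pct_unique_p) == (n_p, uniq_p, 31)
        assert (res.n_q, res.unique_q, res.pct_unique_q) == (n_q, uniq_q, 41)


class TestConfirmHotspots:
    def test_reported_fraction(self):
        """1,090 of 4,074 foreign hotspots overlapping -> 27%."""
        ours = [hotspot("chr1", i * 1000, i * 1000 + 200) for i in range(1090)]
        theirs = [Interval("chr1", i * 1000 + 50, i * 1000 + 150) for i in range(1090)]
        far = 10_000_000
        theirs += [Interval("chr1", far + i * 1000, far + i * 1000 + 100)
                   for i in range(4074 - 1090)]
        n, frac, pct = confirm_hotspots(ours, IntervalSet(theirs, "theirs"))
        assert n == 1090
        assert frac == pytest.approx(1090 / 4074)
        assert pct == 27

    def test_subset_is_fully_confirmed(self):
        ours = [hotspot("chr1", 0, 10_000)]
        theirs = intervals("t", [("chr1", 100, 200), ("chr1", 5_000, 5_100)])
        n, frac, pct = confirm_hotspots(ours, theirs)
        assert (n, frac, pct) == (2, 1.0, 100)

    def test_empty_foreign_set_errors(self):
        with pytest.raises(EmptyInputError):
            confirm_hotspots([hotspot("chr1", 0, 100)], IntervalSet([], "t"))

    def test_matches_quadratic_oracle(self, rng):
        ours = [
            hotspot("chr1", int(s), int(s) + int(rng.integers(100, 2000)))
            for s in rng.integers(0, 500_000, 100)
        ]
        theirs = IntervalSet(
            (Interval("chr1", int(s), int(s) + 500)
             for s in rng.integers(0, 500_000, 100)),
            label="theirs",
        )
        ours_ivs = hotspots_to_intervals(ours)
        brute = sum(any(t.overlaps(o) for o in ours_ivs) for t in theirs)
        n, frac, _ = confirm_hotspots(ours, theirs)
        assert n == brute
        assert frac == pytest.approx(brute / len(theirs))
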