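import numpy as np
import pytest

from locifold import locus_stats as ls
from locifold.contact_core import balance_ice, expected_by_distance

from helpers import make_matrix, random_matrix


class TestContactFrequencyCurve:
    def test_single_separation_concentrates_one_bin(self):
        m = make_matrix(60, [(i, i + 10, 3.0) for i in range(40)])  # sep 20 kb
        curve = ls.contact_frequency_curve(m, 4_000, 100_000)
        hot = np.argmax(curve.fractions)
        assert curve.edges_bp[hot] <= 20_000 < curve.edges_bp[hot + 1]
        assert curve.fractions[hot] == pytest.approx(1.0)

    def test_matches_brute_force_histogram(self, rng):
        m = random_matrix(80, rng)
        min_d, max_d = 4_000, 150_000
        curve = ls.contact_frequency_curve(m, min_d, max_d)
        # oracle: direct per-pixel binning
        totals = np.zeros(len(curve.fractions))
        for i, j, c in m.pixels.itertuples(index=False):
            s = (j - i) * 2000
            if min_d <= s <= max_d:
                k = min(int((np.log10(s) - np.log10(min_d)) / 0.1), len(totals) - 1)
                totals[k] += c
        np.testing.assert_allclose(curve.fractions, totals / totals.sum())

    def test_fractions_sum_to_one(self, rng):
        m = random_matrix(100, rng)
        curve = ls.contact_frequency_curve(m, 2_000, 200_000)
        assert curve.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_uniform_scaling(self, rng):
        m = random_matrix(50, rng)
        scaled = make_matrix(50, [(i, j, c * 7.5) for i, j, c in
                                  m.pixels.itertuples(index=False)])
        c1 = ls.contact_frequency_curve(m, 4_000, 90_000)
        c2 = ls.contact_frequency_curve(scaled, 4_000, 90_000)
        np.testing.assert_allclose(c1.fractions, c2.fractions)


class TestCurveSlope:
    def test_powerlaw_gives_constant_slope(self):
        # per-pair contact frequency proportional to 1/separation
        n = 300
        pixels = [(i, j, 1000.0 / (j - i)) for i in range(n) for j in range(i + 1, n)]
        m = make_matrix(n, pixels)
        curve = ls.contact_frequency_curve(m, 4_000, 400_000)
        slope = ls.curve_slope(curve)
        assert abs(np.nanmean(slope) - (-1.0)) < 0.05

    def test_monotone_decreasing_curve_nonpositive_slopes(self):
        n = 200
        pixels = [(i, j, 100.0 / (j - i) ** 1.5) for i in range(n) for j in range(i + 1, n)]
        m = make_matrix(n, pixels)
        slope = ls.curve_slope(ls.contact_frequency_curve(m, 4_000, 300_000))
        assert np.all(slope[np.isfinite(slope)] <= 0)

    def test_too_few_bins_errors(self):
        m = make_matrix(30, [(0, 10, 5.0)])
        curve = ls.contact_frequency_curve(m, 10_000, 40_000)
        with pytest.raises(ValueError, match="nonzero"):
            ls.curve_slope(curve)


class TestDifferentialMap:
    def test_identity_is_zero(self, rng):
        m = random_matrix(30, rng)
        out = ls.differential_map(m, m)
        assert np.nanmax(np.abs(out)) == 0

    def test_uniform_doubling_without_depth_match(self):
        pixels = [(i, j, 4.0) for i in range(10) for j in range(i, 10)]
        a = make_matrix(10, [(i, j, 8.0) for i, j, _ in pixels])
        b = make_matrix(10, pixels)
        out = ls.differential_map(a, b, pseudocount=0.0, depth_match=False)
        np.testing.assert_allclose(out, 1.0)

    def test_three_bin_hand_computation(self):
        a = make_matrix(3, [(0, 1, 6.0), (1, 2, 2.0)])
        b = make_matrix(3, [(0, 1, 2.0), (1, 2, 2.0)])
        out = ls.differential_map(a, b, pseudocount=1.0, depth_match=False)
        assert out[0, 1] == pytest.approx(np.log2(7 / 3))
        assert out[1, 2] == pytest.approx(np.log2(3 / 3))
        assert out[0, 2] == pytest.approx(0.0)  # log2(p/p)

    def test_depth_match_scales_to_equal_totals(self):
        a = make_matrix(3, [(0, 1, 10.0)])
        b = make_matrix(3, [(0, 1, 40.0)])
        out = ls.differential_map(a, b, pseudocount=0.0)
        assert out[0, 1] == pytest.approx(0.0)

    def test_bin_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="bin"):
            ls.differential_map(random_matrix(10, rng), random_matrix(12, rng))


class TestStripeProfile:
    def test_uniform_stripe_flat_track(self):
        pixels = [(5, j, 4.0) for j in range(10, 40)]
        m = make_matrix(50, pixels)
        track = ls.stripe_profile(m, (10_000, 12_000), (20_000, 80_000), mode="raw")
        np.testing.assert_allclose(track.values, 4.0)

    def test_zero_matrix_zero_track(self):
        m = make_matrix(50, [(0, 0, 0.0)])
        track = ls.stripe_profile(m, (10_000, 12_000), (20_000, 80_000), mode="raw")
        np.testing.assert_allclose(track.values, 0.0)

    def test_fully_masked_anchor_errors(self):
        w = np.ones(50)
        w[5] = np.nan
        m = make_matrix(50, [(5, 20, 3.0)], weights=w)
        with pytest.raises(ValueError, match="masked"):
            ls.stripe_profile(m, (10_000, 12_000), (20_000, 80_000))


def checkerboard(n=40, block=5, hi=20.0, lo=1.0, decay=0.05):
    """Two alternating bin classes with preferential same-class contact and
    mild distance decay; the constructed compartment oracle."""
    pixels = []
    for i in range(n):
        for j in range(i, n):
            same = ((i // block) % 2) == ((j // block) % 2)
            base = hi if same else lo
            pixels.append((i, j, base * np.exp(-decay * (j - i)) + 0.1))
    return make_matrix(n, pixels)


class TestCompartments:
    def test_checkerboard_sign_alternates_with_blocks(self):
        m = checkerboard()
        phase = np.array([1.0 if (i // 5) % 2 == 0 else -1.0 for i in range(40)])
        track = ls.compartment_eigenvector(m, phase)
        signs = np.sign(track.values)
        expected = np.array([1 if (i // 5) % 2 == 0 else -1 for i in range(40)])
        assert (signs == expected).mean() > 0.9

    def test_antialigned_phasing_flips_sign(self):
        m = checkerboard()
        phase = np.array([1.0 if (i // 5) % 2 == 0 else -1.0 for i in range(40)])
        t1 = ls.compartment_eigenvector(m, phase)
        t2 = ls.compartment_eigenvector(m, -phase)
        np.testing.assert_allclose(t1.values, -t2.values, atol=1e-12)

    def test_uniform_matrix_degenerate(self):
        pixels = [(i, j, 5.0) for i in range(25) for j in range(i, 25)]
        m = make_matrix(25, pixels)
        with pytest.raises(ValueError, match="degenerate"):
            ls.compartment_eigenvector(m, np.ones(25))

    def test_strength_above_one_on_checkerboard_and_one_under_permutation(self, rng):
        m = checkerboard()
        phase = np.array([1.0 if (i // 5) % 2 == 0 else -1.0 for i in range(40)])
        track = ls.compartment_eigenvector(m, phase)
        saddle, strength = ls.compartment_strength(m, track, n_quantiles=10)
        assert strength > 1.5
        np.testing.assert_allclose(saddle, saddle.T, atol=1e-9)
        # permutation null ~ 1
        vals = []
        for _ in range(30):
            shuffled = ls.CompartmentTrack(rng.permutation(track.values), track.eigenvalue)
            _, s = ls.compartment_strength(m, shuffled, n_quantiles=10)
            vals.append(s)
        assert abs(np.mean(vals) - 1.0) < 0.1

    def test_too_many_quantiles_errors(self):
        m = checkerboard()
        track = ls.compartment_eigenvector(
            m, np.array([1.0 if (i // 5) % 2 == 0 else -1.0 for i in range(40)]))
        with pytest.raises(ValueError, match="quantiles"):
            ls.compartment_strength(m, track, n_quantiles=100)


class TestLoopCalling:
    def _decay_background(self, n=80, seed=5):
        rng = np.random.default_rng(seed)
        pixels = []
        for i in range(n):
            for j in range(i, n):
                lam = 50.0 / (1 + (j - i))
                c = rng.poisson(lam * 4) / 4
                if c:
                    pixels.append((i, j, float(c)))
        return pixels

    def test_planted_pixel_is_the_only_call(self):
        pixels = [p for p in self._decay_background() if (p[0], p[1]) != (20, 60)]
        pixels.append((20, 60, 120.0))
        m = balance_ice(make_matrix(80, pixels))
        calls = ls.call_loops_simple(m, window=5, min_enrichment=3.0,
                                     min_separation=20_000, balanced=True)
        assert len(calls) == 1
        assert (calls[0].a1_start // 2000, calls[0].a2_start // 2000) == (20, 60)

    def test_smooth_background_no_calls(self):
        m = balance_ice(make_matrix(80, self._decay_background()))
        calls = ls.call_loops_simple(m, window=5, min_enrichment=3.0,
                                     min_separation=20_000, balanced=True)
        assert calls == []

    def test_frozen_cohesins_recovered_as_loops(self):
        from locifold import extrusion_sim as es
        from locifold.contact_core import GenomicBins

        bins = GenomicBins.from_region("chrT", 0, 200 * 2000, 2000)
        spec = es.SyntheticMapSpec(transitive_depth=0, background_fraction=0.5, seed=9)
        s = es.SimState()
        for l, r in [(20, 70), (100, 160)]:
            s.left.append(l); s.right.append(r)
            s.left_cap.append(False); s.right_cap.append(False)
        m = es.snapshots_to_contact_map([s] * 400, spec, bins)
        calls = ls.call_loops_simple(m, window=5, min_enrichment=3.0,
                                     min_separation=30_000)
        found = {(c.a1_start // 2000, c.a2_start // 2000) for c in calls}
        assert {(20, 70), (100, 160)} <= found


class TestLoopOverlap:
    def _loop(self, a, b, width=10_000):
        return ls.LoopCall("chr1", a, a + width, b, b + width, 1.0)

    def test_identical_lists_all_common(self):
        A = [self._loop(0, 100_000), self._loop(50_000, 300_000)]
        part = ls.loop_overlap(A, list(A))
        assert len(part["common_a"]) == 2 and not part["unique_a"] and not part["unique_b"]

    def test_shift_beyond_ten_percent_is_unique(self):
        A = [self._loop(0, 100_000)]
        B = [self._loop(2_000, 102_000)]   # 20% of the 10-kb anchor width
        part = ls.loop_overlap(A, B, min_reciprocal=0.9)
        assert part["unique_a"] == A and part["unique_b"] == B

    def test_partition_matches_brute_force(self, rng):
        def rand_loops(seed, k=12):
            r = np.random.default_rng(seed)
            out = []
            for _ in range(k):
                a = int(r.integers(0, 50)) * 5_000
                b = a + 50_000 + int(r.integers(0, 40)) * 5_000
                out.append(self._loop(a, b))
            return out

        A, B = rand_loops(1), rand_loops(2)
        part = ls.loop_overlap(A, B, min_reciprocal=0.9)

        def reciprocal(x0, x1, y0, y1):
            ov = min(x1, y1) - max(x0, y0)
            return ov > 0 and ov >= 0.9 * (x1 - x0) and ov >= 0.9 * (y1 - y0)

        used = set()
        expect_common = 0
        for la in A:
            for k, lb in enumerate(B):
                if k in used:
                    continue
                if reciprocal(la.a1_start, la.a1_end, lb.a1_start, lb.a1_end) and \
                        reciprocal(la.a2_start, la.a2_end, lb.a2_start, lb.a2_end):
                    used.add(k)
                    expect_common += 1
                    break
        assert len(part["common_a"]) == expect_common


class TestLoopLengthStats:
    def test_median_of_three(self):
        loops = [ls.LoopCall("c", 0, 2000, d, d + 2000, 1.0)
                 for d in (100_000, 200_000, 300_000)]
        stats = ls.loop_length_stats(loops)
        assert stats["median"] == 200_000
        assert stats["count"] == 3

    def test_single_loop_median_is_its_length(self):
        loop = ls.LoopCall("c", 0, 2000, 150_000, 152_000, 1.0)
        assert ls.loop_length_stats([loop])["median"] == loop.length

    def test_empty_flagged(self):
        with pytest.warns(UserWarning, match="empty"):
            stats = ls.loop_length_stats([])
        assert stats["count"] == 0 and np.isnan(stats["median"])
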