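import dataclasses

import numpy as np
import pytest

from locifold import extrusion_sim as es
from locifold.contact_core import GenomicBins


def params(n_bins=200, **kw):
    defaults = dict(n_bins=n_bins, bin_size=2000, loading_rate=0.1,
                    extrusion_speed=1, unload_prob_ref=0.02, wapl_level=1.0,
                    ctcf_stabilization=0.5, pool_size=None)
    defaults.update(kw)
    return es.ExtrusionParams(**defaults)


def run_steps(state, p, barriers, rng, n):
    for _ in range(n):
        state = es.step_state(state, p, barriers, rng)
    return state


def seeded(seed=0):
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))


def load_one(state, left, right):
    state.left.append(left)
    state.right.append(right)
    state.left_cap.append(False)
    state.right_cap.append(False)
    state.occupied.update((left, right))
    return state


class TestStepState:
    def test_convergent_barriers_capture_both_legs(self):
        """Deterministic limit: one immortal cohesin between two convergent
        barriers ends with both legs captured exactly at the barrier bins."""
        p = params(loading_rate=0.0, unload_prob_ref=1e-9)
        barriers = es.BarrierSet([es.Barrier(50, "+", 1.0, 0.0),
                                  es.Barrier(150, "-", 1.0, 0.0)])
        state = load_one(es.SimState(), 99, 100)
        state = run_steps(state, p, barriers, seeded(), 200)
        assert state.left == [50] and state.right == [150]
        assert state.left_cap == [True] and state.right_cap == [True]

    def test_inner_legs_block_at_adjacency(self):
        """Two nested cohesins: the outer pair's inner legs stop next to the
        inner cohesin's legs, forming a 2-chain."""
        p = params(loading_rate=0.0, unload_prob_ref=1e-9)
        barriers = es.BarrierSet([])
        state = load_one(load_one(es.SimState(), 100, 101), 95, 106)
        state = run_steps(state, p, barriers, seeded(), 250)
        # outer cohesin stops at the lattice edges; the inner one blocks at
        # one-bin adjacency inside it
        assert state.left == [1, 0] and state.right == [198, 199]
        chains = es.collision_chains(state)
        assert sorted(map(len, chains)) == [2]

    def test_legs_never_cross_or_collide(self):
        p = params(loading_rate=0.3, unload_prob_ref=0.05, extrusion_speed=2)
        barriers = es.BarrierSet([es.Barrier(60, "+", 0.8, 0.01),
                                  es.Barrier(140, "-", 0.8, 0.01)])
        rng = seeded(3)
        state = es.SimState()
        for _ in range(500):
            state = es.step_state(state, p, barriers, rng)
            state.check_invariants()

    def test_steady_state_count_matches_birth_death_balance(self):
        """Barrier-free occupancy: long-run mean cohesin number ~ lambda/u."""
        lam, u = 0.2, 0.02
        p = params(n_bins=2000, loading_rate=lam, unload_prob_ref=u)
        rng = seeded(7)
        state = es.SimState()
        state = run_steps(state, p, es.BarrierSet([]), rng, 1000)  # burn-in
        counts = []
        for _ in range(10_000):
            state = es.step_state(state, p, es.BarrierSet([]), rng)
            counts.append(state.n_cohesins)
        mean = np.mean(counts)
        expect = lam / u
        # 3 SE with a conservative effective sample size (autocorrelated chain)
        se = np.std(counts) / np.sqrt(len(counts) / (2 / u))
        assert abs(mean - expect) < 3 * se + 0.5


class TestEnsemble:
    def test_same_seed_identical_snapshots(self):
        p = params()
        b = es.BarrierSet([es.Barrier(100, "+", 0.9, 0.01)])
        spec = es.SyntheticMapSpec(n_snapshots=20, burn_in=50, stride=5, seed=5)
        s1 = es.run_ensemble(p, b, spec)
        s2 = es.run_ensemble(p, b, spec)
        assert all(a.left == c.left and a.right == c.right for a, c in zip(s1, s2))

    def test_zero_loading_all_snapshots_empty(self):
        p = params(loading_rate=0.0)
        spec = es.SyntheticMapSpec(n_snapshots=10, burn_in=10, stride=2, seed=1)
        snaps = es.run_ensemble(p, es.BarrierSet([]), spec)
        assert all(s.n_cohesins == 0 for s in snaps)

    def test_snapshot_lengths_match_long_run_time_average(self):
        """Ergodicity: strided snapshots reproduce the time-averaged
        loop-length distribution of an independent long run."""
        p = params(n_bins=500, loading_rate=0.1, unload_prob_ref=0.02)
        spec = es.SyntheticMapSpec(n_snapshots=400, burn_in=500, stride=10, seed=2)
        snaps = es.run_ensemble(p, es.BarrierSet([]), spec)
        med_snap = np.median(es.loop_length_distribution(snaps, 2000))
        # independent continuous run, different seed
        rng = seeded(77)
        state = run_steps(es.SimState(), p, es.BarrierSet([]), rng, 500)
        lengths = []
        for _ in range(4000):
            state = es.step_state(state, p, es.BarrierSet([]), rng)
            lengths.extend((r - l) * 2000 for l, r in zip(state.left, state.right))
        med_run = np.median(lengths)
        assert abs(med_snap - med_run) / med_run < 0.25

    def test_max_cohesins_exceeded_raises(self):
        p = params(loading_rate=5.0, unload_prob_ref=1e-6, max_cohesins=10)
        spec = es.SyntheticMapSpec(n_snapshots=5, burn_in=100, stride=2, seed=1)
        with pytest.raises(RuntimeError, match="max_cohesins"):
            es.run_ensemble(p, es.BarrierSet([]), spec)


class TestContactMap:
    def setup_method(self):
        self.bins = GenomicBins.from_region("chrT", 0, 200 * 2000, 2000)

    def frozen(self, positions):
        s = es.SimState()
        for l, r in positions:
            load_one(s, l, r)
        return s

    def test_frozen_cohesin_one_pixel_per_snapshot(self):
        spec = es.SyntheticMapSpec(transitive_depth=0, background_fraction=0.0, seed=0)
        snaps = [self.frozen([(10, 50)])] * 100
        m = es.snapshots_to_contact_map(snaps, spec, self.bins)
        assert len(m.pixels) == 1
        row = m.pixels.iloc[0]
        assert (row.bin1_id, row.bin2_id, row["count"]) == (10, 50, 100.0)

    def test_three_chain_bridges_outermost_legs(self):
        """A frozen 3-chain yields a transitive pixel between the outermost
        legs with weight w^2 per snapshot (hand-enumerated bridging)."""
        w = 0.5
        spec = es.SyntheticMapSpec(transitive_depth=2, transitive_weight=w,
                                   background_fraction=0.0, seed=0)
        # legs: (10,40),(41,70),(71,100): adjacent -> chain of 3
        snaps = [self.frozen([(10, 40), (41, 70), (71, 100)])] * 50
        m = es.snapshots_to_contact_map(snaps, spec, self.bins)
        dense = m.to_dense()
        assert dense[10, 100] == pytest.approx(w ** 2 * 50)
        assert dense[10, 70] == pytest.approx(w * 50)      # depth-1 bridge
        assert dense[10, 40] == pytest.approx(50)          # direct loop base

    def test_chain_depth_zero_no_bridges(self):
        spec = es.SyntheticMapSpec(transitive_depth=0, background_fraction=0.0, seed=0)
        snaps = [self.frozen([(10, 40), (41, 70)])] * 10
        m = es.snapshots_to_contact_map(snaps, spec, self.bins)
        assert len(m.pixels) == 2

    def test_background_only_powerlaw_slope(self):
        """Empirical P(s) of a background-only map has log-log slope ~ -alpha."""
        from locifold.locus_stats import contact_frequency_curve, curve_slope

        bins = GenomicBins.from_region("chrT", 0, 1000 * 2000, 2000)
        spec = es.SyntheticMapSpec(transitive_depth=0, background_exponent=1.0,
                                   background_fraction=0.999, seed=4)
        # a single immortal tiny cohesin supplies the signal scale; the map is
        # then ~1000x background
        snaps = [self.frozen([(0, 1)])] * 3000
        m = es.snapshots_to_contact_map(snaps, spec, bins)
        curve = contact_frequency_curve(m, 20_000, 1_500_000)
        slope = curve_slope(curve)
        assert abs(np.nanmean(slope) - (-1.0)) < 0.1


class TestPresets:
    def test_igh_full_has_125_forward_barriers(self):
        bins, barriers, truth = es.make_locus_preset("igh_like", "full")
        fwd = [b for b in barriers if b.orientation == "+"]
        rev = [b for b in barriers if b.orientation == "-"]
        assert len(fwd) == 125
        assert len(rev) == 4
        assert max(b.position for b in fwd) < min(b.position for b in rev)

    def test_igk_desk_has_17plus_mixed_internal_barriers(self):
        bins, barriers, truth = es.make_locus_preset("igk_like", "desk")
        internal = truth[truth.name.str.startswith("V_")]
        assert len(internal) >= 17
        assert set(internal.orientation) == {"+", "-"}
        # Cer-like reverse pair and Sis-like forward pair near the 3' end
        assert list(truth[truth.name.str.startswith("Cer")].orientation) == ["-", "-"]
        assert list(truth[truth.name.str.startswith("Sis")].orientation) == ["+", "+"]

    @pytest.mark.parametrize("kind", ["igh_like", "igk_like"])
    @pytest.mark.parametrize("scale", ["desk", "full"])
    def test_positions_strictly_increasing_inside_locus(self, kind, scale):
        bins, barriers, truth = es.make_locus_preset(kind, scale)
        pos = [b.position for b in barriers]
        assert all(a < b for a, b in zip(pos, pos[1:]))
        assert 0 <= pos[0] and pos[-1] < bins.n


class TestLoopLengths:
    def test_single_cohesin_length(self):
        s = es.SimState()
        load_one(s, 10, 50)
        lengths = es.loop_length_distribution([s], 2000)
        assert list(lengths) == [80_000.0]

    def test_median_decreases_when_unloading_doubles(self):
        """Residence halves -> loops shorten (5 paired seeds, dilute lattice)."""
        wins = 0
        for seed in range(5):
            meds = []
            for u in (0.01, 0.02):
                p = params(n_bins=1500, loading_rate=0.05, unload_prob_ref=u)
                spec = es.SyntheticMapSpec(n_snapshots=200, burn_in=400,
                                           stride=10, seed=seed)
                snaps = es.run_ensemble(p, es.BarrierSet([]), spec)
                meds.append(np.median(es.loop_length_distribution(snaps, 2000)))
            wins += meds[0] > meds[1]
        assert wins >= 4

    def test_no_cohesins_flagged_empty(self):
        with pytest.warns(UserWarning, match="no cohesins"):
            lengths = es.loop_length_distribution([es.SimState()], 2000)
        assert lengths.size == 0

    def test_immortal_convergent_limit_is_barrier_distance(self):
        p = params(loading_rate=0.0, unload_prob_ref=1e-9)
        barriers = es.BarrierSet([es.Barrier(40, "+", 1.0, 0.0),
                                  es.Barrier(160, "-", 1.0, 0.0)])
        state = load_one(es.SimState(), 99, 100)
        state = run_steps(state, p, barriers, seeded(), 300)
        assert np.median(es.loop_length_distribution([state], 2000)) == 120 * 2000
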