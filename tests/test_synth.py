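"""Synthetic-data generators: determinism, conservation, generative contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import avanet as an
from avanet.preprocess import ParameterError


class TestSimConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(n_rows=1, n_cols=1),
        dict(branching_ratio=-0.1),
        dict(drive_rate=1.5),
        dict(n_bins=0),
        dict(generations_per_bin=0),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            an.SimConfig(**kwargs)


class TestBranchingRaster:
    def test_same_seed_is_reproducible(self):
        cfg = an.SimConfig(n_bins=5000, seed=42)
        a = an.simulate_branching_raster(cfg)
        b = an.simulate_branching_raster(cfg)
        assert np.array_equal(a.counts, b.counts)

    def test_zero_branching_gives_singleton_avalanches(self):
        # drive so sparse that coincident drive events are essentially
        # impossible: every avalanche is one spontaneous event
        cfg = an.SimConfig(branching_ratio=0.0, drive_rate=2e-5,
                           n_bins=10_000, seed=3)
        raster = an.simulate_branching_raster(cfg)
        sizes = [a.size for a in an.segment_avalanches(raster)]
        assert len(sizes) > 5
        assert all(s == 1 for s in sizes)

    def test_mean_size_grows_with_branching_ratio(self):
        means = []
        for sigma in (0.3, 0.7, 1.0):
            vals = []
            for seed in range(3):
                cfg = an.SimConfig(branching_ratio=sigma, n_bins=20_000,
                                   seed=100 + seed)
                avs = an.segment_avalanches(an.simulate_branching_raster(cfg))
                vals.append(np.mean([a.size for a in avs]))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_supercritical_ratio_on_tiny_pool_rejected(self):
        with pytest.raises(ParameterError):
            an.simulate_branching_raster(
                an.SimConfig(n_rows=1, n_cols=2, branching_ratio=1.5))


class TestCascades:
    def test_deterministic_unit_link_chain(self):
        w = np.zeros((2, 2))
        w[0, 1] = 1.0
        net = an.GroundTruthNetwork(weights=w)
        r = an.simulate_cascades_on_network(net, drive_rate=0.01, n_bins=5000,
                                            seed=5, drive_nodes=[0])
        act = r.counts > 0
        # every activation of node 0 is followed by node 1 in the next bin
        fires = np.flatnonzero(act[0, :-1])
        assert fires.size > 10
        assert act[1, fires + 1].all()

    def test_zero_weights_leave_nodes_independent(self):
        net = an.GroundTruthNetwork(weights=np.zeros((5, 5)))
        r = an.simulate_cascades_on_network(net, drive_rate=0.02,
                                            n_bins=20_000, seed=6)
        act = r.counts > 0
        # transition frequency i->j matches j's unconditional rate: no coupling
        for i, j in [(0, 1), (2, 3), (4, 0)]:
            n_i = act[i, :-1].sum()
            freq = (act[i, :-1] & act[j, 1:]).sum() / n_i
            base = act[j].mean()
            sd = np.sqrt(base * (1 - base) / n_i)
            assert abs(freq - base) < 4 * sd + 1e-12

    def test_transition_frequencies_recover_weights(self):
        drive = 5e-3
        net = an.make_small_world_network(seed=3)
        r = an.simulate_cascades_on_network(net, drive_rate=drive,
                                            n_bins=100_000, seed=4)
        act = r.counts > 0
        # condition on frames where i is the ONLY active node, so the next
        # frame's activations can come only from i's links or from drive
        n_active = act.sum(axis=0)
        checked = 0
        for i in range(net.n_nodes):
            solo = np.flatnonzero(act[i, :-1] & (n_active[:-1] == 1))
            if solo.size < 200:
                continue
            for j in np.flatnonzero(net.weights[i])[:3]:
                w = net.weights[i, j]
                freq = act[j, solo + 1].mean()
                expect = w + (1 - w) * drive  # drive-corrected weight
                sd = np.sqrt(max(expect * (1 - expect), 1e-6) / solo.size)
                assert abs(freq - expect) < 4 * sd + 0.01
                checked += 1
        assert checked >= 10

    def test_invalid_weights_rejected(self):
        with pytest.raises(ParameterError):
            an.GroundTruthNetwork(weights=np.full((3, 3), 1.5))


class TestSyntheticSignal:
    def test_single_noiseless_event_detected_at_planted_time(self):
        counts = np.zeros((1, 100), dtype=int)
        counts[0, 50] = 1
        raster = an.EventRaster(counts=counts, dt_ms=1.0)
        sig = an.make_synthetic_signal(raster, kernel_depth_sd=5.0,
                                       noise_sd=0.0, fs_hz=2000, seed=0)
        # noiseless: detect on the raw signal directly (min at the bin center)
        trough = np.argmin(sig.data[0])
        assert abs(trough / 2000 * 1000 - 50.5) <= 1.0

    def test_planted_events_recovered_through_full_chain(self):
        rng = np.random.default_rng(7)
        counts = np.zeros((10, 60_000), dtype=int)
        idx = rng.choice(counts.size, 1000, replace=False)
        counts[np.unravel_index(idx, counts.shape)] = 1
        raster = an.EventRaster(counts=counts, dt_ms=1.0)
        sig = an.make_synthetic_signal(raster, kernel_depth_sd=4.0,
                                       noise_sd=1.0, fs_hz=2000, seed=8)
        z = an.ztransform(an.bandpass_and_notch(sig))
        ev = an.detect_nlfps(z)
        det = {(c, int(t)) for c, t in zip(ev.events.channel_id,
                                           ev.events.time_ms)}
        planted = list(zip(*np.nonzero(counts)))
        hits = sum(1 for (c, b) in planted
                   if any((c, b + d) in det for d in (-2, -1, 0, 1, 2)))
        assert hits / len(planted) >= 0.95

    def test_empty_raster_gives_only_noise_detections(self):
        raster = an.EventRaster(counts=np.zeros((5, 20_000), dtype=int),
                                dt_ms=1.0)
        sig = an.make_synthetic_signal(raster, kernel_depth_sd=4.0,
                                       noise_sd=1.0, fs_hz=2000, seed=9)
        z = an.ztransform(an.bandpass_and_notch(sig))
        n = len(an.detect_nlfps(z))
        # band-limited Gaussian noise crosses -2 SD at a low, nonzero rate
        assert 0 < n < 0.02 * sig.n_samples

    def test_shallow_kernel_rejected(self):
        raster = an.EventRaster(counts=np.zeros((2, 10), dtype=int), dt_ms=1.0)
        with pytest.raises(ParameterError):
            an.make_synthetic_signal(raster, kernel_depth_sd=1.5)

    def test_incompatible_sampling_rate_rejected(self):
        raster = an.EventRaster(counts=np.zeros((2, 10), dtype=int), dt_ms=1.0)
        with pytest.raises(ParameterError):
            an.make_synthetic_signal(raster, fs_hz=333.0)


class TestSessionSequence:
    def test_no_drift_keeps_networks_identical(self):
        net = an.make_small_world_network(seed=1)
        seq = an.generate_session_sequence(net, an.DriftModel(0.0, 0.0),
                                           n_days=4, per_day_bins=500, seed=2)
        for day_net, _ in seq:
            assert np.array_equal(day_net.weights, net.weights)

    def test_full_resampling_destroys_weight_ranks(self):
        net = an.make_small_world_network(seed=1)
        seq = an.generate_session_sequence(net, an.DriftModel(1.0, 0.0),
                                           n_days=3, per_day_bins=500, seed=2)
        m = net.weights > 0
        rho = stats.spearmanr(seq[0][0].weights[m], seq[1][0].weights[m]).statistic
        assert abs(rho) < 0.25

    def test_slow_drift_raises_mixing_entropy_progressively(self):
        net = an.make_small_world_network(seed=1)
        seq = an.generate_session_sequence(net, an.DriftModel(0.05, 0.0),
                                           n_days=8, per_day_bins=500, seed=2)
        graphs = [an.WeightedDigraph(weights=n.weights) for n, _ in seq]
        traj = an.mixing_trajectory(graphs, days=np.arange(1, 9),
                                    n_mc=10_000, seed=3)
        rho = stats.spearmanr(traj.day[1:], traj.h_m[1:]).statistic
        assert rho > 0.5
        assert traj.h_m[0] == 0.0

    def test_single_day_rejected(self):
        net = an.make_small_world_network(seed=1)
        with pytest.raises(ParameterError):
            an.generate_session_sequence(net, an.DriftModel(), n_days=1,
                                         per_day_bins=100, seed=0)


class TestShuffle:
    def test_per_electrode_counts_conserved_and_reproducible(self, critical_raster):
        a = an.shuffle_raster_times(critical_raster, seed=13)
        b = an.shuffle_raster_times(critical_raster, seed=13)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.counts.sum(axis=1),
                              critical_raster.counts.sum(axis=1))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_for_arbitrary_rasters(self, seed):
        r = np.random.default_rng(seed)
        counts = r.poisson(0.2, size=(4, 50))
        if counts.sum() == 0:
            counts[0, 0] = 1
        raster = an.EventRaster(counts=counts, dt_ms=1.0)
        out = an.shuffle_raster_times(raster, seed=seed)
        assert np.array_equal(out.counts.sum(axis=1), counts.sum(axis=1))

    def test_empty_raster_rejected(self):
        raster = an.EventRaster(counts=np.zeros((2, 5), dtype=int), dt_ms=1.0)
        with pytest.raises(ParameterError):
            an.shuffle_raster_times(raster)
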