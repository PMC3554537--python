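"""Burst detection, spatial statistics and network controls."""

import numpy as np
import pytest

from palisade import analysis
from palisade.analysis import (
    BurstCriteria,
    bin_raster,
    boundary_neurons,
    burst_rate,
    cross_covariance,
    detect_bursts,
    intra_burst_stats,
    sampling_region,
    sever_boundary_connections,
    spatial_rate_profile,
)
from palisade.netgen import LatticeConfig, build_lattice, build_network
from palisade.trauma_hsp import TraumaConfig, apply_trauma


class TestBinRaster:
    def test_empty_raster_all_zero(self):
        counts = bin_raster(np.empty(0), np.empty(0, int), 100.0, np.arange(5),
                            total_time_ms=1000.0)
        assert counts.shape == (5, 10) and counts.sum() == 0

    def test_edge_spike_goes_to_right_bin(self):
        counts = bin_raster(np.array([100.0]), np.array([0]), 100.0, np.arange(2),
                            total_time_ms=300.0)
        assert counts[0, 0] == 0 and counts[0, 1] == 1

    def test_spike_conservation(self, rng):
        times = rng.uniform(0, 5000, 400)
        ids = rng.integers(0, 10, 400)
        counts = bin_raster(times, ids, 100.0, np.arange(10), total_time_ms=5000.0)
        assert counts.sum() == 400

    def test_unrecorded_neurons_ignored(self):
        counts = bin_raster(np.array([10.0, 20.0]), np.array([0, 7]), 100.0,
                            np.array([0, 1]), total_time_ms=100.0)
        assert counts.sum() == 1


def brute_force_supra(counts, crit):
    """Independent per-bin re-evaluation of the burst criterion."""
    flags = []
    n_rec = counts.shape[0]
    for b in range(counts.shape[1]):
        col = counts[:, b]
        active = [c for c in col if c > 0]
        frac_ok = len(active) / n_rec >= crit.f_min
        rate_ok = len(active) > 0 and (sum(active) / len(active)) / (crit.bin_ms / 1000.0) > crit.r_min
        flags.append(frac_ok and rate_ok)
    return flags


class TestDetectBursts:
    def test_hand_computed_example(self):
        # 10 neurons; 6 fire 3 spikes each in one bin -> 30 Hz mean, 0.6 active
        counts = np.zeros((10, 5), dtype=int)
        counts[:6, 2] = 3
        ev = detect_bursts(counts, BurstCriteria(f_min=0.5, r_min=20.0))
        assert len(ev) == 1 and ev[0].start_bin == 2

    def test_insufficient_fraction_rejected(self):
        counts = np.zeros((10, 5), dtype=int)
        counts[:4, 2] = 3
        assert detect_bursts(counts, BurstCriteria(f_min=0.5, r_min=20.0)) == []

    def test_adjacent_bins_merge_into_one_event(self):
        counts = np.zeros((4, 10), dtype=int)
        counts[:, 3:6] = 3
        ev = detect_bursts(counts, BurstCriteria(f_min=0.5, r_min=20.0))
        assert len(ev) == 1
        assert (ev[0].start_bin, ev[0].end_bin) == (3, 5)

    def test_merge_disabled_counts_bins(self):
        counts = np.zeros((4, 10), dtype=int)
        counts[:, 3:6] = 3
        crit = BurstCriteria(f_min=0.5, r_min=20.0, merge_adjacent=False)
        assert len(detect_bursts(counts, crit)) == 3

    def test_oracle_equivalence_on_random_rasters(self):
        rng = np.random.default_rng(99)
        crit = BurstCriteria(f_min=0.4, r_min=15.0)
        for _ in range(1000):
            counts = rng.poisson(rng.uniform(0.1, 2.5), size=(6, 12))
            flags = brute_force_supra(counts, crit)
            ev = detect_bursts(counts, crit)
            # reconstruct merged runs from the brute-force flags
            runs = []
            b = 0
            while b < len(flags):
                if flags[b]:
                    start = b
                    while b + 1 < len(flags) and flags[b + 1]:
                        b += 1
                    runs.append((start, b))
                b += 1
            assert [(e.start_bin, e.end_bin) for e in ev] == runs


class TestBurstRate:
    def test_zero_events(self):
        assert burst_rate([], 10_000.0) == 0.0

    def test_thirty_events_in_100s(self):
        ev = [object()] * 30
        assert burst_rate(ev, 100_000.0) == pytest.approx(0.3)
        assert burst_rate(ev, 200_000.0) == pytest.approx(0.15)

    def test_zero_time_rejected(self):
        with pytest.raises(ValueError):
            burst_rate([], 0.0)


class TestIntraBurstStats:
    def test_two_spikes_per_participant(self):
        counts = np.zeros((10, 3), dtype=int)
        counts[:6, 1] = 2
        crit = BurstCriteria(f_min=0.5, r_min=15.0)
        ev = detect_bursts(counts, crit)
        stats = intra_burst_stats(ev, crit, np.arange(10), np.zeros(10, bool))
        assert stats["spikes_per_neuron_py"] == pytest.approx(2.0)
        assert stats["rate_per_neuron_py"] == pytest.approx(20.0)

    def test_silent_recorded_neurons_do_not_dilute(self):
        counts = np.zeros((10, 3), dtype=int)
        counts[:6, 1] = 4
        crit = BurstCriteria(f_min=0.5, r_min=15.0)
        ev = detect_bursts(counts, crit)
        stats = intra_burst_stats(ev, crit, np.arange(10), np.zeros(10, bool))
        assert stats["spikes_per_neuron_py"] == pytest.approx(4.0)

    def test_two_identical_bursts_same_mean_as_one(self):
        counts = np.zeros((10, 6), dtype=int)
        counts[:6, 1] = 3
        counts[:6, 4] = 3
        crit = BurstCriteria(f_min=0.5, r_min=15.0)
        ev = detect_bursts(counts, crit)
        assert len(ev) == 2
        stats = intra_burst_stats(ev, crit, np.arange(10), np.zeros(10, bool))
        assert stats["spikes_per_neuron_py"] == pytest.approx(3.0)

    def test_no_events_flagged_with_nans(self):
        crit = BurstCriteria()
        stats = intra_burst_stats([], crit, np.arange(4), np.zeros(4, bool))
        assert stats["n_bursts"] == 0
        assert np.isnan(stats["spikes_per_neuron_py"])

    def test_types_reported_separately(self):
        counts = np.zeros((10, 3), dtype=int)
        counts[:8, 1] = 2
        counts[8:, 1] = 6
        crit = BurstCriteria(f_min=0.5, r_min=15.0)
        ev = detect_bursts(counts, crit)
        is_inh = np.zeros(10, bool)
        is_inh[8:] = True
        stats = intra_burst_stats(ev, crit, np.arange(10), is_inh)
        assert stats["spikes_per_neuron_py"] == pytest.approx(2.0)
        assert stats["spikes_per_neuron_in"] == pytest.approx(6.0)


class TestCrossCovariance:
    def test_identical_trains_give_one_at_lag_zero(self, rng):
        x = rng.poisson(1.0, size=(1, 200))
        counts = np.vstack([x, x])
        lags, curve, used = cross_covariance(counts, [(0, 1)], max_lag=3)
        assert used == 1
        assert curve[lags == 0] == pytest.approx(1.0)

    def test_independent_poisson_near_zero(self, rng):
        counts = rng.poisson(1.0, size=(2, 400))
        lags, curve, _ = cross_covariance(counts, [(0, 1)], max_lag=2)
        assert abs(curve[lags == 0]) < 3 / np.sqrt(400)

    def test_shifted_copy_peaks_at_lag_one(self, rng):
        x = rng.poisson(2.0, size=500)
        counts = np.vstack([x, np.roll(x, 1)])
        lags, curve, _ = cross_covariance(counts, [(0, 1)], max_lag=3)
        assert lags[np.argmax(curve)] in (-1, 1)
        assert abs(lags[np.argmax(curve)]) == 1

    def test_zero_variance_pairs_skipped(self, rng):
        counts = np.vstack([np.zeros(100, int), rng.poisson(1.0, 100)])
        lags, curve, used = cross_covariance(counts, [(0, 1)], max_lag=2)
        assert used == 0 and np.isnan(curve).all()


class TestBoundary:
    def test_no_trauma_no_boundary(self, small_network):
        assert boundary_neurons(small_network, np.zeros(100, bool)).size == 0

    def test_slab_trauma_boundary_columns(self):
        # 10x10 lattice, left 5 columns deafferented, half=2, offsets [-2, 1]:
        # boundary deafferented sit in column 4; intact neurons whose footprint
        # reaches column 4 sit in columns 5 and 6
        net = build_lattice(LatticeConfig(side_length=10, footprint_half=2,
                                          p_exc=0.1, p_inh=0.1))
        deaff = net.coords[:, 1] < 5
        b = boundary_neurons(net, deaff)
        cols = np.unique(net.coords[b, 1])
        assert set(cols.tolist()) == {5, 6}

    def test_diffuse_matches_brute_force(self, small_network):
        from palisade.netgen import footprint_sites

        net = small_network
        deaff = apply_trauma(net, TraumaConfig(pattern="diffuse", f_d=0.15, seed=3))
        got = set(boundary_neurons(net, deaff).tolist())
        side, half = net.side, net.config.footprint_half
        # independent scan
        bd = set()
        for i in np.flatnonzero(deaff):
            sites = footprint_sites((i // side, i % side), half, side)
            if any(not deaff[r * side + c] for r, c in sites):
                bd.add(i)
        expected = set()
        for i in np.flatnonzero(~deaff):
            sites = footprint_sites((i // side, i % side), half, side)
            if any((r * side + c) in bd for r, c in sites):
                expected.add(i)
        assert got == expected


class TestSamplingRegion:
    def test_default_80_focal_is_400(self):
        net = build_lattice(LatticeConfig(side_length=80))
        assert sampling_region("focal", net).size == 400

    def test_default_80_diffuse_is_400(self):
        net = build_lattice(LatticeConfig(side_length=80))
        assert sampling_region("diffuse", net).size == 400

    def test_40_focal_is_200(self):
        net = build_lattice(LatticeConfig(side_length=40))
        assert sampling_region("focal", net).size == 200

    def test_region_exceeding_lattice_rejected(self):
        net = build_lattice(LatticeConfig(side_length=10))
        with pytest.raises(ValueError):
            sampling_region("diffuse", net, block=20)


class TestSpatialProfile:
    def test_homogeneous_poisson_profile_is_flat(self, rng):
        net = build_lattice(LatticeConfig(side_length=20))
        lam, T = 20.0, 20_000.0
        n_sp = rng.poisson(lam * T / 1000.0 * net.n_neurons)
        ids = rng.integers(0, net.n_neurons, n_sp)
        times = rng.uniform(0, T, n_sp)
        prof = spatial_rate_profile(times, ids, net, T, strip_half_width=5)
        assert prof.size == 20
        se = np.sqrt(lam / (T / 1000.0) / 8)  # ~8 PY per column cross-section
        assert np.nanmax(np.abs(prof - lam)) < 4 * se

    def test_profile_uses_py_only(self):
        net = build_lattice(LatticeConfig(side_length=10, footprint_half=2,
                                          p_exc=0.1, p_inh=0.1))
        # spikes only from IN neurons: profile must be zero
        ids = net.in_indices
        times = np.linspace(0, 999, ids.size)
        prof = spatial_rate_profile(times, ids, net, 1000.0, strip_half_width=5)
        assert np.nansum(prof) == 0


class TestSever:
    def test_no_trauma_removes_nothing(self, small_network):
        out = sever_boundary_connections(small_network, np.zeros(100, bool))
        assert out.n_synapses == small_network.n_synapses

    def test_removed_count_matches_brute_force(self, small_network):
        net = small_network
        deaff = apply_trauma(net, TraumaConfig(pattern="diffuse", f_d=0.3, seed=1))
        out = sever_boundary_connections(net, deaff)
        crossing = sum(
            1 for p, q in zip(net.pre, net.post) if deaff[p] != deaff[q]
        )
        assert net.n_synapses - out.n_synapses == crossing

    def test_no_crossing_edges_remain(self, small_network):
        deaff = apply_trauma(small_network, TraumaConfig(pattern="focal", f_d=0.4))
        out = sever_boundary_connections(small_network, deaff)
        assert (deaff[out.pre] == deaff[out.post]).all()


def test_rate_map_shape_and_mean(rng):
    net = build_lattice(LatticeConfig(side_length=10))
    ids = rng.integers(0, 100, 1000)
    m = analysis.rate_map(np.zeros(1000), ids, net, 10_000.0)
    assert m.shape == (10, 10)
    assert m.sum() == pytest.approx(100.0)  # 1000 spikes / 10 s
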