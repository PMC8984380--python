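"""ISI summaries, spike widths, wave packets and synchronization."""

from functools import lru_cache

import numpy as np
import pytest

from mycolingua import (
    ChannelTruth,
    DetectionParams,
    GroundTruth,
    Recording,
    SpikeEvent,
    ValidationError,
    detect_spikes,
    find_wave_packets,
    inject_wave_packet,
    isi_summary,
    packet_shape_score,
    prominence_trace,
    spike_width,
    synchronize,
)
from mycolingua.spike_characterization import WavePacket

from conftest import make_train


class TestIsiSummary:
    def test_regular_train(self):
        s = isi_summary(make_train([0, 60, 120]))
        assert s.n_spikes == 3
        assert s.mean_interval_min == pytest.approx(1.0)
        assert s.sd_interval_min == pytest.approx(0.0)

    def test_single_spike_has_no_interval_fields(self):
        s = isi_summary(make_train([42]))
        assert s.n_spikes == 1
        assert s.mean_interval_min is None and s.sd_interval_min is None
        assert s.mean_amplitude_mv == 1.0

    def test_empty_train(self):
        s = isi_summary(make_train([]))
        assert s.n_spikes == 0 and s.mean_amplitude_mv is None

    def test_exponential_gaps_recover_mean(self, rng):
        mean_s = 116 * 60.0
        gaps = rng.exponential(mean_s, size=999)
        times = np.cumsum(np.maximum(np.round(gaps), 1)).astype(int)
        s = isi_summary(make_train(times))
        se_min = (mean_s / 60.0) / np.sqrt(999)
        assert abs(s.mean_interval_min - 116.0) < 3 * se_min

    def test_matches_one_line_recomputation(self, rng):
        times = np.unique(rng.integers(0, 100000, size=200))
        amps = rng.uniform(0.1, 2.0, size=len(times))
        s = isi_summary(make_train(times, amplitudes=amps))
        assert s.mean_interval_min == pytest.approx(np.mean(np.diff(times)) / 60)
        assert s.sd_interval_min == pytest.approx(np.std(np.diff(times), ddof=1) / 60)
        assert s.mean_amplitude_mv == pytest.approx(np.mean(amps))


class TestSpikeWidth:
    def make_event(self, x, params, peak):
        stat = prominence_trace(x, params.w)
        return SpikeEvent(peak_index=peak, amplitude=float(x[peak]),
                          prominence=float(stat[peak]))

    def test_triangular_spike_half_prominence(self):
        # base 200 s, height 10*delta; with a wide window the baseline term is
        # tiny so the half-prominence run is about half the base = 100 s
        params = DetectionParams(w=2500, delta=0.01, d=100)
        n = 4 * params.w + 2001
        x = np.zeros(n)
        center = n // 2
        t = np.arange(n)
        tri = 10 * params.delta * (1 - np.abs(t - center) / 100.0)
        x += np.clip(tri, 0, None)
        event = self.make_event(x, params, center)
        width, censored = spike_width(x, event, params)
        assert not censored
        assert width == pytest.approx(100, abs=4)

    def test_rectangular_impulse_width(self):
        params = DetectionParams(w=200, delta=0.01, d=10)
        n = 4 * params.w + 401
        x = np.zeros(n)
        k = 11
        start = n // 2
        x[start : start + k] = 10 * params.delta
        event = self.make_event(x, params, start + k // 2)
        width, censored = spike_width(x, event, params)
        assert width == k and not censored

    def test_window_truncated_spike_is_censored(self):
        params = DetectionParams(w=50, delta=0.01, d=10)
        n = 4 * params.w + 100
        x = np.zeros(n)
        x[2 * params.w : 2 * params.w + 300] = 10 * params.delta  # runs to edge
        event = self.make_event(x, params, 2 * params.w + 40)
        _, censored = spike_width(x, event, params)
        assert censored


class TestWavePackets:
    def test_single_packet_between_long_gaps(self):
        isi = 64 * 60
        packet = [100000 + k * isi for k in range(12)]
        lone = [1000, 300000]
        train = make_train(sorted(lone + packet))
        packets = find_wave_packets(train, gap_threshold=1.5 * isi, min_spikes=3)
        assert len(packets) == 1
        assert len(packets[0].events) == 12
        assert packets[0].start_index == packet[0]

    def test_all_gaps_above_threshold(self):
        train = make_train([0, 1000, 2000, 3000])
        assert find_wave_packets(train, gap_threshold=500) == []

    def test_min_spikes_one_partitions_all_spikes(self, rng):
        times = np.unique(rng.integers(0, 50000, size=60))
        train = make_train(times)
        packets = find_wave_packets(train, gap_threshold=400.0, min_spikes=1)
        covered = [e.peak_index for p in packets for e in p.events]
        assert covered == list(times)

    def test_packet_needs_three_spikes(self):
        ev = [SpikeEvent(0, 1.0, 1.0), SpikeEvent(10, 1.0, 1.0)]
        with pytest.raises(ValidationError):
            WavePacket(0, 10, ev)


class TestShapeScore:
    def test_rise_fall_profile(self):
        train = make_train([0, 10, 20, 30, 40], amplitudes=[1, 2, 3, 2, 1])
        packet = find_wave_packets(train, gap_threshold=15)[0]
        score = packet_shape_score(packet)
        assert score.rise_fall and score.peak_position == pytest.approx(0.5)

    def test_monotone_profile_is_not_rise_fall(self):
        train = make_train([0, 10, 20, 30], amplitudes=[1, 2, 3, 4])
        packet = find_wave_packets(train, gap_threshold=15)[0]
        assert not packet_shape_score(packet).rise_fall

    def test_injected_packets_score_rise_fall(self):
        # closed loop: inject -> detect -> segment -> score, 20 seeds
        params = DetectionParams(w=100, delta=0.005, d=100)
        isi = 64 * 60
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 12 * isi + 4000
            x = rng.normal(0, params.delta / 10, size=n)
            rec = Recording(["p"], x[None, :])
            truth = GroundTruth(channels={"p": ChannelTruth(
                times=np.array([], dtype=int), amplitudes=np.array([]),
                widths=np.array([]))})
            inject_wave_packet(rec, truth, n_spikes=12, isi_s=isi, at_s=1000,
                               channel="p", sigma_s=40.0)
            train = detect_spikes(rec, params)["p"]
            packets = find_wave_packets(train, gap_threshold=1.5 * isi)
            if packets and packet_shape_score(packets[0]).rise_fall:
                hits += 1
        assert hits >= 18


def oracle_matching(ta, tb, max_lag):
    """Exhaustive best matching: max pair count, ties by total |lag|."""
    tb = tuple(tb)

    @lru_cache(maxsize=None)
    def best(i, used):
        if i == len(ta):
            return (0, 0.0, ())
        candidates = [best(i + 1, used)]
        for j, t in enumerate(tb):
            if not (used >> j) & 1 and abs(ta[i] - t) <= max_lag:
                pairs, lag, match = best(i + 1, used | (1 << j))
                candidates.append((pairs + 1, lag + abs(ta[i] - t),
                                   ((ta[i], t),) + match))
        return max(candidates, key=lambda c: (c[0], -c[1]))

    return best(0, 0)


class TestSynchronize:
    def test_identical_trains(self):
        times = [100, 5000, 9000]
        rep = synchronize(make_train(times), make_train(times), max_lag=1800)
        assert len(rep.pairs) == 3 and np.all(rep.lags == 0)

    def test_shifted_train(self):
        times = np.array([100, 5000, 9000, 14000])
        rep = synchronize(make_train(times), make_train(times + 300), max_lag=1800)
        assert len(rep.pairs) == 4
        np.testing.assert_array_equal(rep.lags, 300.0)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(50):
            na, nb = rng.integers(1, 9, size=2)
            ta = np.sort(rng.integers(0, 4000, size=na))
            tb = np.sort(rng.integers(0, 4000, size=nb))
            max_lag = float(rng.integers(100, 1200))
            rep = synchronize(ta, tb, max_lag=max_lag)
            pairs, total, matching = oracle_matching(tuple(ta), tuple(tb), max_lag)
            assert len(rep.pairs) == pairs
            assert sum(abs(l) for l in rep.lags) == pytest.approx(total)

    def test_pair_count_symmetry(self, rng):
        for _ in range(20):
            ta = np.sort(rng.integers(0, 20000, size=rng.integers(0, 15)))
            tb = np.sort(rng.integers(0, 20000, size=rng.integers(0, 15)))
            ab = synchronize(ta, tb, max_lag=900)
            ba = synchronize(tb, ta, max_lag=900)
            assert len(ab.pairs) == len(ba.pairs)

    def test_each_spike_matched_at_most_once_within_lag(self, rng):
        ta = np.sort(rng.integers(0, 30000, size=12))
        tb = np.sort(rng.integers(0, 30000, size=10))
        rep = synchronize(ta, tb, max_lag=1500)
        assert len({a for a, _, _ in rep.pairs}) == len(rep.pairs)
        assert len({b for _, b, _ in rep.pairs}) == len(rep.pairs)
        assert np.all(np.abs(rep.lags) <= 1500)
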