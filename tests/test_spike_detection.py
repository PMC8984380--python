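"""Detector unit tests: baseline formula, threshold rule, de-duplication."""

import numpy as np
import pytest

from mycolingua import (
    DetectionParams,
    InputTooShortError,
    Recording,
    ValidationError,
    candidate_peaks,
    deduplicate,
    detect_spikes,
    generate_benchmark,
    neighbourhood_average,
    prominence_trace,
)


def naive_neighbourhood_average(x, w):
    """Literal per-index re-evaluation of the baseline formula."""
    n = len(x)
    a = np.full(n, np.nan)
    for i in range(2 * w, n - 2 * w):
        a[i] = sum(x[i - 2 * w : i + 2 * w + 1]) / (4 * w)
    return a


def naive_detect(x, params):
    """Literal scan of the threshold inequality plus greedy de-duplication."""
    a = naive_neighbourhood_average(x, params.w)
    stat = np.abs(x) - np.abs(a)
    cands = [i for i in range(len(x)) if np.isfinite(stat[i]) and stat[i] > params.delta]
    order = sorted(cands, key=lambda i: (-stat[i], i))
    kept = []
    for i in order:
        if all(abs(i - j) >= params.d for j in kept):
            kept.append(i)
    return sorted(kept)


def random_signal(rng, n, n_bumps, height, sigma):
    x = rng.normal(0, height / 20, size=n)
    x += np.cumsum(rng.normal(0, height / 500, size=n))  # slow drift
    for _ in range(n_bumps):
        t = rng.uniform(0.1 * n, 0.9 * n)
        amp = rng.uniform(0.5 * height, 1.5 * height)
        idx = np.arange(max(0, int(t - 4 * sigma)), min(n, int(t + 4 * sigma)))
        x[idx[0] : idx[-1] + 1] += amp * np.exp(-0.5 * ((idx - t) / sigma) ** 2)
    return x


class TestNeighbourhoodAverage:
    @pytest.mark.parametrize("w,c", [(5, 1.0), (20, -0.3), (50, 2.5)])
    def test_constant_signal(self, w, c):
        x = np.full(8 * w, c)
        a = neighbourhood_average(x, w)
        valid = a[2 * w : len(x) - 2 * w]
        np.testing.assert_allclose(valid, c * (4 * w + 1) / (4 * w), rtol=1e-12)

    def test_zero_signal(self):
        a = neighbourhood_average(np.zeros(500), 20)
        np.testing.assert_array_equal(a[40:-40], 0.0)

    def test_matches_naive_oracle(self, rng):
        x = rng.normal(size=2000)
        w = 50
        a = neighbourhood_average(x, w)
        expected = naive_neighbourhood_average(x, w)
        np.testing.assert_allclose(a[2 * w : -2 * w], expected[2 * w : -2 * w],
                                   atol=1e-12)

    def test_window_bounds_are_nan(self):
        a = neighbourhood_average(np.ones(300), 20)
        assert np.all(np.isnan(a[:40])) and np.all(np.isnan(a[-40:]))
        assert np.all(np.isfinite(a[40:-40]))

    def test_too_short_signal_rejected(self):
        with pytest.raises(InputTooShortError):
            neighbourhood_average(np.zeros(80), 20)


class TestCandidatePeaks:
    def test_constant_signal_has_no_candidates(self):
        params = DetectionParams(w=20, delta=0.01, d=10)
        assert len(candidate_peaks(np.full(400, 3.0), params)) == 0

    def test_rectangular_impulse_detected(self):
        params = DetectionParams(w=50, delta=0.01, d=10)
        x = np.zeros(1000)
        x[500:505] = 10 * params.delta
        cands = candidate_peaks(x, params)
        assert set(range(500, 505)) <= set(cands)

    def test_matches_literal_inequality_scan(self, rng):
        params = DetectionParams(w=30, delta=0.05, d=20)
        x = random_signal(rng, 3000, 6, 10 * params.delta, params.w / 3)
        stat = prominence_trace(x, params.w)
        expected = [
            i
            for i in range(len(x))
            if np.isfinite(stat[i]) and stat[i] > params.delta
        ]
        assert list(candidate_peaks(x, params)) == expected


class TestDeduplicate:
    def test_equal_prominence_keeps_earlier(self):
        params = DetectionParams(w=50, delta=0.01, d=100)
        x = np.zeros(1000)
        x[100] = x[150] = 1.0  # both impulses inside each other's window
        train = deduplicate([100, 150], x, params)
        assert list(train.peak_times) == [100]

    def test_higher_prominence_wins(self):
        params = DetectionParams(w=50, delta=0.01, d=100)
        x = np.zeros(1000)
        x[100], x[150], x[400] = 1.0, 2.0, 1.0
        train = deduplicate([100, 150, 400], x, params)
        assert list(train.peak_times) == [150, 400]

    def test_matches_greedy_oracle_on_random_candidates(self, rng):
        params = DetectionParams(w=30, delta=0.01, d=25)
        for _ in range(5):
            x = random_signal(rng, 4000, 8, 0.5, 10)
            stat = prominence_trace(x, params.w)
            cands = np.flatnonzero(
                np.where(np.isfinite(stat), stat, -np.inf) > params.delta
            )
            if len(cands) > 500:
                cands = cands[:500]
            train = deduplicate(cands, x, params)
            order = sorted(cands, key=lambda i: (-stat[i], i))
            kept = []
            for i in order:
                if all(abs(i - j) >= params.d for j in kept):
                    kept.append(int(i))
            assert list(train.peak_times) == sorted(kept)

    def test_minimum_separation_invariant(self, rng):
        params = DetectionParams(w=30, delta=0.02, d=40)
        x = random_signal(rng, 5000, 12, 0.4, 10)
        train = deduplicate(candidate_peaks(x, params), x, params)
        gaps = np.diff(train.peak_times)
        assert np.all(gaps >= params.d)


class TestDetectSpikes:
    def test_injected_spikes_recovered_exactly(self):
        rec, truth = generate_benchmark("schizophyllum", n_spikes=20, seed=3,
                                        noise_factor=0.0)
        params = rec_params = truth_params = None
        from mycolingua import SPECIES_DETECTION_PARAMS

        params = SPECIES_DETECTION_PARAMS["schizophyllum"]
        trains = detect_spikes(rec, params)
        detected = trains["1-2"].peak_times
        injected = truth.channels["1-2"].times
        assert len(detected) == 20
        assert np.all(np.abs(detected - injected) <= 3)

    def test_pure_noise_yields_no_spikes(self):
        params = DetectionParams(w=50, delta=0.1, d=100)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, params.delta / 10, size=5000)
            rec = Recording(["n"], x[None, :])
            trains = detect_spikes(rec, params)
            assert len(trains["n"]) == 0

    def test_flat_recording_yields_no_spikes(self):
        params = DetectionParams(w=20, delta=0.01, d=10)
        rec = Recording(["f"], np.zeros((1, 500)))
        assert len(detect_spikes(rec, params)["f"]) == 0

    def test_full_detector_equals_naive_reevaluation(self, rng):
        params = DetectionParams(w=25, delta=0.05, d=30)
        x = random_signal(rng, 4000, 10, 10 * params.delta, params.w / 3)
        rec = Recording(["c"], x[None, :])
        train = detect_spikes(rec, params)["c"]
        assert list(train.peak_times) == naive_detect(x, params)


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"w": 0, "delta": 0.1, "d": 10},
        {"w": 10, "delta": 0.0, "d": 10},
        {"w": 10, "delta": 0.1, "d": 0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            DetectionParams(**kwargs)
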