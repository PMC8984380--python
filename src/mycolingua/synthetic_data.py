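"""Seeded synthetic recordings with ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes for
1 Hz differential-potential recordings of fruiting fungi:

* species-specific mean inter-spike intervals and mean spike amplitudes
  (four named presets);
* renewal spiking with exponential gaps;
* spikes as smooth unimodal (Gaussian) bumps with lognormal amplitude
  variability;
* slow mean-reverting baseline drift plus white measurement noise;
* bursts (wave packets) whose spike amplitude and width rise to mid-packet
  and then fall;
* near-synchronized spiking on a paired channel with a configurable lag
  schedule.

All randomness flows through one ``numpy`` Generator seeded by the caller,
so the same seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .errors import PlacementError, UsageError, ValidationError
from .linguistics import Sentence
from .signal_io import Recording
from .spike_detection import SPECIES_DETECTION_PARAMS, DetectionParams


@dataclass(frozen=True)
class SpeciesPreset:
    """Species-level generation defaults: mean inter-spike interval (minutes),
    mean spike amplitude (mV) and the matching detection parameters."""

    name: str
    mean_isi_min: float
    mean_amplitude_mv: float
    detection: DetectionParams

    def __post_init__(self) -> None:
        if self.mean_isi_min <= 0 or self.mean_amplitude_mv <= 0:
            raise ValidationError("preset values must be positive")


SPECIES_PRESETS: dict[str, SpeciesPreset] = {
    "cordyceps": SpeciesPreset(
        "cordyceps", 116.0, 0.2, SPECIES_DETECTION_PARAMS["cordyceps"]
    ),
    "flammulina": SpeciesPreset(
        "flammulina", 102.0, 0.3, SPECIES_DETECTION_PARAMS["flammulina"]
    ),
    "schizophyllum": SpeciesPreset(
        "schizophyllum", 41.0, 0.03, SPECIES_DETECTION_PARAMS["schizophyllum"]
    ),
    "omphalotus": SpeciesPreset(
        "omphalotus", 92.0, 0.007, SPECIES_DETECTION_PARAMS["omphalotus"]
    ),
}


def get_preset(name: str) -> SpeciesPreset:
    try:
        return SPECIES_PRESETS[name]
    except KeyError:
        raise UsageError(
            f"unknown species {name!r}; choose from {sorted(SPECIES_PRESETS)}"
        ) from None


@dataclass
class DriftConfig:
    """Slow baseline drift: a mean-reverting (OU) walk.

    ``sd`` is the stationary standard deviation in mV (default ``delta/3``);
    ``tau_s`` the correlation time in seconds (default ``16 w``, slow
    relative to the detector's averaging window so the baseline is locally
    flat). ``enabled=False`` turns drift off.
    """

    enabled: bool = True
    sd: float | None = None
    tau_s: float | None = None


@dataclass
class ChannelTruth:
    """Injected ground truth for one channel."""

    times: np.ndarray  # peak sample indices, seconds
    amplitudes: np.ndarray  # mV
    widths: np.ndarray  # Gaussian sigma, seconds
    packets: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GroundTruth:
    channels: dict[str, ChannelTruth]
    lags: np.ndarray | None = None  # per-spike scheduled lag for paired channels


def _ou_drift(n: int, sd: float, tau_s: float, rng: np.random.Generator) -> np.ndarray:
    rho = float(np.exp(-1.0 / tau_s))
    innovations = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n)
    innovations[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -rho], innovations)


def _add_bump(signal: np.ndarray, t: float, amp: float, sigma: float) -> None:
    lo = max(0, int(t - 4 * sigma))
    hi = min(len(signal), int(t + 4 * sigma) + 1)
    idx = np.arange(lo, hi)
    signal[lo:hi] += amp * np.exp(-0.5 * ((idx - t) / sigma) ** 2)


def _draw_spike_times(
    rng: np.random.Generator, duration_s: float, mean_gap_s: float, margin: int
) -> np.ndarray:
    times = []
    t = margin + rng.exponential(mean_gap_s)
    while t < duration_s - margin:
        times.append(t)
        t += rng.exponential(mean_gap_s)
    return np.round(np.array(times)).astype(int)


def generate_recording(
    preset: SpeciesPreset | str,
    duration_s: float,
    noise_sd: float | None = None,
    drift: DriftConfig | None = None,
    seed: int = 0,
    *,
    n_channels: int = 1,
    amplitude_cv: float = 0.25,
    spike_sigma_s: float | None = None,
    channel_labels: list[str] | None = None,
) -> tuple[Recording, GroundTruth]:
    """Generate a 1 Hz multichannel recording with known spikes.

    The signal is a slow mean-reverting drift plus Gaussian noise plus
    Gaussian spike bumps at exponential-gap times, with amplitudes lognormal
    around the preset mean (coefficient of variation ``amplitude_cv``).
    Defaults: ``noise_sd = delta/10``, spike bump sigma ``w/3`` seconds.
    Fully determined by ``seed``.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    params = preset.detection
    mean_gap_s = preset.mean_isi_min * 60.0
    if duration_s <= 10 * mean_gap_s:
        raise ValidationError(
            f"duration {duration_s} s too short: need > 10 mean ISIs "
            f"({10 * mean_gap_s:.0f} s)"
        )
    if noise_sd is None:
        noise_sd = params.delta / 10.0
    if drift is None:
        drift = DriftConfig()
    sigma_spike = spike_sigma_s if spike_sigma_s is not None else params.w / 3.0
    n = int(round(duration_s))
    margin = 2 * params.w + int(4 * sigma_spike)
    rng = np.random.default_rng(seed)

    if channel_labels is None:
        channel_labels = [f"{2 * k + 1}-{2 * k + 2}" for k in range(n_channels)]
    values = np.zeros((len(channel_labels), n))
    truth: dict[str, ChannelTruth] = {}
    ln_sigma = float(np.sqrt(np.log(1.0 + amplitude_cv**2)))
    ln_mu = float(np.log(preset.mean_amplitude_mv) - 0.5 * ln_sigma**2)
    for row, label in enumerate(channel_labels):
        times = _draw_spike_times(rng, duration_s, mean_gap_s, margin)
        amps = rng.lognormal(ln_mu, ln_sigma, size=len(times))
        widths = sigma_spike * rng.uniform(0.8, 1.2, size=len(times))
        signal = np.zeros(n)
        if drift.enabled:
            sd = drift.sd if drift.sd is not None else params.delta / 3.0
            tau = drift.tau_s if drift.tau_s is not None else 16.0 * params.w
            signal += _ou_drift(n, sd, tau, rng)
        if noise_sd > 0:
            signal += rng.normal(0.0, noise_sd, size=n)
        for t, a, s in zip(times, amps, widths):
            _add_bump(signal, t, a, s)
        values[row] = signal
        truth[label] = ChannelTruth(times=times, amplitudes=amps, widths=widths)
    recording = Recording(channels=list(channel_labels), values=values)
    return recording, GroundTruth(channels=truth)


def generate_benchmark(
    preset: SpeciesPreset | str,
    n_spikes: int = 30,
    seed: int = 0,
    *,
    noise_factor: float = 0.2,
) -> tuple[Recording, GroundTruth]:
    """Clean detection benchmark: spikes separated by at least
    ``max(2 d, 4 w)`` samples, amplitudes uniform in ``[4 delta, 6 delta]``
    (injected prominence >= 3 delta after baseline averaging), white noise of
    ``noise_factor * delta`` (<= delta/5) and no drift."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    params = preset.detection
    rng = np.random.default_rng(seed)
    sigma_spike = params.w / 3.0
    sep = max(2 * params.d, 4 * params.w)
    margin = 2 * params.w + int(4 * sigma_spike)
    gaps = rng.uniform(sep, sep + 2 * params.d, size=n_spikes)
    times = (margin + np.cumsum(gaps)).round().astype(int)
    n = int(times[-1] + margin + 1)
    amps = rng.uniform(4 * params.delta, 6 * params.delta, size=n_spikes)
    widths = np.full(n_spikes, sigma_spike)
    signal = rng.normal(0.0, noise_factor * params.delta, size=n)
    for t, a, s in zip(times, amps, widths):
        _add_bump(signal, t, a, s)
    label = "1-2"
    recording = Recording(channels=[label], values=signal[None, :])
    truth = GroundTruth(
        channels={label: ChannelTruth(times=times, amplitudes=amps, widths=widths)}
    )
    return recording, truth


def detection_scores(
    truth_times, detected_times, tolerance: float
) -> tuple[float, float]:
    """Recall and precision of detected peaks against ground truth.

    A truth spike is recovered when a detection lies within ``tolerance``
    samples; a detection is correct when a truth spike does. With truth
    spacing > 2*tolerance and detections deduplicated the matching is
    automatically one-to-one. Empty sides score 1.0 by convention.
    """
    truth = np.asarray(truth_times, dtype=float)
    det = np.asarray(detected_times, dtype=float)
    if len(truth) == 0 and len(det) == 0:
        return 1.0, 1.0
    hit_truth = (
        np.min(np.abs(truth[:, None] - det[None, :]), axis=1) <= tolerance
        if len(det)
        else np.zeros(len(truth), dtype=bool)
    )
    hit_det = (
        np.min(np.abs(det[:, None] - truth[None, :]), axis=1) <= tolerance
        if len(truth)
        else np.zeros(len(det), dtype=bool)
    )
    recall = float(hit_truth.mean()) if len(truth) else 1.0
    precision = float(hit_det.mean()) if len(det) else 1.0
    return recall, precision


def inject_wave_packet(
    recording: Recording,
    ground_truth: GroundTruth,
    n_spikes: int,
    isi_s: float,
    at_s: float,
    *,
    channel: str | None = None,
    base_amplitude: float = 1.8,
    peak_amplitude: float = 2.5,
    sigma_s: float | None = None,
    width_gain: float = 0.5,
) -> tuple[Recording, GroundTruth]:
    """Add a burst of ``n_spikes`` spikes at ``isi_s`` spacing starting at
    ``at_s``, with amplitudes and widths following a symmetric rise-then-fall
    (half-sine) template; updates the recording and ground truth in place.

    Raises :class:`PlacementError` when the packet does not fit inside the
    window-valid part of the recording.
    """
    if n_spikes < 3:
        raise ValidationError("a wave packet needs at least 3 spikes")
    if channel is None:
        channel = recording.channels[0]
    signal = recording.channel(channel)
    truth = ground_truth.channels[channel]
    sigma0 = sigma_s if sigma_s is not None else 60.0
    margin = int(4 * sigma0 * (1 + width_gain)) + 1
    first = at_s
    last = at_s + (n_spikes - 1) * isi_s
    if first - margin < 0 or last + margin > recording.n_samples:
        raise PlacementError(
            f"packet [{first:.0f}, {last:.0f}] s does not fit in recording of "
            f"{recording.n_samples} samples"
        )
    phase = np.sin(np.pi * np.arange(n_spikes) / (n_spikes - 1))
    amps = base_amplitude + (peak_amplitude - base_amplitude) * phase
    widths = sigma0 * (1.0 + width_gain * phase)
    times = np.round(at_s + isi_s * np.arange(n_spikes)).astype(int)
    for t, a, s in zip(times, amps, widths):
        _add_bump(signal, t, a, s)
    order = np.argsort(np.concatenate([truth.times, times]), kind="stable")
    truth.packets.append((int(times[0]), int(times[-1])))
    all_t = np.concatenate([truth.times, times])[order]
    all_a = np.concatenate([truth.amplitudes, amps])[order]
    all_w = np.concatenate([truth.widths, widths])[order]
    truth.times, truth.amplitudes, truth.widths = all_t, all_a, all_w
    return recording, ground_truth


def generate_synchronized_pair(
    preset: SpeciesPreset | str,
    duration_s: float,
    lag_schedule,
    jitter_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> tuple[Recording, GroundTruth]:
    """Two-channel recording where channel B repeats channel A's spikes
    shifted by a per-spike lag schedule plus Gaussian jitter.

    ``lag_schedule`` is an array of lags in seconds; if shorter than the
    number of spikes the last lag is repeated. Supports decreasing schedules
    (progressively tighter synchronization).
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    rec_a, truth_a = generate_recording(
        preset, duration_s, seed=seed, n_channels=1, channel_labels=["3-4"], **kwargs
    )
    rng = np.random.default_rng((seed, 1))
    params = preset.detection
    label_a = "3-4"
    ta = truth_a.channels[label_a]
    n_spk = len(ta.times)
    schedule = np.asarray(lag_schedule, dtype=float).ravel()
    if schedule.size == 0:
        raise ValidationError("lag_schedule must not be empty")
    if np.any(np.abs(schedule) >= duration_s):
        raise ValidationError("lags must be smaller than the recording duration")
    lags = np.concatenate(
        [schedule, np.full(max(0, n_spk - schedule.size), schedule[-1])]
    )[:n_spk]
    jitter = rng.normal(0.0, jitter_sd, size=n_spk) if jitter_sd > 0 else np.zeros(n_spk)
    tb_times = np.round(ta.times + lags + jitter).astype(int)
    sigma_spike = kwargs.get("spike_sigma_s") or params.w / 3.0
    margin = 2 * params.w + int(4 * sigma_spike)
    keep = (tb_times >= margin) & (tb_times < rec_a.n_samples - margin)
    tb_times = tb_times[keep]
    order = np.argsort(tb_times, kind="stable")
    tb_times = tb_times[order]
    amps_b = ta.amplitudes[keep][order]
    widths_b = ta.widths[keep][order]

    noise_sd = kwargs.get("noise_sd")
    if noise_sd is None:
        noise_sd = params.delta / 10.0
    drift = kwargs.get("drift") or DriftConfig()
    signal_b = np.zeros(rec_a.n_samples)
    if drift.enabled:
        sd = drift.sd if drift.sd is not None else params.delta / 3.0
        tau = drift.tau_s if drift.tau_s is not None else 16.0 * params.w
        signal_b += _ou_drift(rec_a.n_samples, sd, tau, rng)
    if noise_sd > 0:
        signal_b += rng.normal(0.0, noise_sd, size=rec_a.n_samples)
    for t, a, s in zip(tb_times, amps_b, widths_b):
        _add_bump(signal_b, t, a, s)

    label_b = "5-6"
    values = np.vstack([rec_a.values, signal_b[None, :]])
    recording = Recording(channels=[label_a, label_b], values=values)
    truth = GroundTruth(
        channels={
            label_a: ta,
            label_b: ChannelTruth(times=tb_times, amplitudes=amps_b, widths=widths_b),
        },
        lags=lags,
    )
    return recording, truth


def generate_sentence(
    chain: dict[int, dict[int, float]],
    length: int,
    seed: int = 0,
    *,
    start: int | None = None,
    channel: str | None = None,
) -> Sentence:
    """Sample a word-length sentence from a Markov chain.

    ``chain`` maps each state to its successor distribution; every row must
    sum to 1. The walk starts at ``start`` (default: the smallest state) and
    is fully determined by ``seed``.
    """
    states = sorted(chain)
    for s, row in chain.items():
        if not row:
            raise ValidationError(f"state {s} has no outgoing probabilities")
        total = sum(row.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in row.values()):
            raise ValidationError(f"row of state {s} is not stochastic (sum {total})")
    rng = np.random.default_rng(seed)
    node = start if start is not None else states[0]
    if node not in chain:
        raise ValidationError(f"start state {node} not in chain")
    # precompute cumulative rows once; one uniform draw per step
    rows = {}
    for s, row in chain.items():
        succ = sorted(row.items())
        targets = np.array([v for v, _ in succ], dtype=int)
        cum = np.cumsum([p for _, p in succ])
        cum[-1] = 1.0
        rows[s] = (targets, cum)
    draws = rng.random(length)
    words = []
    for u in draws:
        words.append(int(node))
        targets, cum = rows[node]
        node = int(targets[np.searchsorted(cum, u, side="right")])
    return Sentence(tuple(words), theta=None, channel=channel)
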