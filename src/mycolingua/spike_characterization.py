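"""Descriptive statistics of detected spike trains.

Covers inter-spike-interval and amplitude summaries, spike widths
(half-prominence convention), burst / wave-packet segmentation with a
rise-fall shape score, and one-to-one synchronization matching between the
spike trains of paired channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .spike_detection import DetectionParams, SpikeEvent, SpikeTrain, prominence_trace

#: Default synchronization window: half the smallest species mean ISI
#: (about 41 min for the fastest-spiking species), in seconds.
DEFAULT_MAX_LAG_S = 1800.0


# ---------------------------------------------------------------------------
# ISI / amplitude summary
# ---------------------------------------------------------------------------

@dataclass
class IsiSummary:
    """Per-channel spiking summary: spike count, mean/sd inter-spike interval
    in minutes and mean/sd amplitude in mV. Interval fields are ``None``
    when the train has fewer than two spikes."""

    channel: str
    n_spikes: int
    mean_interval_min: float | None
    sd_interval_min: float | None
    mean_amplitude_mv: float | None
    sd_amplitude_mv: float | None


def isi_summary(train: SpikeTrain) -> IsiSummary:
    """Mean/sd of successive peak differences (minutes) and amplitudes (mV).

    Standard deviations use the sample convention (ddof=1) and are ``None``
    when fewer than two values exist.
    """
    times = train.peak_times
    amps = train.amplitudes
    n = len(times)
    if n >= 2:
        gaps_min = np.diff(times) / 60.0
        mean_i = float(np.mean(gaps_min))
        sd_i = float(np.std(gaps_min, ddof=1)) if len(gaps_min) >= 2 else 0.0
    else:
        mean_i = sd_i = None
    if n >= 1:
        mean_a = float(np.mean(amps))
        sd_a = float(np.std(amps, ddof=1)) if n >= 2 else 0.0
    else:
        mean_a = sd_a = None
    return IsiSummary(train.channel, n, mean_i, sd_i, mean_a, sd_a)


# ---------------------------------------------------------------------------
# Spike width
# ---------------------------------------------------------------------------

def spike_width(
    signal,
    event: SpikeEvent,
    params: DetectionParams,
    *,
    signed: bool = False,
    stat: np.ndarray | None = None,
) -> tuple[float, bool]:
    """Half-prominence width of one detected spike, in seconds.

    The width is the length of the maximal contiguous run around the peak on
    which the decision statistic ``|x_j| - |a_j|`` stays above half the
    event's prominence. The run is flagged censored when it touches the edge
    of the window-valid range (the spike is truncated there).
    """
    if stat is None:
        stat = prominence_trace(signal, params.w, signed=signed)
    i = event.peak_index
    if not np.isfinite(stat[i]):
        raise ValidationError(f"peak {i} lies outside the window-valid range")
    threshold = event.prominence / 2.0
    left = i
    while left - 1 >= 0 and np.isfinite(stat[left - 1]) and stat[left - 1] > threshold:
        left -= 1
    right = i
    n = len(stat)
    while right + 1 < n and np.isfinite(stat[right + 1]) and stat[right + 1] > threshold:
        right += 1
    censored = (left > 0 and not np.isfinite(stat[left - 1])) or (
        right < n - 1 and not np.isfinite(stat[right + 1])
    )
    return float(right - left + 1), censored


def fill_widths(
    signal, train: SpikeTrain, *, signed: bool = False
) -> SpikeTrain:
    """Fill ``width`` / ``width_censored`` on every event of a train in place."""
    if train.params is None:
        raise ValidationError("train carries no detection params")
    stat = prominence_trace(signal, train.params.w, signed=signed)
    for event in train.events:
        event.width, event.width_censored = spike_width(
            signal, event, train.params, signed=signed, stat=stat
        )
    return train


# ---------------------------------------------------------------------------
# Wave packets
# ---------------------------------------------------------------------------

@dataclass
class WavePacket:
    """A burst of >= 3 spikes with successive gaps below a threshold."""

    start_index: int
    end_index: int
    events: list[SpikeEvent]

    def __post_init__(self) -> None:
        if len(self.events) < 3:
            raise ValidationError("a wave packet needs at least 3 spikes")
        peaks = [e.peak_index for e in self.events]
        if not (self.start_index <= min(peaks) and max(peaks) <= self.end_index):
            raise ValidationError("packet bounds do not cover its spikes")

    @property
    def amplitude_profile(self) -> np.ndarray:
        return np.array([e.amplitude for e in self.events], dtype=float)

    @property
    def width_profile(self) -> np.ndarray:
        return np.array(
            [np.nan if e.width is None else e.width for e in self.events], dtype=float
        )


def _maximal_runs(times: np.ndarray, gap_threshold: float) -> list[slice]:
    """Maximal runs of successive times with gaps <= gap_threshold."""
    if len(times) == 0:
        return []
    breaks = np.flatnonzero(np.diff(times) > gap_threshold)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [len(times)]))
    return [slice(int(a), int(b)) for a, b in zip(starts, stops)]


def find_wave_packets(
    train: SpikeTrain,
    gap_threshold: float | None = None,
    min_spikes: int = 3,
) -> list[WavePacket]:
    """Maximal runs of spikes with successive gaps <= ``gap_threshold`` and
    at least ``min_spikes`` spikes.

    ``gap_threshold`` defaults to the train's mean inter-spike interval (the
    same spirit as the theta word-separation rule). With ``min_spikes=1`` the
    runs partition all spikes of the train.
    """
    times = train.peak_times
    if gap_threshold is None:
        if len(times) < 2:
            return []
        gap_threshold = float(np.mean(np.diff(times)))
    packets = []
    for run in _maximal_runs(times, gap_threshold):
        events = train.events[run]
        if len(events) < min_spikes:
            continue
        if min_spikes < 3:
            # relax the >=3 packet invariant only through the explicit knob
            packet = WavePacket.__new__(WavePacket)
            packet.start_index = events[0].peak_index
            packet.end_index = events[-1].peak_index
            packet.events = events
        else:
            packet = WavePacket(events[0].peak_index, events[-1].peak_index, events)
        packets.append(packet)
    return packets


@dataclass
class ShapeScore:
    """Rise-fall verdict for a packet profile and the relative position of
    its maximum (0 = first spike, 1 = last spike)."""

    rise_fall: bool
    peak_position: float


def packet_shape_score(packet: WavePacket, profile: str = "amplitude") -> ShapeScore:
    """Test the wave-packet signature: amplitude (or width) increases until
    mid-packet and then decreases.

    The profile is smoothed with a centred 3-point (1-step) moving average;
    the verdict is true iff the smoothed maximum lies strictly inside the
    packet and the smoothed profile is non-decreasing before and
    non-increasing after it.
    """
    values = packet.amplitude_profile if profile == "amplitude" else packet.width_profile
    n = len(values)
    smooth = np.array(
        [np.mean(values[max(0, k - 1) : k + 2]) for k in range(n)], dtype=float
    )
    m = int(np.argmax(smooth))
    eps = 1e-12
    interior = 0 < m < n - 1
    rising = bool(np.all(np.diff(smooth[: m + 1]) >= -eps))
    falling = bool(np.all(np.diff(smooth[m:]) <= eps))
    return ShapeScore(
        rise_fall=interior and rising and falling,
        peak_position=m / (n - 1) if n > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# Cross-channel synchronization
# ---------------------------------------------------------------------------

@dataclass
class SyncReport:
    """One-to-one matching between two spike trains.

    ``pairs`` holds ``(peak_a, peak_b, lag)`` with ``lag = peak_b - peak_a``
    in chronological order; ``lags`` is the per-pair lag sequence (the
    interval dynamics of the matched spikes).
    """

    pairs: list[tuple[int, int, float]]
    unmatched_a: int
    unmatched_b: int
    max_lag: float

    @property
    def lags(self) -> np.ndarray:
        return np.array([lag for _, _, lag in self.pairs], dtype=float)


def synchronize(
    train_a: SpikeTrain | np.ndarray,
    train_b: SpikeTrain | np.ndarray,
    max_lag: float = DEFAULT_MAX_LAG_S,
) -> SyncReport:
    """Chronological one-to-one matching of spikes across two channels.

    Spikes may pair only when their peak times differ by at most ``max_lag``
    seconds and no spike is re-used. Among chronological (non-crossing)
    matchings the pairing maximizes the number of pairs and, among those,
    minimizes the total absolute lag; the result is deterministic.
    """
    ta = train_a.peak_times if isinstance(train_a, SpikeTrain) else np.asarray(train_a)
    tb = train_b.peak_times if isinstance(train_b, SpikeTrain) else np.asarray(train_b)
    n, m = len(ta), len(tb)

    # DP over suffixes; value = (pairs, -total_lag) maximized lexicographically.
    NEG = (-1, 0.0)
    best = np.empty((n + 1, m + 1), dtype=object)
    move = np.empty((n + 1, m + 1), dtype=object)
    best[n][m] = (0, 0.0)
    move[n][m] = None
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            options = []  # (pairs, total_lag, priority, move)
            if i < n and j < m and abs(float(ta[i]) - float(tb[j])) <= max_lag:
                p, lag = best[i + 1][j + 1]
                options.append((p + 1, lag + abs(float(ta[i]) - float(tb[j])), 0, "match"))
            if i < n:
                p, lag = best[i + 1][j]
                options.append((p, lag, 1, "skip_a"))
            if j < m:
                p, lag = best[i][j + 1]
                options.append((p, lag, 2, "skip_b"))
            options.sort(key=lambda o: (-o[0], o[1], o[2]))
            p, lag, _, mv = options[0]
            best[i][j] = (p, lag)
            move[i][j] = mv

    pairs: list[tuple[int, int, float]] = []
    i = j = 0
    while (i, j) != (n, m):
        mv = move[i][j]
        if mv == "match":
            pairs.append((int(ta[i]), int(tb[j]), float(tb[j]) - float(ta[i])))
            i, j = i + 1, j + 1
        elif mv == "skip_a":
            i += 1
        else:
            j += 1
    return SyncReport(
        pairs=pairs,
        unmatched_a=n - len(pairs),
        unmatched_b=m - len(pairs),
        max_lag=float(max_lag),
    )
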