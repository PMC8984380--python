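"""From spike trains to words and sentences.

A spike train is binarized at 1 Hz (bit ``i`` = 1 iff a spike peaks at second
``i``). Consecutive spikes whose gap does not exceed a separation threshold
``theta`` belong to the same *word*; a word's length is its number of spikes,
and the chronological sequence of word lengths from one channel is a
*sentence*. ``theta`` is taken as 1x or 2x the mean inter-spike interval of
the train. Word-length histograms are summarized and fitted with the
length-frequency law ``f(l) = beta * l**c * gamma**l``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import EstimationError, FitUndefinedError, ValidationError
from .spike_detection import SpikeTrain

#: Published per-species average fungal word lengths, keyed by
#: (species, theta multiplier); reference constants used for cross-language
#: comparison, not computed by this package.
FUNGAL_MEAN_WORD_LENGTHS: dict[tuple[str, int], float] = {
    ("cordyceps", 1): 4.7,
    ("cordyceps", 2): 8.9,
    ("flammulina", 1): 3.6,
    ("flammulina", 2): 7.4,
    ("schizophyllum", 1): 4.4,
    ("schizophyllum", 2): 8.5,
    ("omphalotus", 1): 3.3,
    ("omphalotus", 2): 7.0,
}

#: Published average word lengths of human languages (reference constants).
HUMAN_MEAN_WORD_LENGTHS: dict[str, float] = {
    "english": 4.8,
    "russian": 6.0,
    "greek": 4.45,
}


@dataclass(frozen=True)
class Sentence:
    """Chronological sequence of word lengths from one channel."""

    word_lengths: tuple[int, ...]
    theta: float | None = None
    channel: str | None = None

    def __post_init__(self) -> None:
        if any(int(l) != l or l < 1 for l in self.word_lengths):
            raise ValidationError("word lengths must be integers >= 1")

    def __len__(self) -> int:
        return len(self.word_lengths)

    @property
    def n_spikes(self) -> int:
        return int(sum(self.word_lengths))


def binarize(train: SpikeTrain, length: int | None = None) -> np.ndarray:
    """Binary string of the train: bit ``i`` = 1 iff a spike peaks at second i.

    ``length`` defaults to the train's recording length; a peak at or beyond
    ``length`` is a range error.
    """
    if length is None:
        length = train.n_samples
    bits = np.zeros(int(length), dtype=np.uint8)
    times = train.peak_times
    if len(times) and (times.min() < 0 or times.max() >= length):
        raise ValidationError(
            f"peak at {int(times.max())} outside string of length {length}"
        )
    bits[times] = 1
    return bits


def _times_of(train) -> np.ndarray:
    if isinstance(train, SpikeTrain):
        return train.peak_times
    return np.asarray(train)


def theta_from_train(train, multiplier: int = 1) -> float:
    """Word-separation threshold: ``multiplier`` x mean successive gap (s)."""
    if multiplier not in (1, 2):
        raise ValidationError(f"theta multiplier must be 1 or 2, got {multiplier}")
    times = _times_of(train)
    if len(times) < 2:
        raise EstimationError("need >= 2 spikes to define theta")
    return float(multiplier) * float(np.mean(np.diff(times)))


def segment_words(train, theta: float) -> Sentence:
    """Group spikes into words: consecutive spikes with gap <= theta share a
    word; the sentence lists word lengths chronologically.

    The gap is the difference of peak indices and the comparison is
    inclusive. Conservation (sum of word lengths = spike count) is asserted.
    """
    if theta <= 0:
        raise ValidationError("theta must be positive")
    times = _times_of(train)
    channel = train.channel if isinstance(train, SpikeTrain) else None
    if len(times) == 0:
        return Sentence((), theta=float(theta), channel=channel)
    gaps = np.diff(times)
    breaks = np.flatnonzero(gaps > theta)
    bounds = np.concatenate(([0], breaks + 1, [len(times)]))
    lengths = tuple(int(b - a) for a, b in zip(bounds[:-1], bounds[1:]))
    assert sum(lengths) == len(times), "word lengths must conserve spike count"
    return Sentence(lengths, theta=float(theta), channel=channel)


def concatenate_sentences(sentences, channel: str | None = None) -> Sentence:
    """Pool channels by concatenating their sentences in channel order."""
    lengths: tuple[int, ...] = ()
    theta = None
    for s in sentences:
        lengths = lengths + tuple(s.word_lengths)
        theta = s.theta if theta is None else theta
    return Sentence(lengths, theta=theta, channel=channel)


# ---------------------------------------------------------------------------
# Word-length distribution
# ---------------------------------------------------------------------------

@dataclass
class LengthDistribution:
    """Word-length histogram with lexicon size and mean word length."""

    frequencies: dict[int, int]
    n_words: int
    lexicon_size: int
    mean_length: float | None

    @property
    def mean_length_2dp(self) -> float | None:
        """Mean word length at the 2-decimal report precision."""
        return None if self.mean_length is None else round(self.mean_length, 2)

    def lengths(self) -> np.ndarray:
        return np.array(sorted(self.frequencies), dtype=int)

    def counts(self) -> np.ndarray:
        return np.array([self.frequencies[l] for l in sorted(self.frequencies)], dtype=float)


def length_distribution(sentence) -> LengthDistribution:
    """Exact histogram of word lengths of a sentence (or raw length list)."""
    lengths = list(sentence.word_lengths if isinstance(sentence, Sentence) else sentence)
    freq = dict(sorted(Counter(int(l) for l in lengths).items()))
    n = len(lengths)
    mean = float(np.mean(lengths)) if n else None
    assert sum(freq.values()) == n
    return LengthDistribution(freq, n, len(freq), mean)


def mean_word_length(values, decimals: int = 2) -> float:
    """Mean of a collection of word lengths, at report precision."""
    return round(float(np.mean(np.asarray(values, dtype=float))), decimals)


# ---------------------------------------------------------------------------
# Length-frequency law
# ---------------------------------------------------------------------------

@dataclass
class LengthFit:
    """Fitted parameters of ``f(l) = beta * l**c * gamma**l`` with residual
    sum of squares in count space; ``gamma_fixed`` marks the constrained fit."""

    beta: float
    c: float
    gamma: float
    rss: float
    gamma_fixed: bool = False

    def predict(self, l) -> np.ndarray:
        l = np.asarray(l, dtype=float)
        return self.beta * l**self.c * self.gamma**l


def _log_linear_init(ls: np.ndarray, fs: np.ndarray, gamma: float | None):
    """Exact least squares in log space (the model is log-linear)."""
    y = np.log(fs)
    if gamma is None:
        design = np.column_stack([np.ones_like(ls), np.log(ls), ls])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return float(np.exp(coef[0])), float(coef[1]), float(np.exp(coef[2]))
    design = np.column_stack([np.ones_like(ls), np.log(ls)])
    coef, *_ = np.linalg.lstsq(design, y - ls * np.log(gamma), rcond=None)
    return float(np.exp(coef[0])), float(coef[1]), float(gamma)


def fit_length_law(dist: LengthDistribution, gamma: float | None = None) -> LengthFit:
    """Least-squares fit of ``f(l) = beta * l**c * gamma**l`` over observed
    lengths.

    With ``gamma`` given (e.g. 0.73) the exponential base is held fixed and
    only ``beta`` and ``c`` are fitted. The fit is initialized by the exact
    log-space linear solution and refined by nonlinear least squares on the
    raw counts; it requires at least 3 distinct observed lengths.
    """
    ls = dist.lengths().astype(float)
    fs = dist.counts()
    keep = fs > 0
    ls, fs = ls[keep], fs[keep]
    if len(ls) < 3:
        raise FitUndefinedError(
            f"need >= 3 distinct word lengths, got {len(ls)}"
        )
    beta0, c0, g0 = _log_linear_init(ls, fs, gamma)
    beta0 = min(max(beta0, 1e-9), 1e12)
    g0 = min(max(g0, 1e-6), 9.99)
    c0 = min(max(c0, -9.99), 9.99)
    try:
        if gamma is None:
            popt, _ = curve_fit(
                lambda l, b, c, g: b * l**c * g**l,
                ls,
                fs,
                p0=[beta0, c0, g0],
                bounds=([1e-12, -10.0, 1e-9], [1e15, 10.0, 10.0]),
                maxfev=20000,
            )
            beta, c, g = (float(v) for v in popt)
        else:
            popt, _ = curve_fit(
                lambda l, b, c: b * l**c * gamma**l,
                ls,
                fs,
                p0=[beta0, c0],
                bounds=([1e-12, -10.0], [1e15, 10.0]),
                maxfev=20000,
            )
            beta, c = (float(v) for v in popt)
            g = float(gamma)
    except RuntimeError:
        # optimizer failed to improve; report the log-space solution
        beta, c, g = beta0, c0, g0
    rss = float(np.sum((beta * ls**c * g**ls - fs) ** 2))
    return LengthFit(beta=beta, c=c, gamma=g, rss=rss, gamma_fixed=gamma is not None)
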