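"""Information-theoretic and algorithmic complexity of symbol sequences.

Sentences (sequences of word lengths) are encoded into symbol sequences over
a declared alphabet — either clamped to byte symbols (alphabet 256) or
filtered to words of at most nine spikes (alphabet 9) — and scored with
Shannon entropy, second-order (overlapping-pair block) entropy and the
Lempel-Ziv 1976 exhaustive-history phrase count, with a documented
upper-bound conversion to bits. An algorithmic-complexity estimate (e.g. a
block-decomposition backend) can be plugged in; none ships by default.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import EstimationError, UsageError, ValidationError
from .linguistics import Sentence


@dataclass(frozen=True)
class SymbolSequence:
    """Sequence of non-negative integer symbols with a declared alphabet size.

    In filter mode the symbols are raw word lengths ``1..alphabet_size``; the
    declared size bounds the number of distinct codes, and the per-symbol
    coding cost used by the LZ bits conversion is ``log2(alphabet_size)``.
    """

    symbols: tuple[int, ...]
    alphabet_size: int

    def __post_init__(self) -> None:
        if self.alphabet_size < 1:
            raise ValidationError("alphabet_size must be >= 1")
        if any(int(s) != s or s < 0 for s in self.symbols):
            raise ValidationError("symbols must be non-negative integers")
        if len(set(self.symbols)) > self.alphabet_size:
            raise ValidationError("more distinct symbols than the declared alphabet")

    def __len__(self) -> int:
        return len(self.symbols)


def _symbols_of(seq) -> tuple:
    if isinstance(seq, SymbolSequence):
        return seq.symbols
    return tuple(seq)


def shannon_entropy(seq) -> float:
    """First-order Shannon entropy, ``-sum p(s) log2 p(s)``, in bits.

    Accepts a :class:`SymbolSequence` or any sequence of hashable symbols.
    """
    symbols = _symbols_of(seq)
    if not symbols:
        raise EstimationError("entropy of an empty sequence is undefined")
    counts = np.array(list(Counter(symbols).values()), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def second_order_entropy(seq) -> float:
    """Shannon entropy of the empirical distribution of overlapping ordered
    pairs (pair block entropy), in bits.

    Pairs are taken circularly (the last symbol wraps to the first), so the
    pair marginals equal the symbol distribution exactly; this makes the
    subadditivity bound ``H2 <= 2 H1`` hold for every finite sequence and an
    even-length alternation score exactly 1 bit.
    """
    symbols = _symbols_of(seq)
    if len(symbols) < 2:
        raise EstimationError("second-order entropy needs >= 2 symbols")
    return shannon_entropy(list(zip(symbols, symbols[1:] + symbols[:1])))


# ---------------------------------------------------------------------------
# LZ76
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LZ76Result:
    phrases: int
    bits: float
    bits_normalized: float


def _lz76_phrase_count(symbols: tuple[int, ...]) -> int:
    """Exhaustive-history Lempel-Ziv 1976 factorization count.

    Each phrase is the shortest prefix of the remaining string that is not
    reproducible from the preceding history (the copy source may extend into
    the phrase itself); the final phrase may be reproducible.
    """
    n = len(symbols)
    if all(0 <= s < 256 for s in symbols):
        s = bytes(symbols)

        def occurs(i: int, k: int) -> bool:
            # s[i:i+k] occurs as a substring of s[:i+k-1]
            return s[: i + k - 1].find(s[i : i + k]) >= 0

    else:
        toks = [str(v) for v in symbols]

        def occurs(i: int, k: int) -> bool:
            hay = "," + ",".join(toks[: i + k - 1]) + ","
            needle = "," + ",".join(toks[i : i + k]) + ","
            return needle in hay

    phrases = 0
    i = 0
    while i < n:
        k = 0
        while i + k < n and occurs(i, k + 1):
            k += 1
        if i + k >= n and k > 0:
            length = k  # ran off the end while still reproducible
        else:
            length = k + 1
        phrases += 1
        i += length
    return phrases


def lz_bits(phrases: int, alphabet_size: int) -> float:
    """Upper-bound encoding cost of an LZ76 factorization in bits:
    ``phrases * (log2(phrases) + log2(alphabet_size))`` — each phrase names a
    history position and one fresh symbol."""
    return phrases * (math.log2(phrases) + math.log2(alphabet_size))


def lz76(seq, alphabet_size: int | None = None) -> LZ76Result:
    """LZ76 phrase count with the documented bits conversion.

    ``alphabet_size`` defaults to the declared alphabet of a
    :class:`SymbolSequence`, or to the number of distinct symbols otherwise.
    """
    symbols = tuple(int(s) for s in _symbols_of(seq))
    if not symbols:
        raise EstimationError("LZ76 of an empty sequence is undefined")
    if alphabet_size is None:
        alphabet_size = (
            seq.alphabet_size
            if isinstance(seq, SymbolSequence)
            else max(len(set(symbols)), 1)
        )
    phrases = _lz76_phrase_count(symbols)
    bits = lz_bits(phrases, alphabet_size)
    return LZ76Result(
        phrases=phrases, bits=bits, bits_normalized=bits / len(symbols)
    )


# ---------------------------------------------------------------------------
# Encoding and the full report
# ---------------------------------------------------------------------------

def encode_sentence(sentence, cap: int = 9, mode: str = "filter") -> SymbolSequence:
    """Encode word lengths as symbols.

    ``mode="filter"`` drops entries above ``cap`` and declares an alphabet of
    ``cap`` symbols (order and multiplicity of survivors preserved);
    ``mode="cap"`` clamps at 255 and declares the byte alphabet of 256.
    """
    lengths = (
        sentence.word_lengths if isinstance(sentence, Sentence) else tuple(sentence)
    )
    if any(l < 1 for l in lengths):
        raise ValidationError("word lengths must be positive")
    if mode == "filter":
        symbols = tuple(int(l) for l in lengths if l <= cap)
        return SymbolSequence(symbols, alphabet_size=int(cap))
    if mode == "cap":
        symbols = tuple(min(int(l), 255) for l in lengths)
        return SymbolSequence(symbols, alphabet_size=256)
    raise UsageError(f"unknown encoding mode {mode!r} (expected 'filter' or 'cap')")


@dataclass
class ComplexityReport:
    """All complexity measures for one encoded sentence.

    ``algorithmic_complexity`` is only present when an external backend was
    configured and is flagged backend-dependent. ``empty`` marks a sentence
    with no symbols left after encoding.
    """

    shannon_entropy: float | None
    second_order_entropy: float | None
    lz_phrases: int | None
    lz_bits: float | None
    lz_bits_normalized: float | None
    input_length: int
    alphabet_size: int
    algorithmic_complexity: float | None = None
    empty: bool = False


def complexity_report(
    sentence,
    cap: int = 9,
    mode: str = "filter",
    backend: Callable[[SymbolSequence], float] | None = None,
) -> ComplexityReport:
    """Assemble the complexity measures of a sentence after encoding."""
    seq = encode_sentence(sentence, cap=cap, mode=mode)
    n = len(seq)
    if n == 0:
        return ComplexityReport(
            shannon_entropy=None,
            second_order_entropy=None,
            lz_phrases=None,
            lz_bits=None,
            lz_bits_normalized=None,
            input_length=0,
            alphabet_size=seq.alphabet_size,
            empty=True,
        )
    h1 = shannon_entropy(seq)
    h2 = second_order_entropy(seq) if n >= 2 else None
    lz = lz76(seq)
    ac = float(backend(seq)) if backend is not None else None
    return ComplexityReport(
        shannon_entropy=h1,
        second_order_entropy=h2,
        lz_phrases=lz.phrases,
        lz_bits=lz.bits,
        lz_bits_normalized=lz.bits_normalized,
        input_length=n,
        alphabet_size=seq.alphabet_size,
        algorithmic_complexity=ac,
    )
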