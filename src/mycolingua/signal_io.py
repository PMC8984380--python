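"""Plain-text readers and writers for recordings, spike tables, sentences and graphs.

Conventions (global for the package):

* recordings are CSV with one header row; the first column is time in
  seconds, remaining columns are one channel each, values in mV;
* indices are 0-based seconds from recording start; intervals are closed on
  both ends when counting samples;
* floats are serialized with Python's shortest round-trip ``repr`` (always
  more than 6 significant digits), so sub-µV amplitudes survive a round trip
  exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError, ValidationError

SPIKE_COLUMNS = ("channel", "peak_index", "amplitude", "prominence", "width")


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel differential-potential recording sampled at a fixed rate.

    Attributes
    ----------
    channels
        Ordered channel labels, e.g. ``"3-4"`` for an electrode pair.
    values
        Array of shape ``(n_channels, n_samples)`` holding potentials in mV.
    sample_rate
        Samples per second; the recordings this package targets use 1 Hz.
    start_index
        Integer sample offset of the first sample.
    """

    channels: list[str]
    values: np.ndarray
    sample_rate: float = 1.0
    start_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if len(self.channels) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.channels)} channel labels for "
                f"{self.values.shape[0]} value rows"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.values[self.channels.index(label)]
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None


def read_recording(path: str | Path) -> Recording:
    """Read a recording from CSV (first column time, one column per channel).

    Raises
    ------
    OSError
        If the file does not exist.
    FormatError
        On ragged rows, non-numeric cells or a non-monotone time column; the
        message names the offending line (1-based, header is line 1).
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: need a time column plus at least one channel")

    columns = []
    for name in raw.columns:
        probe = pd.to_numeric(raw[name], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(probe)
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path}: line {line}: missing or non-numeric value in column {name!r}"
            )
        # to_numeric only located bad cells; astype(float) parses exactly
        col = raw[name].astype(float).to_numpy()
        columns.append((name, col, None))

    tname, t, _ = columns[0]
    if len(t) == 0:
        raise FormatError(f"{path}: no data rows")
    steps = np.diff(t)
    if np.any(steps <= 0):
        line = int(np.flatnonzero(steps <= 0)[0]) + 3
        raise FormatError(f"{path}: line {line}: time column {tname!r} not increasing")
    if len(steps) and not np.allclose(steps, steps[0]):
        line = int(np.flatnonzero(~np.isclose(steps, steps[0]))[0]) + 3
        raise FormatError(f"{path}: line {line}: non-uniform sampling step")
    sample_rate = 1.0 / steps[0] if len(steps) else 1.0
    start_index = int(round(t[0] * sample_rate))

    labels = [name for name, _, _ in columns[1:]]
    values = np.vstack([col for _, col, _ in columns[1:]])
    return Recording(labels, values, sample_rate=sample_rate, start_index=start_index)


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as CSV (lossless float serialization)."""
    t = (recording.start_index + np.arange(recording.n_samples)) / recording.sample_rate
    frame = pd.DataFrame({"time_s": t})
    for label, row in zip(recording.channels, recording.values):
        frame[label] = row
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Spike tables
# ---------------------------------------------------------------------------

def validate_spike_table(table: pd.DataFrame) -> None:
    """Check spike-table invariants (monotone peaks per channel, prominence ≥ 0)."""
    missing = [c for c in SPIKE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"spike table missing columns {missing}")
    if len(table) == 0:
        return
    if (table["prominence"].to_numpy(dtype=float) < 0).any():
        raise ValidationError("negative prominence in spike table")
    for channel, group in table.groupby("channel", sort=False):
        peaks = group["peak_index"].to_numpy(dtype=float)
        if np.any(np.diff(peaks) <= 0):
            raise ValidationError(
                f"peak_index not strictly increasing within channel {channel!r}"
            )


def write_spike_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a spike table as TSV with header; validates invariants first."""
    validate_spike_table(table)
    out = table.loc[:, list(SPIKE_COLUMNS)]
    out.to_csv(path, sep="\t", index=False)


def read_spike_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"channel": str},
    )
    if len(table):
        table["peak_index"] = table["peak_index"].astype(int)
    validate_spike_table(table)
    return table


# ---------------------------------------------------------------------------
# Sentences
# ---------------------------------------------------------------------------

def write_sentences(sentences: Iterable, path: str | Path) -> None:
    """Serialize sentences, one channel per line.

    Line layout: ``channel<TAB>theta<TAB>l1 l2 l3 ...`` where the third field
    is the whitespace-separated word lengths (empty for an empty sentence).
    """
    with open(path, "w") as fh:
        fh.write("channel\ttheta\tword_lengths\n")
        for sentence in sentences:
            lengths = " ".join(str(int(l)) for l in sentence.word_lengths)
            theta = "" if sentence.theta is None else repr(float(sentence.theta))
            fh.write(f"{sentence.channel or ''}\t{theta}\t{lengths}\n")


def read_sentences(path: str | Path) -> list:
    from .linguistics import Sentence

    sentences = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("channel"):
            raise FormatError(f"{path}: line 1: expected sentence header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 tab fields")
            channel, theta, lengths = parts
            try:
                words = tuple(int(tok) for tok in lengths.split())
                theta_val = float(theta) if theta else None
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            sentences.append(
                Sentence(word_lengths=words, theta=theta_val, channel=channel or None)
            )
    return sentences


# ---------------------------------------------------------------------------
# Transition graphs
# ---------------------------------------------------------------------------

def _graph_edges(graph) -> list[tuple[int, int, float]]:
    """Extract (from, to, probability) rows from either graph flavour."""
    if hasattr(graph, "probabilities"):
        edges = [(u, v, p) for (u, v), p in graph.probabilities.items()]
    elif hasattr(graph, "retained"):
        edges = [(u, v, p) for u, (v, p) in graph.retained.items()]
    else:  # pragma: no cover - defensive
        raise UsageError(f"cannot serialize object of type {type(graph).__name__}")
    return sorted(edges)


def write_graph(graph, path: str | Path, format: str = "tsv") -> None:
    """Write a transition graph as an edge-list TSV or as Graphviz DOT.

    Parameters
    ----------
    graph
        A :class:`~mycolingua.spiking_machine.TransitionGraph` or
        :class:`~mycolingua.spiking_machine.FilteredGraph`.
    format
        ``"tsv"`` (rows ``from  to  probability``) or ``"dot"``.
    """
    fmt = format.lower()
    edges = _graph_edges(graph)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("from\tto\tprobability\n")
            for u, v, p in edges:
                fh.write(f"{u}\t{v}\t{p!r}\n")
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("digraph spiking_machine {\n")
            for state in sorted(getattr(graph, "states", ())):
                fh.write(f'    "{state}";\n')
            for u, v, p in edges:
                fh.write(f'    "{u}" -> "{v}" [label="{p:.3f}", weight={p:.6f}];\n')
            fh.write("}\n")
    else:
        raise UsageError(f"unknown graph format {format!r} (expected 'tsv' or 'dot')")


def read_graph(path: str | Path):
    """Read an edge-list TSV back into a TransitionGraph (counts unknown)."""
    from .spiking_machine import TransitionGraph

    probabilities: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("from"):
            raise FormatError(f"{path}: line 1: expected edge-list header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 tab fields")
            try:
                u, v, p = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            probabilities[(u, v)] = p
    return TransitionGraph.from_probabilities(probabilities, atol=1e-6)
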