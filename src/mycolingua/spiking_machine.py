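"""Probabilistic spiking machines estimated from sentences.

A spiking machine is a finite-state machine over observed word lengths whose
transition probabilities are the row-normalized counts of consecutive word
pairs in a sentence. The module analyzes the resulting weighted directed
graph: Garden-of-Eden (leaf) states, absorbing states, attractive cores
(closed communicating classes), cycles of the max-weight-filtered graph and
the longest leaf-to-core transient.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .errors import EstimationError, ValidationError
from .linguistics import Sentence


@dataclass(frozen=True)
class TransitionGraph:
    """Weighted digraph over word-length states.

    ``counts`` maps ordered state pairs to transition counts (``None`` when
    the graph was read from disk without counts); ``probabilities`` are the
    per-source row-normalized weights.
    """

    states: tuple[int, ...]
    probabilities: dict[tuple[int, int], float]
    counts: dict[tuple[int, int], int] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        rows: dict[int, float] = {}
        for (u, v), p in self.probabilities.items():
            if u not in self.states or v not in self.states:
                raise ValidationError(f"edge ({u}, {v}) references unknown state")
            if not (0.0 <= p <= 1.0 + atol):
                raise ValidationError(f"probability {p} outside [0, 1]")
            rows[u] = rows.get(u, 0.0) + p
        for u, total in rows.items():
            if abs(total - 1.0) > atol:
                raise ValidationError(
                    f"outgoing probabilities of state {u} sum to {total}, not 1"
                )

    @classmethod
    def from_probabilities(
        cls, probabilities: dict[tuple[int, int], float], atol: float = 1e-9
    ) -> "TransitionGraph":
        states = tuple(sorted({s for edge in probabilities for s in edge}))
        graph = cls.__new__(cls)
        object.__setattr__(graph, "states", states)
        object.__setattr__(graph, "probabilities", dict(probabilities))
        object.__setattr__(graph, "counts", None)
        graph.validate(atol=atol)
        return graph

    def successors(self, state: int) -> dict[int, float]:
        return {v: p for (u, v), p in self.probabilities.items() if u == state}

    def sinks(self) -> tuple[int, ...]:
        """States never observed as a transition source (sentence-final only)."""
        sources = {u for u, _ in self.probabilities}
        return tuple(s for s in self.states if s not in sources)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        for (u, v), p in self.probabilities.items():
            g.add_edge(u, v, probability=p)
        return g


@dataclass(frozen=True)
class FilteredGraph:
    """Max-weight filtering of a transition graph: each non-sink state keeps
    only its most probable successor, so out-degree is at most 1 everywhere."""

    states: tuple[int, ...]
    retained: dict[int, tuple[int, float]]  # state -> (successor, weight)

    @property
    def successor(self) -> dict[int, int]:
        return {u: v for u, (v, _) in self.retained.items()}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        for u, (v, p) in self.retained.items():
            g.add_edge(u, v, probability=p)
        return g


@dataclass
class GraphAnalysis:
    """Structural summary of a (possibly filtered) transition graph.

    ``cycles`` and ``max_transient`` are only defined on filtered graphs
    (out-degree <= 1 makes cycles disjoint and paths unique) and are ``None``
    when a probabilistic graph was analyzed.
    """

    leaves: tuple[int, ...]
    absorbing: tuple[int, ...]
    cores: tuple[frozenset, ...]
    sinks: tuple[int, ...]
    cycles: tuple[tuple[int, ...], ...] | None
    max_transient: int | None


def estimate_machine(sentences: Sentence | list[Sentence]) -> TransitionGraph:
    """Estimate transition counts and probabilities from sentences.

    Counts come from consecutive word-length pairs; with several sentences
    (e.g. one per channel) the counts are pooled and no pair spans a sentence
    boundary. At least one pair must exist.
    """
    if isinstance(sentences, Sentence):
        sentences = [sentences]
    counts: Counter = Counter()
    states: set[int] = set()
    for sentence in sentences:
        words = sentence.word_lengths
        states.update(int(w) for w in words)
        counts.update(zip(words, words[1:]))
    if not counts:
        raise EstimationError("need a sentence with >= 2 words to estimate a machine")
    totals: Counter = Counter()
    for (u, _), n in counts.items():
        totals[u] += n
    probabilities = {
        (int(u), int(v)): n / totals[u] for (u, v), n in counts.items()
    }
    graph = TransitionGraph.__new__(TransitionGraph)
    object.__setattr__(graph, "states", tuple(sorted(states)))
    object.__setattr__(graph, "probabilities", probabilities)
    object.__setattr__(
        graph, "counts", {(int(u), int(v)): int(n) for (u, v), n in counts.items()}
    )
    graph.validate(atol=1e-9)
    return graph


def filter_max(graph: TransitionGraph) -> FilteredGraph:
    """Keep, per state, the successor with maximal weight (ties toward the
    smaller state label)."""
    retained: dict[int, tuple[int, float]] = {}
    for state in graph.states:
        succ = graph.successors(state)
        if not succ:
            continue
        best = min(succ, key=lambda v: (-succ[v], v))
        retained[state] = (best, succ[best])
    return FilteredGraph(states=graph.states, retained=retained)


def _cycle_sequence(core: frozenset, successor: dict[int, int]) -> tuple[int, ...]:
    start = min(core)
    seq = [start]
    node = successor[start]
    while node != start:
        seq.append(node)
        node = successor[node]
    return tuple(seq)


def analyze(graph: TransitionGraph | FilteredGraph) -> GraphAnalysis:
    """Structural analysis of a transition graph.

    * leaves: states with no predecessors (in-degree 0, self-loops count as
      predecessors);
    * absorbing: states whose retained transitions all self-loop;
    * cores: closed communicating classes — strongly connected components
      with no edge leaving the component (singletons only when self-looped);
    * sinks: states with no outgoing transitions, reported distinctly;
    * on a filtered graph additionally the disjoint cycles (cores of size
      >= 2, listed from their smallest state) and the maximal transient: the
      largest number of transitions from a leaf until a core or sink is
      reached.
    """
    g = graph.to_networkx()
    leaves = tuple(sorted(n for n in g.nodes if g.in_degree(n) == 0))
    sinks = tuple(sorted(n for n in g.nodes if g.out_degree(n) == 0))
    absorbing = tuple(
        sorted(
            n
            for n in g.nodes
            if g.out_degree(n) >= 1 and set(g.successors(n)) == {n}
        )
    )
    cores = []
    for scc in nx.strongly_connected_components(g):
        closed = all(v in scc for u in scc for v in g.successors(u))
        nontrivial = len(scc) > 1 or g.has_edge(next(iter(scc)), next(iter(scc)))
        if closed and nontrivial:
            cores.append(frozenset(scc))
    cores.sort(key=min)

    cycles = None
    max_transient = None
    if isinstance(graph, FilteredGraph):
        successor = graph.successor
        cycles = tuple(
            _cycle_sequence(core, successor) for core in cores if len(core) >= 2
        )
        targets = set().union(*cores) if cores else set()
        targets |= set(sinks)
        transients = []
        for leaf in leaves:
            steps = 0
            node = leaf
            while node not in targets:
                node = successor[node]
                steps += 1
            transients.append(steps)
        max_transient = max(transients) if transients else None
    return GraphAnalysis(
        leaves=leaves,
        absorbing=absorbing,
        cores=tuple(cores),
        sinks=sinks,
        cycles=cycles,
        max_transient=max_transient,
    )
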