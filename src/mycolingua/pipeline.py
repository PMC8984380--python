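"""End-to-end pipeline: simulate/read -> detect -> characterize -> words ->
machine -> complexity, with a reproducible run manifest.

A run writes a fixed-name report bundle into one directory:

* ``recording.csv`` (only when simulated), ``spikes.tsv``, ``isi_summary.tsv``
* ``sentences_theta{1,2}.txt``
* ``graph_theta{m}.tsv`` / ``.dot``, ``graph_theta{m}_filtered.tsv``,
  ``analysis_theta{m}.json``
* ``complexity.tsv`` (both theta multipliers x both encodings)
* ``manifest.json`` — parameters, seed and package version; a manifest plus
  the package suffices to reproduce the bundle byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError, UsageError, ValidationError
from .complexity import complexity_report
from .linguistics import (
    Sentence,
    concatenate_sentences,
    length_distribution,
    segment_words,
    theta_from_train,
)
from .signal_io import (
    Recording,
    read_recording,
    write_graph,
    write_recording,
    write_sentences,
    write_spike_table,
)
from .spike_characterization import fill_widths, isi_summary
from .spike_detection import (
    SPECIES_DETECTION_PARAMS,
    DetectionParams,
    detect_spikes,
    trains_to_table,
)
from .spiking_machine import GraphAnalysis, analyze, estimate_machine, filter_max
from .synthetic_data import SPECIES_PRESETS, generate_recording


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    species: str | None = "schizophyllum"
    w: int | None = None
    delta: float | None = None
    d: int | None = None
    theta_multipliers: tuple[int, ...] = (1, 2)
    encodings: tuple[tuple[str, int], ...] = (("filter", 9), ("cap", 255))
    duration_days: float = 1.5
    n_channels: int = 2
    seed: int = 0
    out_dir: str = "run"

    def __post_init__(self) -> None:
        for m in self.theta_multipliers:
            if m not in (1, 2):
                raise ValidationError(f"theta multiplier must be 1 or 2, got {m}")
        for mode, cap in self.encodings:
            if mode not in ("filter", "cap"):
                raise ValidationError(f"unknown encoding mode {mode!r}")
            if cap not in (9, 255):
                raise ValidationError(f"cap must be 9 or 255, got {cap}")
        if self.species is None and None in (self.w, self.delta, self.d):
            raise ValidationError("give a species or explicit w/delta/d")
        if self.species is not None and self.species not in SPECIES_DETECTION_PARAMS:
            raise UsageError(f"unknown species {self.species!r}")

    @property
    def detection_params(self) -> DetectionParams:
        if self.w is not None and self.delta is not None and self.d is not None:
            return DetectionParams(w=self.w, delta=self.delta, d=self.d)
        return SPECIES_DETECTION_PARAMS[self.species]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "theta_multipliers" in data:
            data["theta_multipliers"] = tuple(data["theta_multipliers"])
        if "encodings" in data:
            data["encodings"] = tuple((m, int(c)) for m, c in data["encodings"])
        return cls(**data)


def _analysis_to_dict(analysis: GraphAnalysis) -> dict:
    return {
        "leaves": list(analysis.leaves),
        "absorbing": list(analysis.absorbing),
        "cores": [sorted(core) for core in analysis.cores],
        "sinks": list(analysis.sinks),
        "cycles": None
        if analysis.cycles is None
        else [list(c) for c in analysis.cycles],
        "max_transient": analysis.max_transient,
    }


def run_pipeline(config: PipelineConfig, input: str | Path = "simulate") -> dict:
    """Run every stage and write the report bundle; returns a summary dict.

    Any stage error aborts with a :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.detection_params

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # 1. input
    if str(input) == "simulate":
        if config.species is None:
            raise PipelineError("stage 'input' failed: simulation needs a species")
        recording, _truth = stage("simulate")(
            generate_recording,
            SPECIES_PRESETS[config.species],
            config.duration_days * 86400.0,
            seed=config.seed,
            n_channels=config.n_channels,
        )
        stage("simulate")(write_recording, recording, out / "recording.csv")
    else:
        recording = stage("read")(read_recording, input)

    # 2. detection
    trains = stage("detect")(detect_spikes, recording, params)
    for label, train in trains.items():
        stage("characterize")(fill_widths, recording.channel(label), train)
    stage("detect")(write_spike_table, trains_to_table(trains), out / "spikes.tsv")

    # 3. characterization
    summaries = [isi_summary(t) for t in trains.values()]
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(
        out / "isi_summary.tsv", sep="\t", index=False
    )

    # 4-6. words, machines, complexity per theta multiplier
    complexity_rows = []
    summary: dict = {"channels": list(trains), "n_spikes": {c: len(t) for c, t in trains.items()}}
    for m in config.theta_multipliers:
        sentences = []
        for label, train in trains.items():
            if len(train) < 2:
                sentences.append(Sentence((), theta=None, channel=label))
                continue
            theta = theta_from_train(train, m)
            sentences.append(segment_words(train, theta))
        stage("words")(write_sentences, sentences, out / f"sentences_theta{m}.txt")
        pooled = concatenate_sentences(
            [s for s in sentences if len(s)], channel="pooled"
        )
        dist = length_distribution(pooled)
        summary[f"mean_word_length_theta{m}"] = dist.mean_length_2dp

        graph = stage("machine")(estimate_machine, [s for s in sentences if len(s) >= 2])
        filtered = filter_max(graph)
        stage("machine")(write_graph, graph, out / f"graph_theta{m}.tsv", "tsv")
        stage("machine")(write_graph, graph, out / f"graph_theta{m}.dot", "dot")
        stage("machine")(
            write_graph, filtered, out / f"graph_theta{m}_filtered.tsv", "tsv"
        )
        analyses = {
            "probabilistic": _analysis_to_dict(analyze(graph)),
            "filtered": _analysis_to_dict(analyze(filtered)),
        }
        with open(out / f"analysis_theta{m}.json", "w") as fh:
            json.dump(analyses, fh, indent=2, sort_keys=True)
        summary[f"analysis_theta{m}"] = analyses

        for mode, cap in config.encodings:
            report = stage("complexity")(complexity_report, pooled, cap=cap, mode=mode)
            complexity_rows.append(
                {
                    "theta_multiplier": m,
                    "mode": mode,
                    "cap": cap,
                    **{
                        k: getattr(report, k)
                        for k in (
                            "shannon_entropy",
                            "second_order_entropy",
                            "lz_phrases",
                            "lz_bits",
                            "lz_bits_normalized",
                            "input_length",
                        )
                    },
                }
            )
    pd.DataFrame(complexity_rows).to_csv(out / "complexity.tsv", sep="\t", index=False)

    manifest = {
        "package": "mycolingua",
        "version": __version__,
        "seed": config.seed,
        "input": str(input),
        "config": {
            "species": config.species,
            "w": params.w,
            "delta": params.delta,
            "d": params.d,
            "theta_multipliers": list(config.theta_multipliers),
            "encodings": [list(e) for e in config.encodings],
            "duration_days": config.duration_days,
            "n_channels": config.n_channels,
        },
        "outputs": sorted(
            p.name for p in out.iterdir() if p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    summary["manifest"] = manifest
    return summary
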