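# mycolingua

Spike detection and linguistic/complexity analysis of fungal extracellular
electrical activity.

Fruiting fungi such as *Schizophyllum commune* (split gill), *Flammulina
velutipes* (enoki), *Cordyceps militaris* (caterpillar fungus) and
*Omphalotus nidiformis* (ghost fungus) produce trains of action-potential-like
spikes of extracellular potential, recordable at 1 Hz with pairs of
differential electrodes inserted into colonized substrate or sporocarps.
This package is for researchers who want to take such multichannel mV
recordings (or seeded synthetic stand-ins) through a complete,
tested analysis chain:

1. **Spike detection.** For each sample `x_i` a neighbourhood baseline
   `a_i = (4w)^-1 * Σ_{i-2w ≤ j ≤ i+2w} x_j` is computed; index `i` is a
   candidate peak iff `|x_i| − |a_i| > δ`; candidates closer than `d` samples
   are de-duplicated keeping the most prominent peak. Species presets:
   `w=200, δ=0.1 mV, d=300` (*C. militaris*, *F. velutipes*),
   `w=100, δ=0.005, d=100` (*S. commune*), `w=50, δ=0.003, d=100`
   (*O. nidiformis*).
2. **Characterization.** Inter-spike-interval and amplitude summaries,
   half-prominence spike widths, wave-packet (burst) segmentation with a
   rise–fall shape score, and one-to-one synchronization matching of spikes
   across neighbouring channels.
3. **Linguistics.** Spike trains become binary strings; consecutive spikes
   with gaps ≤ θ form a *word* (θ = 1× or 2× the mean inter-spike interval);
   each channel yields a *sentence* of word lengths. Word-length histograms
   are fitted with the length–frequency law `f(l) = β · l^c · γ^l` (free and
   γ = 0.73 constrained fits).
4. **Spiking machines.** A probabilistic finite-state machine over word
   lengths is estimated from consecutive word pairs; its transition graph is
   analyzed for Garden-of-Eden (leaf) states, absorbing states, attractive
   cores (closed communicating classes), cycles of the max-weight-filtered
   graph and the longest leaf-to-core transient.
5. **Complexity.** Shannon entropy, second-order (circular pair block)
   entropy and Lempel–Ziv 1976 phrase counts with a documented bits
   conversion, over byte-capped (alphabet 256) or ≤9-spike-filtered
   (alphabet 9) encodings. An algorithmic-complexity backend (e.g. a
   block-decomposition estimator) can be plugged in; none ships by default.

A seeded synthetic-recording generator reproduces the statistical structure
the analysis assumes (species-specific rates and amplitudes, drift and noise,
rise–fall wave packets, lag-scheduled channel pairs) and provides ground
truth for every stage.

## Worked example

One command simulates a 1.5-day two-channel split-gill recording and runs
every stage:

```sh
mycolingua run --species schizophyllum --days 1.5 --seed 7 --out-dir demo
```

`demo/isi_summary.tsv` then holds the per-channel spiking statistics:

```
channel  n_spikes  mean_interval_min  sd_interval_min  mean_amplitude_mv  sd_amplitude_mv
1-2      52        41.44              38.16            0.0315             0.0081
3-4      57        36.93              34.34            0.0325             0.0100
```

i.e. the detector recovered the preset's ~41-minute mean inter-spike interval
and ~0.03 mV mean amplitude. `demo/sentences_theta1.txt` holds one sentence
per channel (θ = mean ISI, here ≈ 2486 s and ≈ 2216 s):

```
channel  theta               word_lengths
1-2      2486.3529411764707  1 4 1 6 1 2 6 2 3 3 2 4 1 1 1 1 4 1 3 4 1
3-4      2215.625            6 2 9 1 2 3 1 1 2 1 1 3 7 2 4 1 1 1 2 2 4 1
```

`demo/analysis_theta1.json` reports that the max-weight-filtered spiking
machine has the single absorbing state `1` (a machine wandering the
word-length graph eventually settles on one-spike words), leaves `3, 6, 7, 9`
and a maximal transient of 3 transitions. `demo/complexity.tsv` gives, for
the pooled θ = a sentence in the 9-symbol filtered encoding, a Shannon
entropy of 2.28 bits, second-order entropy of 3.98 bits and 18 LZ76 phrases
(132.1 bits, 3.07 bits/symbol).

Every subcommand (`simulate`, `detect`, `characterize`, `sync`, `words`,
`machine`, `complexity`) is also available separately; `mycolingua run
--config run.yaml` reads the same settings from YAML, and `manifest.json` in
the output bundle pins parameters, seed and version so a run can be
reproduced byte-identically.

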