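# Methods

This note documents the models, conventions and numerical choices behind
mycolingua, and what the synthetic benchmarks do and do not establish about
real recordings.

## Spike detection

The detector operates on 1 Hz single-channel traces in mV. The baseline at
index `i` is the mean of the symmetric neighbourhood of `4w + 1` samples,
with the divisor kept at `4w`:

    a_i = (4w)^-1 * Σ_{i-2w ≤ j ≤ i+2w} x_j .

The divisor is retained verbatim from the detection rule this package
implements, so the baseline is biased high by a relative factor
`1/(4w)` (0.125–0.5 %, far below the threshold scale). Index `i` is a
candidate peak iff `|x_i| − |a_i| > δ`. Indices whose window does not fit
(`i < 2w` or `i ≥ n − 2w`) are excluded entirely rather than padded: the
formula is undefined there and padding would manufacture edge spikes.

De-duplication visits candidates in (prominence descending, index ascending)
order and keeps a candidate iff it lies at least `d` samples from every
already-kept peak ("distance `d`" is read strictly: conflicts are `< d`).
Consequences, asserted in tests: retained peaks are pairwise ≥ `d` apart,
every removed candidate is within `d` of a retained peak, and ties go to the
earlier index.

Because the decision statistic uses absolute values, a negative-going spike
riding on a positive baseline (or vice versa) can be suppressed. The
`signed=True` variant replaces the statistic with `|x_i − a_i|`; it is an
extension, off by default, and none of the published-value comparisons use
it.

## Characterization conventions

* **ISI summary.** Intervals are successive peak differences, reported in
  minutes; standard deviations use the sample convention (ddof = 1);
  interval fields are absent for trains with fewer than two spikes.
* **Spike width.** The measurement of spike "duration" is not defined by the
  source analysis, so the package fixes a half-prominence convention: the
  width is the length of the maximal contiguous run around the peak on which
  `|x_j| − |a_j|` stays above half the peak's prominence. For a spike on a
  flat baseline with a wide window this coincides with the full width at
  half maximum. Runs touching the window-valid boundary are flagged
  censored. Published duration values are therefore not comparison surfaces.
* **Wave packets** are maximal runs of spikes with successive gaps at or
  below a threshold (default: the train's mean ISI, the same spirit as the
  θ word rule) and at least 3 spikes. The rise–fall score smooths the
  amplitude (or width) profile with a centred 3-point mean and requires the
  maximum strictly inside the packet with a non-decreasing/non-increasing
  flank on either side.
* **Synchronization.** Matching between two channels is one-to-one and
  chronological (non-crossing), pairs only spikes within `max_lag`
  (default 1800 s, half the fastest species' mean ISI), maximizes the number
  of pairs and, among such matchings, minimizes the total absolute lag. A
  dynamic program over both trains computes this exactly; for sorted trains
  a non-crossing optimum always attains the global optimum (rearrangement
  inequality for `|·|`). A one-pass greedy was considered and rejected: it
  attains maximum cardinality but not always minimum total lag, making it
  needlessly sensitive to near-threshold coincidences.

## Words, sentences and the length law

The gap between spikes is the difference of their peak indices and the word
rule is inclusive (`gap ≤ θ` keeps spikes in one word). θ defaults to 1× or
2× the train's mean ISI. Conservation (word lengths sum to the spike count)
is asserted on every segmentation. Species-level statistics pool channels by
concatenating per-channel sentences in channel order; pooling is a
documented switch, not a hidden default, because the alternative
(per-channel averaging) is equally defensible.

The word-length histogram is fitted with the three-parameter family
`f(l) = β · l^c · γ^l`, which covers every consistent reading of the
published length–frequency law; the γ = 0.73 constrained two-parameter
variant is reported alongside. The model is log-linear, so the fit is
initialized by exact least squares in log space and refined by bounded
nonlinear least squares on the raw counts; it requires at least three
distinct observed lengths. On noiseless model-generated counts the
parameters are recovered to 1e-6; under Poisson noise at ~5000 words the
exponent `c` is recovered with median absolute error below 0.1.

## Spiking machines

Transition counts come from consecutive word pairs within a sentence (pairs
never span channel boundaries); probabilities are row-normalized counts and
row-stochasticity is validated to 1e-9. States observed only sentence-finally
have no outgoing transitions and are reported as sinks, not coerced into
self-loops.

"Attractive core" is formalized as a closed communicating class: a strongly
connected component with no edge leaving it (singletons only when
self-looped). This is the unique standard object matching "once entered,
never left". Cores are computed on whichever graph is supplied —
probabilistic or max-weight-filtered — since the source analysis is
ambiguous about which was used; the pipeline reports both. Cycle
enumeration and the maximal leaf-to-core transient are defined only on the
filtered graph, where out-degree ≤ 1 makes cycles disjoint and paths unique.
Ties in max-weight filtering go to the smaller word length (deterministic
and reproducible; the choice is otherwise unconstrained).

## Complexity measures

* **Shannon entropy** is the plug-in estimate over empirical symbol
  frequencies, in bits.
* **Second-order entropy** is the block entropy of overlapping ordered
  pairs, taken *circularly* (the last symbol wraps to the first). With
  circular pairs the pair marginals equal the symbol distribution exactly,
  so `H₂ ≤ 2·H₁` holds for every finite string and an even-length
  alternation scores exactly 1 bit; with the usual `n−1` pairs both
  properties fail on short strings by edge effects. Values exceed the
  first-order entropy on structured strings, consistent with a pair block
  entropy (a conditional entropy could not exceed `H₁`).
* **LZ76** is the exhaustive-history factorization: each phrase is the
  shortest prefix of the remainder not reproducible from the preceding
  history (the copy source may extend into the phrase); the final phrase may
  be reproducible. The bits figure `phrases · (log₂ phrases + log₂ alphabet)`
  is this package's documented upper-bound encoding (one history position
  plus one fresh symbol per phrase); published LZ bit values rest on an
  unspecified encoding and are not comparison surfaces, but phrase counts
  are verified against an independent pointer-based reference parser.
* **Encodings.** `cap` clamps word lengths at 255 over the byte alphabet
  (256); `filter` drops words longer than 9 spikes and declares a 9-symbol
  alphabet while keeping the raw lengths 1–9 as symbols (the declared size
  bounds the number of distinct codes and sets the per-symbol cost).
* **Algorithmic complexity** (block-decomposition style) requires external
  precomputed small-machine frequency tables with no closed form; the report
  exposes a backend hook and ships none, rather than shipping unverifiable
  numbers.

## Synthetic recordings

The generator emulates what the analysis assumes about real recordings:

* **Spike times** are a renewal process with exponential gaps at the
  species' mean ISI (116, 102, 41 and 92 minutes for the caterpillar, enoki,
  split gill and ghost fungus presets). No generative model is published for
  the recordings; a renewal process is the minimal structure reproducing the
  interval statistics.
* **Spike shape** is a Gaussian bump of σ ≈ `w/3` seconds (±20 % jitter),
  scaled by lognormal amplitudes around the preset mean (0.2, 0.3, 0.03,
  0.007 mV). The default amplitude coefficient of variation is 0.25: large
  enough to exercise the amplitude statistics, small enough that essentially
  all spikes clear the species' detection threshold. Real recordings show
  considerably larger amplitude spread (sd comparable to the mean for the
  high-amplitude species); `amplitude_cv` exposes that regime, in which
  threshold censoring makes mean-amplitude recovery systematically biased —
  passing the default-condition tests therefore does not show that amplitude
  statistics are unbiased on real data.
* **Baseline drift** is a mean-reverting (Ornstein–Uhlenbeck) walk with
  stationary sd `δ/3` and correlation time `16w` s — slow relative to the
  averaging window, so the baseline subtraction can track it. An unbounded
  random walk was rejected: the absolute-value statistic `|x| − |a|`
  degrades once the baseline wanders below minus half the spike amplitude,
  which is a genuine limitation of the detector on strongly drifting
  recordings, not of the generator.
* **Measurement noise** is white Gaussian, default sd `δ/10`.
* **Wave packets** add spikes at a fixed intra-packet ISI whose amplitudes
  and widths follow a symmetric half-sine rise–fall template.
* **Paired channels** repeat channel A's spikes at per-spike scheduled lags
  plus Gaussian jitter, supporting decreasing-lag schedules.

Everything is driven by one seeded numpy Generator: the same seed gives
bit-identical output.

What the closed-loop tests show: on signals with these statistics the
detector attains ≥ 95 % recall and precision (clean benchmark: prominence
≥ 3δ, separation ≥ max(2d, 4w), noise ≤ δ/5), the full pipeline recovers
preset mean ISI and amplitude within 3 standard errors at 5 recording days,
and every downstream stage equals its independent oracle. What they do not
show: robustness to mV-scale drift, non-renewal spike timing, asymmetric or
multiphasic spike shapes, or heavy-tailed amplitudes — real-data features
the generator deliberately does not model.

Known small biases under the default conditions, measured and accepted
rather than hidden: detected mean amplitude sits slightly high (threshold
censoring of the lognormal low tail, max-prominence selection over the noise
field, drift at the peak — together ≈ +5–10 % of the spike amplitude for the
high-threshold presets), and detected mean ISI sits ≈ +4 % high where
exponential gaps shorter than `d` are merged by de-duplication.

## Problem sizes

The shipped suites use: 100 seeded signals (96 of 10⁴ and 4 of 10⁵ samples)
for detector–oracle equivalence; 10 benchmark runs of 30 spikes for
recall/precision; 1000 random trains for segmentation; a 10⁴-step sentence
and 200 random ≤ 10-state functional graphs for the machine; 500 random
strings of ≤ 64 symbols for LZ76; and one 5-day recording per species for
end-to-end recovery. The acceptance script additionally runs the per-species
recovery at study scale (8 channels; 1.5 days for the split gill, 5 days
otherwise), which keeps the relative standard error of the recovered mean
ISI near 5 %.
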