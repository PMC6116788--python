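# Methods

## Model overview

The package simulates *liquids*: sparse random recurrent networks of
excitatory (e) and inhibitory (i) leaky integrate-and-fire neurons driven by
an input layer through plastic synapses. Training is unsupervised — STDP on
the input → e synapses sensitizes individual excitatory neurons to recurring
input structure — and inference reads the class directly off the spike counts
of class-tagged neurons. An ensemble (SpiLinC) splits the input across
several independent liquids and averages their per-class spike-count means.

## Neuron model

Current-based LIF with adaptive threshold. State per neuron: membrane
potential `v_mem`, adaptive threshold offset `theta_adapt`, refractory timer,
excitatory and inhibitory post-synaptic currents. All decays are exact
exponential updates per step (`x ← x·exp(−dt/τ)`), so the update commutes
with step splitting and carries no Euler step-size error; the test suite
asserts one step of `dt` equals two steps of `dt/2` to 1e−9.

Per-step order (step `t` carries time stamp `t·t_step`):

1. input spikes for step `t` are drawn (Bernoulli per neuron per step);
2. spikes emitted at step `t−1` are delivered through the weighted masks into
   the post-synaptic currents (one-step delay; this breaks same-step
   causality cycles in the recurrent graph deterministically; simultaneous
   pre-spikes sum linearly);
3. all state variables decay;
4. currents integrate into the potential: `v_mem += i_exc − i_inh`
   (weights are dimensionless "current per step" units — the model has no
   physical current scale);
5. threshold test `v_mem > theta_base + theta_adapt` gated by the refractory
   timer; spiking neurons reset, raise `theta_adapt` by `theta_plus`
   (training mode) and start their refractory period;
6. training mode: STDP at the post-spike instants (below).

Defaults (all configurable; times ms, potentials mV): excitatory —
τ_mem = 100, V_rest = V_rst = −65, θ_base = −52, θ+ = 0.05, τ_θ = 1e7,
t_ref = 5; inhibitory — τ_mem = 10, V_rest = −65, V_rst = −45, θ_base = −40,
t_ref = 2, fixed threshold (θ+ = 0). Synaptic current time constants 2 ms
(excitatory) and 1 ms (inhibitory) for both populations. These are the
standard values of the two-layer unsupervised-SNN lineage this architecture
family builds on. The adaptive threshold applies to excitatory neurons only:
homeostasis is what equalizes firing across the competing excitatory
population; inhibitory neurons need no such competition.

Between pattern presentations the potentials, currents, refractory timers and
pre-spike caches reset; the adaptive thresholds persist across the whole
training phase (that is what accumulates the homeostatic pressure) and are
frozen — neither incremented nor decayed — during testing.

## Plasticity

Power-law weight-dependent STDP, evaluated only at excitatory post-spike
instants and only for input synapses whose input has spiked within the
current presentation:

    Δw = η · [exp(−(t_post − t_pre)/τ) − offset] · (w_max − w)^μ

with nearest-neighbor pairing (the most recent pre-spike per synapse).
Depression of uncorrelated synapses emerges from the offset term; the same
soft-bound factor `(w_max − w)^μ` scales both signs, and updates are hard
clipped to `[w_min, w_max]`. The rule changes sign at
`t_post − t_pre = −τ·ln(offset)`; with the image parameters
(τ = 15 ms, offset = 0.4) that is ≈ 13.74 ms, and with offset = 0 (temporal
task) no weight is ever depressed.

Task defaults: temporal/speech η = 0.0001, offset = 0; image η = 0.005,
offset = 0.4; both τ = 15 ms, μ = 0.9, w ∈ [0, 1]. Recurrent weights are
fixed scalars per projection (e→e 1, e→i 10 image / 3 speech, i→e 1, i→i 1)
and never learn.

## Topology

Connectivity between any two neuron groups is Bernoulli: a uniform(0, 1)
matrix thresholded at `percent/100`. Plastic input weights initialize
uniformly ([0.003, 0.303] image, [0.005, 0.505] speech). Connection
percentages: image 30% input→e (50% per ensemble liquid), speech 25%;
recurrent e→e/i→i 0.5–1%, e→i 5%, i→e 20–30%. Self-connections are permitted
in the e→e and i→i masks (the group-by-group Bernoulli construction does not
exclude the diagonal). The expected synapse count
`Σ (p/100)·n_pre·n_post` is reported as the (possibly fractional) Bernoulli
mean; realized networks report their actual mask counts separately.

Ensemble input partitions: images split into left/right column halves (each
`width/2 + overlap/2` wide, 4 shared columns by default; a four-liquid
ensemble adds the top/bottom row halves); channel inputs split into blocks of
`ceil(channels/n_liquids) + overlap` consecutive channels, spaced so the
first block starts at channel 0 and the last ends at the top channel. Two
30-channel blocks of a 39-channel input therefore share 21 channels — with
2×30 > 39 the "distinct channel groups" cannot be disjoint. Effective
(unpruned) synapses are counted as mask-supported weights above a threshold
ε, default 0.01·w_max — small enough that only synapses STDP has driven to
the floor (e.g. those from background pixels) fall below it.

## Encoding

Images: rate coding, `rate = intensity·63.75/255` spikes/s held constant over
a 350 ms presentation; probability per 0.5 ms step is `rate/1000·t_step`.
Temporal matrices: intensities are normalized by the *sample's* global
maximum (one scalar per sample, the natural reading of normalizing "with
respect to the maximum intensity"; per-step normalization is a configurable
alternative) and used as per-step firing probabilities over a 750 ms
presentation, resampled onto the 0.5 ms grid by zero-order hold — the
simplest contract given that cochleagram frame rates vary. Spike draws are
independent Bernoulli per neuron per step.

## Inference

Each excitatory neuron with nonzero cumulative training spikes is tagged with
its top-1 (images) or top-2 (temporal) classes by cumulative training spike
count; classes with fewer training presentations are not rebalanced, and a
two-tag neuron contributes its full test spike count to both of its groups.
Per class `j`, `avg(j)` is the mean spike count of the neurons tagged `j`
(0 for an empty group); the ensemble-resultant average divides the sum of
per-liquid averages by the number of liquids even when some liquid has no
neurons with that tag. Argmax ties resolve to the lowest class index with a
logged warning, for reproducibility. Labels enter only this bookkeeping —
the weight updates never see them.

## Synthetic data

The generator provides desk-scale datasets with the statistical structure
the method assumes, for both modalities, so every stage is testable without
external corpora.

*Images* (default 12×12, 4 classes): distinct deterministic binary glyphs
(left bar, top bar, diagonal and anti-diagonal bands, thin frame, center
cross) at intensity 255 on background 0, constructed so any two templates
share fewer than half of their active pixels; samples flip each pixel
independently with probability `noise_level` (default 0.1).

*Temporal matrices* (default 20 channels × 100 frames, 4 classes):
hard-edged channel supports built from sixths of the channel axis such that
any two class supports differ in at least half the channels — rising/falling
sweeps clipped to the bottom/middle third, a pulsing top-third band, pulsing
even/odd-sixth combs in antiphase, a full-range V sweep. Samples apply
multiplicative Gaussian intensity noise (sd = `noise_level`) and a circular
temporal jitter of up to `0.2·noise_level·frames` frames.

Templates are deterministic functions of (class index, shape), so tests can
reference them; a nearest-template classifier achieves 100% on noiseless
samples and stays above 90% at noise 0.15, which bounds what the liquid can
be asked to learn. What the generator does *not* emulate: the visual
variability of handwritten digits, speaker/phonetic variability of real
speech, correlated (non-independent) pixel noise, variable utterance
lengths. Passing the learning study therefore demonstrates that the
machinery — encoding, dynamics, plasticity, tagging, ensemble combination —
learns and generalizes over its stated noise model, not that it reaches any
particular accuracy on real corpora.

## Study sizes and numerical choices

The scaled-down learning study uses a 400-neuron liquid (320e/80i) and a
two-liquid ensemble of 200-neuron liquids on the 4-class 12×12 image set,
2,000 training presentations (a 40-sample pool cycled in order), held-out
evaluation on 40 freshly drawn samples; the temporal run uses a 320-neuron
liquid (240e/80i, 3:1) and 400 presentations. These sizes train in minutes
on one CPU while leaving the learning signal far from floor or ceiling.

All randomness flows through explicitly seeded generators: topology
generation, input spike sampling (one stream per liquid, derived from the
schedule seed) and dataset synthesis are independently seeded, so full runs
are bit-reproducible and checkpoints store the sampling RNG state for exact
resumption. Degenerate inputs are defined, not special-cased: an all-zero
intensity matrix encodes to zero probabilities, empty tag groups score 0,
and a probability-0 input yields an empty raster.

## Known limitations

- Conductance-based synapses, axonal delays beyond the uniform one-step
  delay, and sub-millisecond adaptive solvers are out of scope.
- The cochlear front-end is consumed, not computed: temporal inputs must
  arrive as channel × time intensity matrices.
- No supervised readout layer; accuracy on hard real-world corpora is known
  to benefit from one, and this package deliberately stops at the
  readout-free architecture.
- The engine is single-threaded; ensemble liquids are independent, so
  process-level parallelism is the caller's concern.
- One published observation — that swapping the synaptic time constants
  raises excitatory test-phase rates specifically — has no stated mechanism;
  no train/test change of time constants is implemented.
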