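# spilinc

Unsupervised liquid-computing spiking neural networks: single sparse random
liquids (Liquid-SNN) and liquid ensembles (SpiLinC) whose input synapses
self-organize with spike-timing-dependent plasticity, classifying speech-like
and image-like inputs directly from tagged spike counts — no supervised
readout layer.

## Who this is for

Researchers in neuromorphic computing and computational neuroscience who want
a tested, deterministic reference implementation of readout-free liquid state
machines: leaky integrate-and-fire liquids with fixed sparse recurrent
connectivity, plastic input synapses, homeostatic thresholds, Poisson rate
coding of images and cochleagram-style channel × time matrices, and
spike-count ensemble inference — runnable end to end on built-in synthetic
datasets with no external corpus.

## The model

**Neurons.** Current-based leaky integrate-and-fire with exact exponential
updates. Excitatory and inhibitory post-synaptic currents decay with
τ_syn,e = 2 ms and τ_syn,i = 1 ms; the membrane potential leaks toward
V_rest and integrates the net current; a neuron fires when
V_mem > θ_base + θ_adapt, then resets to V_rst, raises its adaptive threshold
by θ+ (homeostasis, excitatory neurons only) and is refractory for t_ref.

**Plasticity.** Power-law weight-dependent STDP on the input → excitatory
synapses only, applied at every post-spike and paired with the most recent
pre-spike per synapse:

    Δw = η · [exp(−(t_post − t_pre)/τ) − offset] · (w_max − w)^μ

Tight pre/post correlation potentiates; stale correlations depress (for
offset > 0). With the temporal-task parameters (offset = 0) weights are never
depressed. Recurrent liquid weights stay fixed.

**Encoding.** Pixel intensities in [0, 255] map to Poisson rates in
[0, 63.75] spikes/s (rate = intensity/4); the per-step firing probability is
rate/1000 · t_step with t_step = 0.5 ms, so a saturated pixel fires with
probability 0.031875 per step. Channel × time matrices are normalized by
their maximum intensity and used directly as per-step probabilities.

**Inference.** After unsupervised training, each excitatory neuron is tagged
with the class(es) that drove it most (1 tag for images, 2 for temporal
inputs). A test pattern is classified by the tag group with the highest
average spike count,

    avg(j) = (1/n_j) Σ_k spike_count(k, j),   predicted = argmax_j avg(j),

and an ensemble averages the per-liquid group means before the argmax. Each
liquid of an ensemble sees one (possibly overlapping) input segment; there
are no synapses between liquids.

**Synapse accounting.** The expected synapse count of one liquid is

    #synapses = Σ over projections of (p/100) · n_pre · n_post

summed over input→e, e→e, e→i, i→e and i→i, times the number of liquids for
an ensemble; the sparsity ratio of two architectures is the ratio of their
counts.

## Worked example

```
$ spilinc generate --seed 1 --set synthetic.samples_per_class=4 --out demo/data
wrote 16 samples (4 classes) to demo/data

$ spilinc train --seed 1 --set synthetic.samples_per_class=4 \
    --set liquid.n_e=160 --set liquid.n_i=40 \
    --set schedule.n_examples=400 --data demo/data --out demo/ckpt
trained 1 liquid(s) for 400 presentations -> demo/ckpt

$ spilinc generate --seed 2 --set synthetic.samples_per_class=4 --out demo/test
$ spilinc evaluate --checkpoint demo/ckpt --data demo/test --out demo/metrics
accuracy: 100.00% over 16 test samples -> demo/metrics
```

A 200-neuron liquid (160 excitatory, 40 inhibitory) trains unsupervised for
400 presentations of 12×12 four-class glyph images and classifies 16 fresh
noisy samples perfectly; `demo/metrics/metrics.txt` also lists per-class
false-negative and false-positive percentages (all 0 here). The `report`
command prints expected synapse counts; at the published 12,800-neuron image
architecture:

```
$ spilinc report --preset image --set liquid.n_e=10240 \
    --set liquid.n_i=2560 --set 'synthetic.input_shape=[28,28]'
single_liquid_synapses: 12697600.0
sparsity_ratio: 1.0
```

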