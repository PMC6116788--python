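"""Clock-driven simulation of liquids: presentation, training, checkpoints.

Per-time-step contract (documented order, one step = ``t_step`` ms; step ``t``
carries the time stamp ``t * t_step``):

1. Input spikes for step ``t`` are drawn from the encoded firing
   probabilities; in training mode each spiking input's "last pre-spike time"
   is recorded for STDP pairing.
2. Spikes emitted at step ``t - 1`` (inputs and liquid neurons alike) are
   delivered through the weighted masks into the post-synaptic currents
   (one-step axonal delay; simultaneous pre-spikes sum linearly).
3. All state variables decay exactly (exponential updates).
4. Currents are integrated into the membrane potentials
   (``v += i_exc - i_inh``).
5. Threshold test: spiking neurons reset, raise their adaptive threshold
   (training mode) and enter their refractory period.
6. Training mode only: at every excitatory post-spike, the plastic input
   weights of the spiking neurons are updated by the STDP rule, pairing each
   with the most recent pre-spike per input synapse.

Membrane potentials, synaptic currents, refractory timers and the pre-spike
cache reset between presentations; the adaptive thresholds persist across the
whole training phase and are frozen (neither incremented nor decayed) during
testing. Recurrent weights are fixed; only input->excitatory synapses learn.
The class labels supplied during training feed the per-neuron per-class spike
bookkeeping used for tagging and never influence the weight update.

The inner loop is vectorized in-place for speed; it implements exactly the
update rules of :mod:`spilinc.dynamics` and :mod:`spilinc.plasticity` (the
test suite replays it against a scalar step-by-step simulator).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from .dynamics import LIFParams
from .encoding import EncodedInput, T_STEP
from .plasticity import STDPParams
from .topology import (EnsembleConfig, LiquidTopology, build_liquid,
                       load_topology, save_topology)

__all__ = ["SpikeRecord", "TrainingSchedule", "Liquid", "LiquidEnsemble",
           "present_pattern", "train", "slice_encoded",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class SpikeRecord:
    """Spiking activity of one neuron population over one presentation."""

    raster: np.ndarray        # (n_neurons, n_steps) bool
    t_step: float = T_STEP

    @property
    def spike_count(self) -> np.ndarray:
        """Per-neuron total spike count over the presentation."""
        return self.raster.sum(axis=1)

    @property
    def duration(self) -> float:
        return self.raster.shape[1] * self.t_step

    def spike_times(self, neuron: int) -> np.ndarray:
        """Spike times (ms) of one neuron, strictly increasing."""
        return np.flatnonzero(self.raster[neuron]) * self.t_step

    def mean_rate(self) -> float:
        """Population-mean firing rate in spikes/s."""
        return float(self.raster.sum() / self.raster.shape[0]
                     / (self.duration / 1000.0))


@dataclass(frozen=True)
class TrainingSchedule:
    """How many patterns to present (cycling through the dataset in order)
    and the seed for input spike sampling."""

    n_examples: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_examples < 1:
            raise ValueError("n_examples must be >= 1")


def slice_encoded(enc: EncodedInput, indices: np.ndarray) -> EncodedInput:
    """Restrict an encoded input to one ensemble partition (by flat input
    index), keeping the time base."""
    return EncodedInput(firing_prob=enc.firing_prob[np.asarray(indices)],
                        t_step=enc.t_step, duration=enc.duration)


class Liquid:
    """One liquid plus its neuron/plasticity parameters and persistent state.

    The object owns the live plastic weight matrix (``topology.w_inp_e``) and
    the excitatory adaptive-threshold offsets, which persist across
    presentations during training.
    """

    def __init__(self, topology: LiquidTopology,
                 lif_e: LIFParams | None = None,
                 lif_i: LIFParams | None = None,
                 stdp: STDPParams | None = None):
        self.topology = topology
        self.lif_e = lif_e or LIFParams.excitatory()
        self.lif_i = lif_i or LIFParams.inhibitory()
        self.stdp = stdp or STDPParams.image()
        cfg = topology.config
        self.n_inp, self.n_e, self.n_i = cfg.n_inp, cfg.n_e, cfg.n_i
        self.theta_adapt = np.zeros(self.n_e)
        # fixed recurrent weight matrices (frozen for the object's lifetime)
        self._m_ee = topology.mask_ee * cfg.w_ee
        self._m_ei = topology.mask_ei * cfg.w_ei
        self._m_ie = topology.mask_ie * cfg.w_ie
        self._m_ii = topology.mask_ii * cfg.w_ii

    @property
    def w_inp_e(self) -> np.ndarray:
        return self.topology.w_inp_e

    def present(self, enc: EncodedInput, mode: str,
                rng: np.random.Generator) -> SpikeRecord:
        """Simulate one pattern presentation; in ``"train"`` mode the plastic
        weights and adaptive thresholds are updated, in ``"test"`` mode both
        are frozen. Returns the excitatory spike record."""
        if mode not in ("train", "test"):
            raise ValueError(f"mode must be 'train' or 'test', got {mode!r}")
        if enc.n_inputs != self.n_inp:
            raise ValueError(f"encoded input has {enc.n_inputs} neurons, "
                             f"topology expects {self.n_inp}")
        training = mode == "train"
        dt = enc.t_step
        n_steps = enc.n_steps
        le, li, p = self.lif_e, self.lif_i, self.stdp
        w = self.topology.w_inp_e
        mask_inp_e = self.topology.mask_inp_e

        inp_raster = rng.random((self.n_inp, n_steps)) < enc.step_probabilities()
        inp_f = inp_raster.astype(float)

        # decay factors
        fe_mem, fe_the = math.exp(-dt / le.tau_mem), math.exp(-dt / le.tau_theta)
        fe_se, fe_si = math.exp(-dt / le.tau_syn_e), math.exp(-dt / le.tau_syn_i)
        fi_mem = math.exp(-dt / li.tau_mem)
        fi_se, fi_si = math.exp(-dt / li.tau_syn_e), math.exp(-dt / li.tau_syn_i)

        # fresh per-presentation state; theta persists across presentations
        v_e = np.full(self.n_e, le.v_rest)
        v_i = np.full(self.n_i, li.v_rest)
        ie_exc = np.zeros(self.n_e); ie_inh = np.zeros(self.n_e)
        ii_exc = np.zeros(self.n_i); ii_inh = np.zeros(self.n_i)
        refr_e = np.zeros(self.n_e); refr_i = np.zeros(self.n_i)
        theta = self.theta_adapt
        last_pre = np.full(self.n_inp, np.nan)

        prev_inp = np.zeros(self.n_inp)
        prev_e = np.zeros(self.n_e)
        prev_i = np.zeros(self.n_i)
        prev_inp_any = prev_e_any = prev_i_any = False
        raster_e = np.zeros((self.n_e, n_steps), dtype=bool)

        for t in range(n_steps):
            inp = inp_f[:, t]
            if training:
                last_pre[inp_raster[:, t]] = t * dt
            # deliver previous-step spikes (skip matmuls for silent groups)
            if prev_inp_any:
                ie_exc += prev_inp @ w
            if prev_e_any:
                ie_exc += prev_e @ self._m_ee
                ii_exc += prev_e @ self._m_ei
            if prev_i_any:
                ie_inh += prev_i @ self._m_ie
                ii_inh += prev_i @ self._m_ii
            # decay
            v_e = le.v_rest + (v_e - le.v_rest) * fe_mem
            v_i = li.v_rest + (v_i - li.v_rest) * fi_mem
            ie_exc *= fe_se; ie_inh *= fe_si
            ii_exc *= fi_se; ii_inh *= fi_si
            np.maximum(refr_e - dt, 0.0, out=refr_e)
            np.maximum(refr_i - dt, 0.0, out=refr_i)
            if training:
                theta *= fe_the
            # integrate
            v_e += ie_exc - ie_inh
            v_i += ii_exc - ii_inh
            # threshold test
            sp_e = (refr_e == 0) & (v_e > le.theta_base + theta)
            sp_i = (refr_i == 0) & (v_i > li.theta_base)
            v_e[sp_e] = le.v_reset; refr_e[sp_e] = le.t_refrac
            v_i[sp_i] = li.v_reset; refr_i[sp_i] = li.t_refrac
            prev_e_any = bool(sp_e.any())
            prev_i_any = bool(sp_i.any())
            if training:
                theta[sp_e] += le.theta_plus
                if prev_e_any:
                    self._stdp_update(sp_e, last_pre, t * dt)
            raster_e[:, t] = sp_e
            prev_inp = inp
            prev_inp_any = bool(inp_raster[:, t].any())
            prev_e = sp_e.astype(float)
            prev_i = sp_i.astype(float)

        return SpikeRecord(raster=raster_e, t_step=dt)

    def _stdp_update(self, sp_e: np.ndarray, last_pre: np.ndarray,
                     t_post: float) -> None:
        """Apply the STDP rule to the input synapses of every excitatory
        neuron that spiked at ``t_post``, pairing with the most recent
        pre-spike per input; only mask-supported synapses with a recorded
        pre-spike are touched."""
        p = self.stdp
        has = ~np.isnan(last_pre)
        if not has.any():
            return
        cols = np.flatnonzero(sp_e)
        sub = self.topology.w_inp_e[np.ix_(has, cols)]
        msub = self.topology.mask_inp_e[np.ix_(has, cols)]
        bracket = np.exp(-(t_post - last_pre[has]) / p.tau) - p.stdp_offset
        new = sub + p.eta * bracket[:, None] * (p.w_max - sub) ** p.mu
        np.clip(new, p.w_min, p.w_max, out=new)
        self.topology.w_inp_e[np.ix_(has, cols)] = np.where(msub, new, sub)


def present_pattern(liquid: Liquid, enc: EncodedInput, mode: str,
                    rng: np.random.Generator) -> SpikeRecord:
    """Functional wrapper around :meth:`Liquid.present`."""
    return liquid.present(enc, mode, rng)


def train(liquid: Liquid, dataset, schedule: TrainingSchedule,
          n_classes: int | None = None, rng: np.random.Generator | None = None,
          start_index: int = 0, record_presentation_counts: bool = False,
          log_every: int = 0, log=print):
    """Train a liquid on labeled encoded inputs.

    ``dataset`` is a sequence of ``(EncodedInput, label)`` pairs, cycled in
    order until ``schedule.n_examples`` presentations have been made.
    Accumulates per-excitatory-neuron, per-class training spike counts — the
    raw material for tagging; the labels serve only this bookkeeping and do
    not enter the weight update.

    Returns the ``(n_e, n_classes)`` cumulative count matrix; with
    ``record_presentation_counts`` additionally a ``(n_examples, n_e)``
    per-presentation count matrix. ``rng``/``start_index`` support resuming a
    checkpointed run deterministically.
    """
    if len(dataset) == 0:
        raise ValueError("dataset must be nonempty")
    labels = [int(lab) for _, lab in dataset]
    if n_classes is None:
        n_classes = max(labels) + 1
    if rng is None:
        rng = np.random.default_rng(schedule.seed)
    class_counts = np.zeros((liquid.n_e, n_classes))
    per_pres = (np.zeros((schedule.n_examples - start_index, liquid.n_e))
                if record_presentation_counts else None)
    for k in range(start_index, schedule.n_examples):
        enc, label = dataset[k % len(dataset)]
        rec = liquid.present(enc, "train", rng)
        counts = rec.spike_count
        class_counts[:, int(label)] += counts
        if per_pres is not None:
            per_pres[k - start_index] = counts
        if log_every and (k + 1) % log_every == 0:
            log(f"presentations={k + 1} mean_rate={rec.mean_rate():.2f}Hz "
                f"mean_weight={liquid.w_inp_e[liquid.topology.mask_inp_e].mean():.4f}")
    if record_presentation_counts:
        return class_counts, per_pres
    return class_counts


class LiquidEnsemble:
    """Several independent liquids, each fed one input partition; there are
    no synapses between liquids. A single-liquid ensemble on the full input
    reduces exactly to the single-liquid model."""

    def __init__(self, liquids: list[Liquid], partitions: list[np.ndarray]):
        if len(liquids) != len(partitions):
            raise ValueError("one partition per liquid required")
        for liq, part in zip(liquids, partitions):
            if liq.n_inp != len(part):
                raise ValueError("partition size must match liquid n_inp")
        self.liquids = liquids
        self.partitions = [np.asarray(p) for p in partitions]

    @classmethod
    def from_config(cls, ens_cfg: EnsembleConfig,
                    lif_e: LIFParams | None = None,
                    lif_i: LIFParams | None = None,
                    stdp: STDPParams | None = None) -> "LiquidEnsemble":
        liquids = [Liquid(build_liquid(cfg), lif_e, lif_i, stdp)
                   for cfg in ens_cfg.liquid_configs]
        return cls(liquids, ens_cfg.partitions)

    @property
    def n_liquids(self) -> int:
        return len(self.liquids)

    def present(self, enc: EncodedInput, mode: str,
                rngs: list[np.random.Generator]) -> list[SpikeRecord]:
        """Present one full-input pattern: each liquid sees its own slice and
        consumes its own rng stream."""
        return [liq.present(slice_encoded(enc, part), mode, rng)
                for liq, part, rng in zip(self.liquids, self.partitions, rngs)]

    def train(self, dataset, schedule: TrainingSchedule,
              n_classes: int | None = None) -> list[np.ndarray]:
        """Train every liquid on its partition of the dataset (liquids are
        independent, each with its own spike-sampling stream derived from the
        schedule seed). Returns the per-liquid class-count matrices."""
        results = []
        for idx, (liq, part) in enumerate(zip(self.liquids, self.partitions)):
            sub = [(slice_encoded(enc, part), lab) for enc, lab in dataset]
            sub_schedule = TrainingSchedule(schedule.n_examples,
                                            seed=schedule.seed + idx)
            results.append(train(liq, sub, sub_schedule, n_classes))
        return results


# --------------------------------------------------------------------------
# Checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(path, liquid: Liquid, class_counts: np.ndarray,
                    examples_seen: int, rng: np.random.Generator,
                    config_echo: str = "") -> None:
    """Persist everything needed to resume training deterministically:
    topology (with live weights), adaptive thresholds, cumulative tag
    statistics, presentation counter and the spike-sampling RNG state."""
    with h5py.File(path, "w") as h:
        save_topology(liquid.topology, h.create_group("topology"))
        h.create_dataset("theta_adapt", data=liquid.theta_adapt)
        h.create_dataset("class_counts", data=class_counts)
        h.attrs["examples_seen"] = examples_seen
        h.attrs["rng_state"] = json.dumps(rng.bit_generator.state)
        h.attrs["config_echo"] = config_echo
        for name, prm in (("lif_e", liquid.lif_e), ("lif_i", liquid.lif_i)):
            g = h.create_group(name)
            for k, v in vars(prm).items():
                g.attrs[k] = v
        g = h.create_group("stdp")
        for k, v in vars(liquid.stdp).items():
            g.attrs[k] = v


def load_checkpoint(path):
    """Load a checkpoint; returns ``(liquid, class_counts, examples_seen,
    rng, config_echo)`` with the RNG restored mid-stream."""
    with h5py.File(path, "r") as h:
        topo = load_topology(h["topology"])
        lif_e = LIFParams(**{k: float(v) for k, v in h["lif_e"].attrs.items()})
        lif_i = LIFParams(**{k: float(v) for k, v in h["lif_i"].attrs.items()})
        stdp = STDPParams(**{k: float(v) for k, v in h["stdp"].attrs.items()})
        liquid = Liquid(topo, lif_e, lif_i, stdp)
        liquid.theta_adapt = h["theta_adapt"][...]
        class_counts = h["class_counts"][...]
        examples_seen = int(h.attrs["examples_seen"])
        rng = np.random.default_rng()
        rng.bit_generator.state = json.loads(h.attrs["rng_state"])
        echo = str(h.attrs["config_echo"])
    return liquid, class_counts, examples_seen, rng, echo
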