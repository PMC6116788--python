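"""Current-based leaky integrate-and-fire dynamics with adaptive thresholds.

The neuron model used throughout the package: excitatory and inhibitory
post-synaptic currents decay exponentially between spikes, the membrane
potential leaks exponentially toward the resting potential and integrates the
net current, and a neuron fires when its potential exceeds an adaptive
threshold ``theta_base + theta_adapt``. On firing, the potential is reset, the
adaptive threshold offset is incremented (homeostasis), and the neuron is
refractory for ``t_refrac``.

All state updates are exact exponential updates per time step (not Euler), so
one update of ``dt`` equals two consecutive updates of ``dt/2`` for the pure
decay terms. The per-step contract used by the simulation engine is:
deliver previous-step spikes into the currents -> decay -> integrate currents
into the membrane potential -> threshold test.

State containers hold numpy arrays so one ``NeuronState`` represents a whole
population; scalars work as size-1 arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["LIFParams", "NeuronState", "decay_state", "inject_spikes",
           "integrate_currents", "fire_and_reset"]


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire parameters for one neuron population.

    Times are in ms, potentials in mV. Synaptic weights are dimensionless
    "current per step" units: a spike of weight w adds w to the post-synaptic
    current, which is added to the membrane potential once per step while it
    decays with its synaptic time constant.
    """

    tau_mem: float = 100.0       # membrane time constant
    v_rest: float = -65.0        # resting potential
    v_reset: float = -65.0       # reset potential after a spike
    theta_base: float = -52.0    # base firing threshold
    theta_plus: float = 0.05     # adaptive-threshold increment per spike
    tau_theta: float = 1e7       # adaptive-threshold decay time constant
    t_refrac: float = 5.0        # refractory period
    tau_syn_e: float = 2.0       # excitatory post-synaptic current decay
    tau_syn_i: float = 1.0       # inhibitory post-synaptic current decay

    def __post_init__(self) -> None:
        for name in ("tau_mem", "tau_theta", "tau_syn_e", "tau_syn_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.t_refrac < 0:
            raise ValueError(f"t_refrac must be >= 0, got {self.t_refrac}")
        if self.theta_base <= self.v_reset:
            raise ValueError("theta_base must exceed v_reset")

    @classmethod
    def excitatory(cls) -> "LIFParams":
        """Defaults for the excitatory population (adaptive threshold on)."""
        return cls()

    @classmethod
    def inhibitory(cls) -> "LIFParams":
        """Defaults for the inhibitory population: faster membrane, fixed
        threshold (theta_plus = 0), shorter refractory period."""
        return cls(tau_mem=10.0, v_reset=-45.0, theta_base=-40.0,
                   theta_plus=0.0, t_refrac=2.0)


@dataclass
class NeuronState:
    """Per-neuron dynamic state (vectorized over a population)."""

    v_mem: np.ndarray              # membrane potential (mV)
    theta_adapt: np.ndarray        # adaptive threshold offset (mV, >= 0)
    refrac_remaining: np.ndarray   # time until the neuron may fire (ms)
    i_exc: np.ndarray              # excitatory post-synaptic current
    i_inh: np.ndarray              # inhibitory post-synaptic current (>= 0,
                                   # subtracted from v_mem on integration)

    @classmethod
    def resting(cls, n: int, params: LIFParams) -> "NeuronState":
        z = np.zeros(n, dtype=float)
        return cls(v_mem=np.full(n, params.v_rest, dtype=float),
                   theta_adapt=z.copy(), refrac_remaining=z.copy(),
                   i_exc=z.copy(), i_inh=z.copy())

    def copy(self) -> "NeuronState":
        return NeuronState(self.v_mem.copy(), self.theta_adapt.copy(),
                           self.refrac_remaining.copy(), self.i_exc.copy(),
                           self.i_inh.copy())


def decay_state(state: NeuronState, params: LIFParams, dt: float) -> NeuronState:
    """Relax all state variables over an interval ``dt`` with no input.

    v_mem decays toward v_rest with exp(-dt/tau_mem); the synaptic currents
    and the adaptive threshold decay with their own time constants; the
    refractory timer is decremented and floored at zero.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    f_mem = math.exp(-dt / params.tau_mem)
    return NeuronState(
        v_mem=params.v_rest + (state.v_mem - params.v_rest) * f_mem,
        theta_adapt=state.theta_adapt * math.exp(-dt / params.tau_theta),
        refrac_remaining=np.maximum(state.refrac_remaining - dt, 0.0),
        i_exc=state.i_exc * math.exp(-dt / params.tau_syn_e),
        i_inh=state.i_inh * math.exp(-dt / params.tau_syn_i),
    )


def inject_spikes(state: NeuronState, weighted_exc_input, weighted_inh_input) -> NeuronState:
    """Add weighted presynaptic spike input to the post-synaptic currents.

    Both arguments are total synaptic drive (sum of weights of presynaptic
    neurons that spiked) and must be non-negative; inhibition is stored
    positive and lowers the membrane potential at integration time.
    """
    exc = np.asarray(weighted_exc_input, dtype=float)
    inh = np.asarray(weighted_inh_input, dtype=float)
    if np.any(exc < 0) or np.any(inh < 0):
        raise ValueError("weighted spike inputs must be non-negative")
    out = state.copy()
    out.i_exc = out.i_exc + exc
    out.i_inh = out.i_inh + inh
    return out


def integrate_currents(state: NeuronState) -> NeuronState:
    """Integrate the standing post-synaptic currents into v_mem for one step:
    v_mem += i_exc - i_inh (currents are step-wise constant inputs)."""
    out = state.copy()
    out.v_mem = out.v_mem + out.i_exc - out.i_inh
    return out


def fire_and_reset(state: NeuronState, params: LIFParams):
    """Threshold test with reset, homeostatic increment and refractory gate.

    Returns ``(spiked, new_state)`` where ``spiked`` is a boolean array. A
    neuron spikes iff it is out of its refractory period and
    v_mem > theta_base + theta_adapt; spiking neurons are reset to v_reset,
    their adaptive threshold offset grows by theta_plus, and their refractory
    timer is set to t_refrac.
    """
    spiked = (state.refrac_remaining == 0) & (
        state.v_mem > params.theta_base + state.theta_adapt)
    out = state.copy()
    out.v_mem = np.where(spiked, params.v_reset, out.v_mem)
    out.theta_adapt = np.where(spiked, out.theta_adapt + params.theta_plus,
                               out.theta_adapt)
    out.refrac_remaining = np.where(spiked, params.t_refrac,
                                    out.refrac_remaining)
    return spiked, out
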