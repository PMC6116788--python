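"""Power-law weight-dependent STDP on the plastic input synapses.

The weight update applied at every post-synaptic (excitatory) spike is

    dw = eta * [exp(-(t_post - t_pre)/tau) - offset] * (w_max - w)**mu

so tightly correlated pre/post pairs potentiate (exp term above the offset)
and weakly correlated ones depress, with a soft upper bound: the (w_max-w)**mu
factor shrinks updates as a weight approaches w_max. Only the most recent
pre-spike per synapse is paired with each post-spike; synapses whose input has
not spiked within the current pattern presentation are untouched. Updates are
hard-clipped to [w_min, w_max].

With offset = 0 the bracket is always positive, so no weight is ever
depressed — the regime used for the temporal (speech-like) task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["STDPParams", "stdp_delta", "apply_post_spike"]


@dataclass(frozen=True)
class STDPParams:
    """Parameters of the power-law weight-dependent STDP rule."""

    eta: float = 0.005       # learning rate
    tau: float = 15.0        # STDP time constant (ms)
    stdp_offset: float = 0.4  # offset in [0, 1); potentiation window edge
    mu: float = 0.9          # weight-dependence exponent
    w_max: float = 1.0       # upper weight bound
    w_min: float = 0.0       # lower weight bound

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not 0 <= self.stdp_offset < 1:
            raise ValueError(f"stdp_offset must be in [0, 1), got {self.stdp_offset}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.w_min >= self.w_max:
            raise ValueError("w_min must be < w_max")

    @classmethod
    def speech(cls) -> "STDPParams":
        """Temporal-input (speech-like) defaults: slow, potentiation-only."""
        return cls(eta=0.0001, stdp_offset=0.0)

    @classmethod
    def image(cls) -> "STDPParams":
        """Static-image defaults: faster learning with depression."""
        return cls(eta=0.005, stdp_offset=0.4)

    def potentiation_window(self) -> float:
        """Spike-time difference (ms) at which the rule changes sign.

        Pairs with t_post - t_pre below this value potentiate; beyond it they
        depress. Infinite when the offset is zero (no depression).
        """
        if self.stdp_offset == 0:
            return float("inf")
        return -self.tau * float(np.log(self.stdp_offset))


def stdp_delta(dt_spike, w, p: STDPParams):
    """Weight change for a pre/post pair separated by ``dt_spike`` ms (>= 0).

    Vectorized over both arguments. Raises if a weight lies outside
    [w_min, w_max] or a spike-time difference is negative.
    """
    dt_spike = np.asarray(dt_spike, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(dt_spike < 0):
        raise ValueError("dt_spike must be >= 0 (post after pre)")
    if np.any(w < p.w_min) or np.any(w > p.w_max):
        raise ValueError("weight outside [w_min, w_max]")
    delta = p.eta * (np.exp(-dt_spike / p.tau) - p.stdp_offset) * (p.w_max - w) ** p.mu
    return delta if delta.ndim else float(delta)


def apply_post_spike(weights, last_pre_spike_times, t_post: float,
                     p: STDPParams, mask=None):
    """Update all input-synapse weights of one (or several) spiking post-neurons.

    Parameters
    ----------
    weights
        Shape ``(n_inp,)`` for one post-neuron or ``(n_inp, k)`` for k
        post-neurons spiking at the same instant (they share the pre-spike
        record).
    last_pre_spike_times
        Shape ``(n_inp,)``; time of the most recent pre-spike per input
        synapse, ``nan`` where the input has not spiked yet.
    t_post
        Time of the post-synaptic spike; must not precede any recorded
        pre-spike.
    mask
        Optional boolean array of the same shape as ``weights`` restricting
        the update to actually existing synapses.

    Returns the updated weight array, clipped to [w_min, w_max]; synapses with
    no recorded pre-spike (or outside the mask) are returned unchanged.
    """
    weights = np.asarray(weights, dtype=float)
    t_pre = np.asarray(last_pre_spike_times, dtype=float)
    has_pre = ~np.isnan(t_pre)
    if np.any(t_pre[has_pre] > t_post):
        raise ValueError("t_post precedes a recorded pre-spike")
    if not has_pre.any():
        return weights.copy()

    dt_spike = np.where(has_pre, t_post - t_pre, 0.0)
    if weights.ndim == 2:
        dt_spike = dt_spike[:, None]
        has_pre = np.broadcast_to(has_pre[:, None], weights.shape)
    active = has_pre if mask is None else (has_pre & mask)
    delta = stdp_delta(dt_spike, np.clip(weights, p.w_min, p.w_max), p)
    out = np.where(active, np.clip(weights + delta, p.w_min, p.w_max), weights)
    return out
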