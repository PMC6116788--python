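"""Shared fixtures and the independent scalar replay oracle.

The replay oracle re-implements the documented per-step simulation contract
in plain Python scalar arithmetic (explicit loops, ``math.exp``), independent
of the vectorized engine, so engine runs can be checked step by step.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from spilinc import (EncodedInput, LIFParams, LiquidConfig, LiquidTopology,
                     STDPParams, build_liquid)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_topology():
    """A 7-neuron network: 4 inputs, 2 excitatory, 1 inhibitory, dense."""
    cfg = LiquidConfig(n_inp=4, n_e=2, n_i=1, p_inp_e=100, p_ee=100, p_ei=100,
                      p_ie=100, p_ii=0, w_init_min=0.1, w_init_max=0.5, seed=3)
    return build_liquid(cfg)


def scalar_replay(topology: LiquidTopology, lif_e: LIFParams, lif_i: LIFParams,
                  stdp: STDPParams, probs_list, n_steps: int, dt: float,
                  seed: int, mode: str = "train"):
    """Pure-Python scalar re-implementation of the presentation loop.

    ``probs_list``: per presentation, an (n_inp, n_steps) probability array.
    Input rasters are drawn exactly as the engine draws them (one uniform
    block per presentation from a generator seeded with ``seed``).

    Returns (weights, theta, rasters) after presenting every pattern in order.
    """
    cfg = topology.config
    n_inp, n_e, n_i = cfg.n_inp, cfg.n_e, cfg.n_i
    w = [[float(topology.w_inp_e[k][j]) for j in range(n_e)]
         for k in range(n_inp)]
    mask_inp = topology.mask_inp_e
    theta = [0.0] * n_e
    training = mode == "train"
    master = np.random.default_rng(seed)
    rasters = []

    for probs in probs_list:
        raster = master.random((n_inp, n_steps)) < np.asarray(probs)
        v_e = [lif_e.v_rest] * n_e
        v_i = [lif_i.v_rest] * n_i
        ie_exc = [0.0] * n_e; ie_inh = [0.0] * n_e
        ii_exc = [0.0] * n_i; ii_inh = [0.0] * n_i
        refr_e = [0.0] * n_e; refr_i = [0.0] * n_i
        last_pre = [None] * n_inp
        prev_inp = [0.0] * n_inp
        prev_e = [0.0] * n_e
        prev_i = [0.0] * n_i
        out = np.zeros((n_e, n_steps), dtype=bool)

        for t in range(n_steps):
            if training:
                for k in range(n_inp):
                    if raster[k][t]:
                        last_pre[k] = t * dt
            # deliver previous-step spikes
            for j in range(n_e):
                exc = sum(prev_inp[k] * w[k][j] for k in range(n_inp))
                exc += sum(prev_e[a] * cfg.w_ee * topology.mask_ee[a][j]
                           for a in range(n_e))
                ie_exc[j] += exc
                ie_inh[j] += sum(prev_i[b] * cfg.w_ie * topology.mask_ie[b][j]
                                 for b in range(n_i))
            for b in range(n_i):
                ii_exc[b] += sum(prev_e[a] * cfg.w_ei * topology.mask_ei[a][b]
                                 for a in range(n_e))
                ii_inh[b] += sum(prev_i[c] * cfg.w_ii * topology.mask_ii[c][b]
                                 for c in range(n_i))
            # decay
            for j in range(n_e):
                v_e[j] = lif_e.v_rest + (v_e[j] - lif_e.v_rest) * math.exp(-dt / lif_e.tau_mem)
                ie_exc[j] *= math.exp(-dt / lif_e.tau_syn_e)
                ie_inh[j] *= math.exp(-dt / lif_e.tau_syn_i)
                refr_e[j] = max(refr_e[j] - dt, 0.0)
                if training:
                    theta[j] *= math.exp(-dt / lif_e.tau_theta)
            for b in range(n_i):
                v_i[b] = lif_i.v_rest + (v_i[b] - lif_i.v_rest) * math.exp(-dt / lif_i.tau_mem)
                ii_exc[b] *= math.exp(-dt / lif_i.tau_syn_e)
                ii_inh[b] *= math.exp(-dt / lif_i.tau_syn_i)
                refr_i[b] = max(refr_i[b] - dt, 0.0)
            # integrate
            for j in range(n_e):
                v_e[j] += ie_exc[j] - ie_inh[j]
            for b in range(n_i):
                v_i[b] += ii_exc[b] - ii_inh[b]
            # threshold test
            sp_e = [refr_e[j] == 0 and v_e[j] > lif_e.theta_base + theta[j]
                    for j in range(n_e)]
            sp_i = [refr_i[b] == 0 and v_i[b] > lif_i.theta_base
                    for b in range(n_i)]
            for j in range(n_e):
                if sp_e[j]:
                    v_e[j] = lif_e.v_reset
                    refr_e[j] = lif_e.t_refrac
                    if training:
                        theta[j] += lif_e.theta_plus
                    out[j][t] = True
            for b in range(n_i):
                if sp_i[b]:
                    v_i[b] = lif_i.v_reset
                    refr_i[b] = lif_i.t_refrac
            # STDP at post-spike instants, most recent pre-spike pairing
            if training:
                for j in range(n_e):
                    if not sp_e[j]:
                        continue
                    for k in range(n_inp):
                        if last_pre[k] is None or not mask_inp[k][j]:
                            continue
                        dts = t * dt - last_pre[k]
                        delta = stdp.eta * (math.exp(-dts / stdp.tau)
                                            - stdp.stdp_offset) \
                            * (stdp.w_max - w[k][j]) ** stdp.mu
                        w[k][j] = min(max(w[k][j] + delta, stdp.w_min),
                                      stdp.w_max)
            prev_inp = [1.0 if raster[k][t] else 0.0 for k in range(n_inp)]
            prev_e = [1.0 if s else 0.0 for s in sp_e]
            prev_i = [1.0 if s else 0.0 for s in sp_i]
        rasters.append(out)

    return np.array(w), np.array(theta), rasters
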