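"""Liquid topology generation, synapse accounting and input partitioning.

A liquid is a sparse random recurrent network of excitatory (e) and inhibitory
(i) spiking neurons driven by an input layer. Connectivity between any two
neuron groups is Bernoulli: a uniform(0, 1) matrix thresholded at
``percent/100``. Input->e synapses are plastic and initialized uniformly in
``[w_init_min, w_init_max]``; the four recurrent projections (e->e, e->i,
i->e, i->i) carry fixed scalar weights.

Ensembles split the input across several independent liquids (no cross-liquid
synapses); overlapping segments keep boundary features visible to both
liquids.

Matrix convention: rows are pre-synaptic, columns post-synaptic; images are
flattened row-major; indices are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

__all__ = [
    "LiquidConfig", "LiquidTopology", "EnsembleConfig",
    "build_mask", "init_input_weights", "build_liquid",
    "count_synapses", "count_synapses_config", "inputs_per_liquid",
    "partition_input", "effective_synapse_count",
    "save_topology", "load_topology",
]


@dataclass(frozen=True)
class LiquidConfig:
    """Size, connectivity-percentage and weight-initialization parameters of
    one liquid. Percentages are on the 0-100 scale."""

    n_inp: int
    n_e: int
    n_i: int
    p_inp_e: float      # input -> excitatory connection percentage
    p_ee: float         # excitatory -> excitatory
    p_ei: float         # excitatory -> inhibitory
    p_ie: float         # inhibitory -> excitatory
    p_ii: float         # inhibitory -> inhibitory
    w_init_min: float = 0.003
    w_init_max: float = 0.303
    w_ee: float = 1.0   # fixed recurrent weights
    w_ei: float = 10.0
    w_ie: float = 1.0
    w_ii: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_inp", "n_e", "n_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("p_inp_e", "p_ee", "p_ei", "p_ie", "p_ii"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.w_init_min >= self.w_init_max:
            raise ValueError("w_init_min must be < w_init_max")


@dataclass
class LiquidTopology:
    """Realized connectivity of one liquid: boolean masks plus the plastic
    input weight matrix. Recurrent weights are scalars applied through masks."""

    config: LiquidConfig
    mask_inp_e: np.ndarray   # (n_inp, n_e) bool
    mask_ee: np.ndarray      # (n_e, n_e) bool
    mask_ei: np.ndarray      # (n_e, n_i) bool
    mask_ie: np.ndarray      # (n_i, n_e) bool
    mask_ii: np.ndarray      # (n_i, n_i) bool
    w_inp_e: np.ndarray      # (n_inp, n_e) float, nonzero only on mask

    def realized_synapse_count(self) -> int:
        """Actual number of generated synapses (cf. the expected count from
        :func:`count_synapses`, which is the Bernoulli mean)."""
        return int(self.mask_inp_e.sum() + self.mask_ee.sum() +
                   self.mask_ei.sum() + self.mask_ie.sum() + self.mask_ii.sum())


@dataclass
class EnsembleConfig:
    """An ensemble of independent liquids, each fed one input partition."""

    partitions: list            # per-liquid ordered arrays of input indices
    liquid_configs: list        # per-liquid LiquidConfig

    def __post_init__(self) -> None:
        if len(self.partitions) != len(self.liquid_configs):
            raise ValueError("one LiquidConfig per partition required")
        for part, cfg in zip(self.partitions, self.liquid_configs):
            if len(part) == 0:
                raise ValueError("empty input partition")
            if len(part) != cfg.n_inp:
                raise ValueError("partition size must equal the liquid's n_inp")

    @property
    def n_liquids(self) -> int:
        return len(self.partitions)


def build_mask(n_pre: int, n_post: int, percent: float,
               rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(percent/100) boolean connectivity matrix of shape
    (n_pre, n_post): uniform(0,1) entries thresholded at percent/100."""
    if not 0 <= percent <= 100:
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    return rng.random((n_pre, n_post)) < percent / 100.0


def init_input_weights(mask: np.ndarray, w_init_min: float, w_init_max: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Uniform[w_init_min, w_init_max) weights on the mask support, zero off it."""
    if w_init_min >= w_init_max:
        raise ValueError("w_init_min must be < w_init_max")
    w = rng.uniform(w_init_min, w_init_max, size=mask.shape)
    return np.where(mask, w, 0.0)


def build_liquid(cfg: LiquidConfig) -> LiquidTopology:
    """Generate a liquid from its config; the same seed yields a bit-identical
    topology. Self-connections are permitted in the e-e and i-i masks."""
    rng = np.random.default_rng(cfg.seed)
    mask_inp_e = build_mask(cfg.n_inp, cfg.n_e, cfg.p_inp_e, rng)
    mask_ee = build_mask(cfg.n_e, cfg.n_e, cfg.p_ee, rng)
    mask_ei = build_mask(cfg.n_e, cfg.n_i, cfg.p_ei, rng)
    mask_ie = build_mask(cfg.n_i, cfg.n_e, cfg.p_ie, rng)
    mask_ii = build_mask(cfg.n_i, cfg.n_i, cfg.p_ii, rng)
    w_inp_e = init_input_weights(mask_inp_e, cfg.w_init_min, cfg.w_init_max, rng)
    return LiquidTopology(cfg, mask_inp_e, mask_ee, mask_ei, mask_ie, mask_ii,
                          w_inp_e)


def count_synapses(n_inp: int, n_e: int, n_i: int, p_inp_e: float, p_ee: float,
                   p_ei: float, p_ie: float, p_ii: float,
                   n_liquids: int = 1) -> float:
    """Expected synapse count of a liquid (times ``n_liquids`` for an ensemble
    of identical liquids):

        p_inp_e/100*n_inp*n_e + p_ee/100*n_e^2 + p_ei/100*n_e*n_i
        + p_ie/100*n_i*n_e + p_ii/100*n_i^2

    Generation is Bernoulli, so this is the mean of the realized count; it can
    be fractional.
    """
    per_liquid = ((p_inp_e * n_inp * n_e) / 100.0
                  + (p_ee * n_e * n_e) / 100.0
                  + (p_ei * n_e * n_i) / 100.0
                  + (p_ie * n_i * n_e) / 100.0
                  + (p_ii * n_i * n_i) / 100.0)
    return n_liquids * per_liquid


def count_synapses_config(cfg: LiquidConfig, n_liquids: int = 1) -> float:
    return count_synapses(cfg.n_inp, cfg.n_e, cfg.n_i, cfg.p_inp_e, cfg.p_ee,
                          cfg.p_ei, cfg.p_ie, cfg.p_ii, n_liquids)


def inputs_per_liquid(p_inp_e: float, input_dimension: int, n_liquids: int,
                      n_overlap: float) -> float:
    """Expected number of connected inputs per liquid in an ensemble:
    (p_inp_e/100) * (input_dimension/n_liquids + n_overlap). Larger ensembles
    leave each liquid fewer effective inputs."""
    if n_liquids < 1:
        raise ValueError("n_liquids must be >= 1")
    return (p_inp_e / 100.0) * (input_dimension / n_liquids + n_overlap)


def _flat_block(h: int, w: int, rows: range, cols: range) -> np.ndarray:
    rr, cc = np.meshgrid(np.fromiter(rows, int), np.fromiter(cols, int),
                         indexing="ij")
    return (rr * w + cc).ravel()


def partition_input(shape, scheme: str, n_liquids: int = 2,
                    overlap: int = 4) -> list:
    """Split an input across the liquids of an ensemble.

    Parameters
    ----------
    shape
        ``(height, width)`` for images (row-major flattening) or
        ``(n_channels,)`` / int for channel inputs.
    scheme
        ``"vertical-halves"``: two column blocks, each ``width//2 +
        overlap//2`` wide, sharing ``overlap`` central columns (a 28-wide
        image with overlap 4 gives columns [0,16) and [12,28)). With
        ``n_liquids=4`` the matching horizontal (row) halves are appended.
        ``"horizontal-halves"``: the row-block analogue.
        ``"channel-blocks"``: ``n_liquids`` blocks of consecutive channels of
        size ``ceil(dim/n_liquids) + overlap``, evenly spaced so the first
        block starts at 0 and the last ends at ``dim`` (39 channels, 2 blocks,
        overlap 10 gives channels [0,30) and [9,39)).

    Returns a list of index arrays into the flattened input. ``n_liquids=1``
    always returns the whole input as one partition.
    """
    shape = (int(shape), ) if np.isscalar(shape) else tuple(int(s) for s in shape)
    dim = int(np.prod(shape))
    if n_liquids == 1:
        return [np.arange(dim)]

    if scheme in ("vertical-halves", "horizontal-halves"):
        if len(shape) != 2:
            raise ValueError("image schemes need a (height, width) shape")
        h, w = shape
        parts: list = []

        def column_halves():
            half = w // 2 + overlap // 2
            if half > w:
                raise ValueError("segment larger than input width")
            return [_flat_block(h, w, range(h), range(0, half)),
                    _flat_block(h, w, range(h), range(w - half, w))]

        def row_halves():
            half = h // 2 + overlap // 2
            if half > h:
                raise ValueError("segment larger than input height")
            return [_flat_block(h, w, range(0, half), range(w)),
                    _flat_block(h, w, range(h - half, h), range(w))]

        first = column_halves if scheme == "vertical-halves" else row_halves
        second = row_halves if scheme == "vertical-halves" else column_halves
        if n_liquids == 2:
            parts = first()
        elif n_liquids == 4:
            parts = first() + second()
        else:
            raise ValueError("image schemes support 1, 2 or 4 liquids")
        return parts

    if scheme == "channel-blocks":
        size = math.ceil(dim / n_liquids) + overlap
        if size > dim:
            raise ValueError("segment larger than input")
        starts = [round(i * (dim - size) / (n_liquids - 1))
                  for i in range(n_liquids)]
        return [np.arange(s, s + size) for s in starts]

    raise ValueError(f"unknown partition scheme: {scheme}")


def effective_synapse_count(w_inp_e: np.ndarray, epsilon: float = 0.01,
                            mask: np.ndarray | None = None) -> int:
    """Number of effective (unpruned) plastic synapses: mask-supported weights
    strictly greater than ``epsilon``. Depression drives insignificant weights
    toward zero, so this count shrinks during training on image-like tasks.

    The default threshold is 1% of the usual w_max = 1.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    w = np.asarray(w_inp_e)
    sig = w > epsilon
    if mask is not None:
        sig = sig & mask
    return int(sig.sum())


def save_topology(topo: LiquidTopology, group: "h5py.Group | str") -> None:
    """Write a topology to an HDF5 group or file path (masks as index lists,
    weights dense, config echoed as attributes)."""
    owned = isinstance(group, str)
    h = h5py.File(group, "w") if owned else group
    try:
        for key, val in asdict(topo.config).items():
            h.attrs[key] = val
        for name in ("mask_inp_e", "mask_ee", "mask_ei", "mask_ie", "mask_ii"):
            mask = getattr(topo, name)
            idx = np.flatnonzero(mask)
            ds = h.create_dataset(name, data=idx)
            ds.attrs["shape"] = mask.shape
        h.create_dataset("w_inp_e", data=topo.w_inp_e)
    finally:
        if owned:
            h.close()


def load_topology(group: "h5py.Group | str") -> LiquidTopology:
    owned = isinstance(group, str)
    h = h5py.File(group, "r") if owned else group
    try:
        cfg = LiquidConfig(**{k: (v.item() if hasattr(v, "item") else v)
                              for k, v in h.attrs.items()})
        masks = {}
        for name in ("mask_inp_e", "mask_ee", "mask_ei", "mask_ie", "mask_ii"):
            ds = h[name]
            shape = tuple(ds.attrs["shape"])
            mask = np.zeros(shape, dtype=bool)
            mask.ravel()[ds[...]] = True
            masks[name] = mask
        return LiquidTopology(cfg, w_inp_e=h["w_inp_e"][...], **masks)
    finally:
        if owned:
            h.close()
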