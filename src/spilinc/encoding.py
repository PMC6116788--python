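"""Poisson rate coding of images and channel-by-time intensity matrices.

Static images: each pixel intensity in [0, 255] maps linearly to an average
Poisson firing rate in [0, 63.75] spikes/s (rate = intensity/4), held constant
over the presentation. The per-time-step firing probability is
``rate/1000 * t_step``; with the 0.5 ms step a saturated pixel fires with
probability 0.031875 per step.

Temporal inputs (cochleagram-style channel x time matrices): intensities are
normalized by the sample's maximum intensity and used directly as per-step
firing probabilities for the channel neurons, resampled onto the simulation
grid by zero-order hold.

Spikes are drawn independently per neuron per step: spike iff a uniform(0,1)
draw falls below the firing probability.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "T_STEP", "IMAGE_DURATION", "TEMPORAL_DURATION", "MAX_RATE",
    "EncodedInput", "intensity_to_rate", "rate_to_probability",
    "normalize_channels", "encode_image", "encode_channels", "sample_spikes",
    "load_idx", "read_channel_matrix_csv", "write_channel_matrix_csv",
    "write_raster_csv", "read_raster_csv",
    "write_channel_matrix_hdf5", "read_channel_matrix_hdf5",
    "write_raster_hdf5", "read_raster_hdf5",
]

T_STEP = 0.5              # simulation time step (ms)
IMAGE_DURATION = 350.0    # image presentation interval (ms)
TEMPORAL_DURATION = 750.0  # temporal-pattern presentation interval (ms)
MAX_RATE = 63.75          # peak Poisson rate for a saturated pixel (spikes/s)


@dataclass(frozen=True)
class EncodedInput:
    """Per-input-neuron firing probabilities over one presentation.

    ``firing_prob`` is either 1-D ``(n_inputs,)`` (constant over the
    presentation) or 2-D ``(n_inputs, n_frames)``; frames are resampled to the
    simulation grid by zero-order hold.
    """

    firing_prob: np.ndarray
    t_step: float = T_STEP
    duration: float = IMAGE_DURATION

    def __post_init__(self) -> None:
        p = np.asarray(self.firing_prob, dtype=float)
        object.__setattr__(self, "firing_prob", p)
        if p.ndim not in (1, 2):
            raise ValueError("firing_prob must be 1-D or 2-D")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("firing probabilities must lie in [0, 1]")
        if self.t_step <= 0 or self.duration <= 0:
            raise ValueError("t_step and duration must be > 0")
        n = self.duration / self.t_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be a multiple of t_step")

    @property
    def n_inputs(self) -> int:
        return self.firing_prob.shape[0]

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.t_step))

    def step_probabilities(self) -> np.ndarray:
        """Probabilities on the simulation grid, shape (n_inputs, n_steps)."""
        n_steps = self.n_steps
        if self.firing_prob.ndim == 1:
            return np.broadcast_to(self.firing_prob[:, None],
                                   (self.n_inputs, n_steps))
        n_frames = self.firing_prob.shape[1]
        frame_of_step = (np.arange(n_steps) * n_frames) // n_steps
        return self.firing_prob[:, frame_of_step]


def intensity_to_rate(pixel):
    """Map a pixel intensity in [0, 255] to its average Poisson rate in
    spikes/s: rate = intensity * 63.75/255 = intensity/4."""
    pixel = np.asarray(pixel, dtype=float)
    if np.any(pixel < 0) or np.any(pixel > 255):
        raise ValueError("pixel intensity must lie in [0, 255]")
    rate = pixel * (MAX_RATE / 255.0)
    return rate if rate.ndim else float(rate)


def rate_to_probability(rate, t_step: float = T_STEP):
    """Per-time-step firing probability p = rate/1000 * t_step (rate in
    spikes/s, t_step in ms). Rejects rates that exceed one spike per step."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be >= 0")
    p = rate / 1000.0 * t_step
    if np.any(p > 1):
        raise ValueError("rate too high for the time step (p > 1)")
    return p if p.ndim else float(p)


def normalize_channels(intensity: np.ndarray) -> np.ndarray:
    """Normalize a channel x time intensity matrix by its global maximum so
    entries become firing probabilities in [0, 1]; an all-zero matrix maps to
    all-zero."""
    intensity = np.asarray(intensity, dtype=float)
    if intensity.size == 0:
        raise ValueError("empty intensity matrix")
    if np.any(intensity < 0):
        raise ValueError("intensities must be >= 0")
    peak = intensity.max()
    if peak == 0:
        return np.zeros_like(intensity)
    return intensity / peak


def encode_image(image: np.ndarray, t_step: float = T_STEP,
                 duration: float = IMAGE_DURATION) -> EncodedInput:
    """Rate-code a 2-D (or already flat) intensity array; pixels flatten
    row-major onto the input neurons."""
    flat = np.asarray(image, dtype=float).ravel()
    p = rate_to_probability(intensity_to_rate(flat), t_step)
    return EncodedInput(firing_prob=p, t_step=t_step, duration=duration)


def encode_channels(intensity: np.ndarray, t_step: float = T_STEP,
                    duration: float = TEMPORAL_DURATION) -> EncodedInput:
    """Encode a channel x time intensity matrix: normalize to probabilities,
    one input neuron per channel, zero-order hold onto the step grid."""
    intensity = np.asarray(intensity, dtype=float)
    if intensity.ndim != 2:
        raise ValueError("expected a 2-D channel x time matrix")
    return EncodedInput(firing_prob=normalize_channels(intensity),
                        t_step=t_step, duration=duration)


def sample_spikes(enc: EncodedInput, rng: np.random.Generator) -> np.ndarray:
    """Draw a Bernoulli spike raster, shape (n_inputs, n_steps), one
    independent uniform draw per neuron per step."""
    probs = enc.step_probabilities()
    return rng.random(probs.shape) < probs


# --------------------------------------------------------------------------
# File adapters
# --------------------------------------------------------------------------

def load_idx(path) -> np.ndarray:
    """Read an IDX-format array (the MNIST container format): big-endian
    magic (2 zero bytes, type code, ndim) followed by dimension sizes and raw
    data."""
    type_codes = {0x08: np.uint8, 0x09: np.int8, 0x0B: np.int16,
                  0x0C: np.int32, 0x0D: np.float32, 0x0E: np.float64}
    with open(path, "rb") as fh:
        zeros, code, ndim = struct.unpack(">HBB", fh.read(4))
        if zeros != 0 or code not in type_codes:
            raise ValueError(f"not an IDX file: {path}")
        dims = struct.unpack(f">{ndim}I", fh.read(4 * ndim))
        dtype = np.dtype(type_codes[code]).newbyteorder(">")
        data = np.frombuffer(fh.read(), dtype=dtype)
    return data.reshape(dims).astype(type_codes[code])


def read_channel_matrix_csv(path) -> np.ndarray:
    """Read one channel x time intensity matrix (rows = channels, no header)."""
    return pd.read_csv(path, header=None).to_numpy(dtype=float)


def write_channel_matrix_csv(matrix: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(matrix)).to_csv(path, header=False, index=False)


def write_raster_csv(raster: np.ndarray, path, t_step: float = T_STEP) -> None:
    """Write a boolean (neuron, step) raster as an event list CSV with columns
    neuron, step, time_ms."""
    neuron, step = np.nonzero(np.asarray(raster, dtype=bool))
    pd.DataFrame({"neuron": neuron, "step": step,
                  "time_ms": step * t_step}).to_csv(path, index=False)


def read_raster_csv(path, n_neurons: int, n_steps: int) -> np.ndarray:
    events = pd.read_csv(path)
    raster = np.zeros((n_neurons, n_steps), dtype=bool)
    raster[events["neuron"].to_numpy(), events["step"].to_numpy()] = True
    return raster


def write_channel_matrix_hdf5(matrix: np.ndarray, path) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("intensity", data=np.asarray(matrix, dtype=float))


def read_channel_matrix_hdf5(path) -> np.ndarray:
    with h5py.File(path, "r") as h:
        return h["intensity"][...]


def write_raster_hdf5(raster: np.ndarray, path, t_step: float = T_STEP) -> None:
    """Store a raster as (neuron, step) event lists plus shape metadata."""
    neuron, step = np.nonzero(np.asarray(raster, dtype=bool))
    with h5py.File(path, "w") as h:
        h.create_dataset("neuron", data=neuron)
        h.create_dataset("step", data=step)
        h.attrs["shape"] = raster.shape
        h.attrs["t_step"] = t_step


def read_raster_hdf5(path) -> np.ndarray:
    with h5py.File(path, "r") as h:
        raster = np.zeros(tuple(h.attrs["shape"]), dtype=bool)
        raster[h["neuron"][...], h["step"][...]] = True
    return raster
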