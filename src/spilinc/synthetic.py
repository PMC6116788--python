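"""Desk-scale synthetic datasets for both input modalities.

Image-like data: each class is a distinct deterministic binary glyph (bars,
diagonal bands, frame, cross) at intensity 255 on a 0 background, chosen so
that any two templates share fewer than half of their active pixels; samples
flip a ``noise_level`` fraction of pixels at random.

Temporal (cochleagram-like) data: each class is a distinct trajectory of
active channels over frames — band-limited rising/falling sweeps and pulsing
low/high bands — whose time-summed channel profiles differ across classes in
at least a third of the channels; samples apply multiplicative intensity noise
and a small temporal jitter.

Templates are deterministic functions of (class index, input shape), so tests
can reference them; all sampling is seed-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import read_channel_matrix_csv, write_channel_matrix_csv

__all__ = ["SyntheticSpec", "image_template", "temporal_template",
           "make_image_classes", "make_temporal_classes",
           "write_dataset", "read_dataset",
           "N_IMAGE_TEMPLATES", "N_TEMPORAL_TEMPLATES"]

N_IMAGE_TEMPLATES = 6
N_TEMPORAL_TEMPLATES = 6


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of one synthetic labeled dataset."""

    n_classes: int = 4
    input_shape: tuple = (12, 12)   # (H, W) image or (channels, frames)
    noise_level: float = 0.1        # per-pixel flip / intensity noise fraction
    samples_per_class: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0 <= self.noise_level <= 1:
            raise ValueError("noise_level must be in [0, 1]")
        if self.samples_per_class < 1:
            raise ValueError("samples_per_class must be >= 1")


def image_template(k: int, shape) -> np.ndarray:
    """Binary glyph template for class ``k`` on an (H, W) grid (values 0/1)."""
    if not 0 <= k < N_IMAGE_TEMPLATES:
        raise ValueError(f"no image template for class {k} "
                         f"(have {N_IMAGE_TEMPLATES})")
    h, w = (int(s) for s in shape)
    if h < 10 or w < 10:
        raise ValueError("image templates need at least a 10x10 grid")
    r = np.arange(h)[:, None]
    c = np.arange(w)[None, :]
    # frame thinner than bars/bands so no template pair shares half its pixels
    frame_thick = max(1, min(h, w) // 8)
    thick = max(1, min(h, w) // 6)
    band = max(1, min(h, w) // 6)
    if k == 0:      # left vertical bar
        t = c < math.ceil(w / 3)
    elif k == 1:    # top horizontal bar
        t = r < math.ceil(h / 3)
    elif k == 2:    # main diagonal band
        t = np.abs(r * (w - 1) - c * (h - 1)) <= band * (max(h, w) - 1)
    elif k == 3:    # anti-diagonal band
        t = np.abs(r * (w - 1) + c * (h - 1) - (h - 1) * (w - 1)) \
            <= band * (max(h, w) - 1)
    elif k == 4:    # rectangular frame
        t = ((r < frame_thick) | (r >= h - frame_thick)
             | (c < frame_thick) | (c >= w - frame_thick))
    else:           # center cross
        t = (np.abs(r - (h - 1) / 2) <= thick) | (np.abs(c - (w - 1) / 2) <= thick)
    return np.broadcast_to(t, (h, w)).astype(float)


def temporal_template(k: int, shape) -> np.ndarray:
    """Channel x frame intensity trajectory for class ``k`` (peak 1.0).

    Each class occupies a hard-edged channel support built from sixths of the
    channel axis, chosen so any two class supports differ in at least half
    the channels: 0/1 are rising/falling sweeps clipped to the bottom/middle
    third, 2 a pulsing top-third band, 3/4 pulsing combs over the
    even/odd sixths (in temporal antiphase), 5 a full-range V sweep.
    """
    if not 0 <= k < N_TEMPORAL_TEMPLATES:
        raise ValueError(f"no temporal template for class {k} "
                         f"(have {N_TEMPORAL_TEMPLATES})")
    n_ch, n_fr = (int(s) for s in shape)
    if n_ch < 12 or n_fr < 8:
        raise ValueError("temporal templates need >= 12 channels and 8 frames")
    ch = np.arange(n_ch)[:, None]
    t = np.arange(n_fr)[None, :] / (n_fr - 1)
    width = max(0.75, n_ch / 12)
    sextant = ch * 6 // n_ch

    def sweep(lo, hi, phase):
        center = lo + (hi - lo) * phase
        return np.exp(-0.5 * ((ch - center) / width) ** 2)

    third = n_ch / 3
    if k == 0:      # rising sweep in the bottom third
        m = (ch < third) * sweep(0, third - 1, t)
    elif k == 1:    # falling sweep in the middle third
        m = ((ch >= third) & (ch < 2 * third)) * sweep(2 * third - 1, third, t)
    elif k == 2:    # pulsing top-third band
        m = (ch >= 2 * third) * (0.2 + 0.8 * np.sin(2 * np.pi * t) ** 2)
    elif k == 3:    # even-sixths comb, pulsing
        m = (sextant % 2 == 0) * (0.2 + 0.8 * np.sin(2 * np.pi * t) ** 2)
    elif k == 4:    # odd-sixths comb, pulsing in antiphase
        m = (sextant % 2 == 1) * (0.2 + 0.8 * np.cos(2 * np.pi * t) ** 2)
    else:           # V sweep across the full range
        m = sweep(n_ch - 1, 0, 1 - np.abs(1 - 2 * t))
    return (m * np.ones_like(t)).astype(float)


def _check_template_count(spec: SyntheticSpec, available: int) -> None:
    if spec.n_classes > available:
        raise ValueError(f"only {available} distinct templates available, "
                         f"requested {spec.n_classes} classes")


def make_image_classes(spec: SyntheticSpec):
    """Labeled image samples: per class, the 0/255 glyph template with a
    ``noise_level`` fraction of pixels flipped independently per sample.

    Returns ``(images, labels)`` with images of shape (N, H, W), classes
    interleaved (0, 1, 2, ..., 0, 1, ...) for balanced cyclic training.
    """
    _check_template_count(spec, N_IMAGE_TEMPLATES)
    rng = np.random.default_rng(spec.seed)
    templates = [image_template(k, spec.input_shape) > 0
                 for k in range(spec.n_classes)]
    images, labels = [], []
    for _ in range(spec.samples_per_class):
        for k in range(spec.n_classes):
            flips = rng.random(templates[k].shape) < spec.noise_level
            images.append(np.where(templates[k] ^ flips, 255.0, 0.0))
            labels.append(k)
    return np.stack(images), np.array(labels)


def make_temporal_classes(spec: SyntheticSpec):
    """Labeled channel x frame samples: the class trajectory with
    multiplicative intensity noise (sd = noise_level, clipped at 0) and a
    circular temporal jitter of up to ~20% of ``noise_level`` x frames.

    Returns ``(matrices, labels)``, matrices of shape (N, channels, frames).
    """
    _check_template_count(spec, N_TEMPORAL_TEMPLATES)
    rng = np.random.default_rng(spec.seed)
    n_fr = int(spec.input_shape[1])
    jitter_max = int(round(spec.noise_level * 0.2 * n_fr))
    templates = [temporal_template(k, spec.input_shape)
                 for k in range(spec.n_classes)]
    mats, labels = [], []
    for _ in range(spec.samples_per_class):
        for k in range(spec.n_classes):
            m = templates[k] * (1 + spec.noise_level
                                * rng.standard_normal(templates[k].shape))
            np.clip(m, 0.0, None, out=m)
            if jitter_max:
                m = np.roll(m, int(rng.integers(-jitter_max, jitter_max + 1)),
                            axis=1)
            mats.append(m)
            labels.append(k)
    return np.stack(mats), np.array(labels)


# --------------------------------------------------------------------------
# Dataset directory round-trip (one CSV matrix per sample + label sidecar)
# --------------------------------------------------------------------------

def write_dataset(directory, samples: np.ndarray, labels: np.ndarray) -> None:
    """Write samples as one CSV matrix per file plus a ``labels.csv`` sidecar
    (columns: file, label) — the layout the encoding adapters read."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, sample in enumerate(samples):
        name = f"sample_{i:05d}.csv"
        write_channel_matrix_csv(sample, directory / name)
        names.append(name)
    pd.DataFrame({"file": names, "label": np.asarray(labels, dtype=int)}) \
        .to_csv(directory / "labels.csv", index=False)


def read_dataset(directory):
    """Read a dataset directory written by :func:`write_dataset`; returns
    ``(samples, labels)`` with samples stacked into one array."""
    directory = Path(directory)
    sidecar = pd.read_csv(directory / "labels.csv")
    samples = [read_channel_matrix_csv(directory / name)
               for name in sidecar["file"]]
    return np.stack(samples), sidecar["label"].to_numpy(dtype=int)
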