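"""Run configuration: YAML schema, task presets and model assembly.

A :class:`RunConfig` bundles everything one training/evaluation run needs:
the task preset (image-like or speech-like), per-liquid topology parameters,
STDP and neuron parameters, the training schedule, the presentation timing
and the synthetic-dataset spec. The two shipped presets carry the published
connectivity/weight/plasticity tables for the image and speech tasks at
desk-scale liquid sizes; any field can be overridden with dotted-key
assignments (e.g. ``liquid.n_e=640``).
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .dynamics import LIFParams
from .encoding import EncodedInput, encode_channels, encode_image
from .engine import Liquid, LiquidEnsemble, TrainingSchedule
from .plasticity import STDPParams
from .synthetic import SyntheticSpec
from .topology import LiquidConfig, build_liquid, partition_input

__all__ = ["RunConfig", "load_preset", "load_config", "dump_config",
           "apply_overrides", "build_model", "encode_sample", "PRESETS"]

PRESETS = ("image", "speech")


@dataclass
class RunConfig:
    """Complete, reproducible description of one run."""

    task: str                      # "image-like" | "speech-like"
    liquid: LiquidConfig           # per-liquid topology (n_inp is per liquid)
    stdp: STDPParams
    lif_e: LIFParams
    lif_i: LIFParams
    schedule: TrainingSchedule
    synthetic: SyntheticSpec
    duration: float                # presentation interval (ms)
    t_step: float = 0.5
    n_tags: int = 1                # tags per neuron (1 image / 2 speech)
    n_liquids: int = 1
    partition_scheme: str = "vertical-halves"
    partition_overlap: int = 4
    p_inp_e_ensemble: float | None = None  # input connectivity when n_liquids > 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("image-like", "speech-like"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_tags < 1:
            raise ValueError("n_tags must be >= 1")
        if self.n_liquids < 1:
            raise ValueError("n_liquids must be >= 1")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                v = {k: (list(x) if isinstance(x, tuple) else x)
                     for k, x in dataclasses.asdict(v).items()}
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = copy.deepcopy(d)
        syn = d.get("synthetic", {})
        if "input_shape" in syn:
            syn["input_shape"] = tuple(syn["input_shape"])
        kwargs = dict(
            liquid=LiquidConfig(**d.pop("liquid")),
            stdp=STDPParams(**d.pop("stdp")),
            lif_e=LIFParams(**d.pop("lif_e", {})),
            lif_i=LIFParams(**{**dataclasses.asdict(LIFParams.inhibitory()),
                               **d.pop("lif_i", {})}),
            schedule=TrainingSchedule(**d.pop("schedule")),
            synthetic=SyntheticSpec(**d.pop("synthetic")),
        )
        kwargs.update(d)
        return cls(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def dump_config(cfg: RunConfig, path) -> None:
    """Write a config echo sufficient to reproduce the run bit-exactly."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_preset(name: str) -> RunConfig:
    """Load a named shipped preset (``image`` or ``speech``)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")
    text = resources.files("spilinc").joinpath(f"presets/{name}.yaml").read_text()
    return RunConfig.from_dict(yaml.safe_load(text))


def _coerce(old, value: str):
    if isinstance(old, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(old, int) and not isinstance(old, bool):
        return int(value)
    if isinstance(old, float):
        return float(value)
    if isinstance(old, (tuple, list)):
        return [int(x) for x in value.strip("[]() ").split(",")]
    return value


def apply_overrides(cfg: RunConfig, assignments) -> RunConfig:
    """Apply dotted-key overrides (``section.field=value`` or ``field=value``)
    to a config, returning a new one; unknown keys raise."""
    d = cfg.to_dict()
    for item in assignments:
        key, _, value = item.partition("=")
        if not _:
            raise ValueError(f"override {item!r} is not of the form key=value")
        parts = key.strip().split(".")
        node = d
        for p in parts[:-1]:
            if p not in node or not isinstance(node[p], dict):
                raise ValueError(f"unknown config section {p!r} in {key!r}")
            node = node[p]
        leaf = parts[-1]
        if leaf not in node:
            raise ValueError(f"unknown config field {key!r}")
        node[leaf] = _coerce(node[leaf], value.strip())
    return RunConfig.from_dict(d)


def input_shape(cfg: RunConfig) -> tuple:
    return tuple(cfg.synthetic.input_shape)


def build_model(cfg: RunConfig):
    """Assemble the configured model.

    Returns ``(ensemble, partitions)``: a :class:`LiquidEnsemble` whose
    per-liquid ``n_inp`` matches its input partition. With ``n_liquids = 1``
    the single partition is the whole input and the ensemble reduces to the
    single-liquid model.
    """
    shape = input_shape(cfg)
    dim = int(np.prod(shape)) if cfg.task == "image-like" else int(shape[0])
    part_shape = shape if cfg.task == "image-like" else shape[0]
    partitions = partition_input(part_shape, cfg.partition_scheme,
                                 cfg.n_liquids, cfg.partition_overlap)
    p_inp_e = cfg.liquid.p_inp_e
    if cfg.n_liquids > 1 and cfg.p_inp_e_ensemble is not None:
        p_inp_e = cfg.p_inp_e_ensemble
    liquids = []
    for i, part in enumerate(partitions):
        lc = dataclasses.replace(cfg.liquid, n_inp=len(part), p_inp_e=p_inp_e,
                                 seed=cfg.liquid.seed + i)
        liquids.append(Liquid(build_liquid(lc), cfg.lif_e, cfg.lif_i, cfg.stdp))
    return LiquidEnsemble(liquids, partitions), partitions


def encode_sample(cfg: RunConfig, sample: np.ndarray) -> EncodedInput:
    """Encode one raw sample (full input, before partitioning) according to
    the task preset."""
    if cfg.task == "image-like":
        return encode_image(sample, cfg.t_step, cfg.duration)
    return encode_channels(sample, cfg.t_step, cfg.duration)
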