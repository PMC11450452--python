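"""Run configuration (YAML) and run manifests.

Config keys mirror the model's parameter names: ``f_max``, ``tau_zi``,
``tau_zj``, ``tau_p``, ``tau_m``, ``T_no_input``, ``T_ffwd``, ``T_overlap``,
``T_recr``, ``N_conn_ff``, ``N_conn_rec``, ``N_conn_fb``, ``N_flipconn``,
``N_intvconn``, plus ``variant``, ``seed``, and the population shapes.
"""

from __future__ import annotations

import dataclasses
import time
from pathlib import Path

import yaml

from .network import NetworkConfig

__all__ = ["load_config", "save_config", "RunManifest"]

# YAML key -> NetworkConfig field
_KEY_MAP = {
    "T_no_input": "t_no_input",
    "T_ffwd": "t_ffwd",
    "T_overlap": "t_overlap",
    "T_recr": "t_recr",
    "N_conn_ff": "n_conn_ff",
    "N_conn_rec": "n_conn_rec",
    "N_conn_fb": "n_conn_fb",
    "N_flipconn": "n_flipconn",
    "N_intvconn": "n_intvconn",
    "N_epoch": "n_epochs",
}


def load_config(path) -> NetworkConfig:
    """Build a NetworkConfig from a YAML file.

    The ``variant`` key selects the default parameter bindings; any other
    key overrides them.  Shapes are given as ``inp_shape: [H, M]`` /
    ``hid_shape: [H, M]``.
    """
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    variant = raw.pop("variant", "spspk_full")
    inp_shape = tuple(raw.pop("inp_shape", (784, 2)))
    hid_shape = tuple(raw.pop("hid_shape", (100, 100)))
    overrides = {}
    valid = {f.name for f in dataclasses.fields(NetworkConfig)}
    for key, value in raw.items():
        name = _KEY_MAP.get(key, key)
        if name not in valid:
            raise ValueError(f"unknown config key {key!r}")
        overrides[name] = value
    return NetworkConfig.from_variant(variant, inp_shape=inp_shape,
                                      hid_shape=hid_shape, **overrides)


def save_config(cfg: NetworkConfig, path) -> None:
    d = dataclasses.asdict(cfg)
    d["inp_shape"] = [cfg.inp_shape.n_hyper, cfg.inp_shape.n_mini]
    d["hid_shape"] = [cfg.hid_shape.n_hyper, cfg.hid_shape.n_mini]
    with open(path, "w") as f:
        yaml.safe_dump(d, f, sort_keys=False)


@dataclasses.dataclass
class RunManifest:
    """What a run did: config snapshot, seed, wall-times, output paths."""

    config: dict
    seed: int
    outputs: list[str] = dataclasses.field(default_factory=list)
    wall_times: dict = dataclasses.field(default_factory=dict)
    _t0: dict = dataclasses.field(default_factory=dict, repr=False)

    @classmethod
    def for_run(cls, cfg: NetworkConfig) -> "RunManifest":
        d = dataclasses.asdict(cfg)
        d["inp_shape"] = [cfg.inp_shape.n_hyper, cfg.inp_shape.n_mini]
        d["hid_shape"] = [cfg.hid_shape.n_hyper, cfg.hid_shape.n_mini]
        return cls(config=d, seed=cfg.seed)

    def start(self, stage: str) -> None:
        self._t0[stage] = time.perf_counter()

    def stop(self, stage: str) -> None:
        self.wall_times[stage] = time.perf_counter() - self._t0.pop(stage)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        blob = {"config": self.config, "seed": self.seed,
                "outputs": self.outputs, "wall_times": self.wall_times}
        Path(path).write_text(yaml.safe_dump(blob, sort_keys=False))
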