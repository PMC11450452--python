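"""Checkpointing: the full network state in one structured container.

Uses NumPy's ``.npz`` archive with hierarchical ``{name}/{field}`` keys —
``{projection}/{z_pre|z_post|p_pre|p_post|p_joint|bias|weight|conn|patch_mask}``
and ``{population}/{v|pi}`` — plus the config serialized as JSON.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .network import Network, NetworkConfig, build_network
from .population import PopulationShape
from .rewiring import ConnectivityMask

__all__ = ["save_checkpoint", "load_checkpoint", "checkpoint_arrays"]


def _config_to_json(cfg: NetworkConfig) -> str:
    d = dataclasses.asdict(cfg)
    d["inp_shape"] = [cfg.inp_shape.n_hyper, cfg.inp_shape.n_mini]
    d["hid_shape"] = [cfg.hid_shape.n_hyper, cfg.hid_shape.n_mini]
    return json.dumps(d)


def _config_from_json(blob: str) -> NetworkConfig:
    d = json.loads(blob)
    d["inp_shape"] = PopulationShape(*d["inp_shape"])
    d["hid_shape"] = PopulationShape(*d["hid_shape"])
    return NetworkConfig(**d)


def checkpoint_arrays(net: Network) -> dict[str, np.ndarray]:
    """Flat key -> array mapping of the complete network state."""
    arrays: dict[str, np.ndarray] = {}
    for name, pop in (("inp", net.inp), ("hid", net.hid), ("inprc", net.inprc)):
        arrays[f"{name}/v"] = pop.v
        arrays[f"{name}/pi"] = pop.pi
    for p in net.projections:
        t = p.traces
        arrays.update({
            f"{p.name}/z_pre": t.z_pre, f"{p.name}/z_post": t.z_post,
            f"{p.name}/p_pre": t.p_pre, f"{p.name}/p_post": t.p_post,
            f"{p.name}/p_joint": t.p_joint,
            f"{p.name}/bias": p.weights.bias,
            f"{p.name}/weight": p.weights.weight,
            f"{p.name}/conn": p.weights.conn,
            f"{p.name}/patch_mask": p.mask.patch,
        })
    return arrays


def save_checkpoint(net: Network, path) -> None:
    arrays = checkpoint_arrays(net)
    arrays["config_json"] = np.array(_config_to_json(net.config))
    arrays["pattern_count"] = np.array(net.pattern_count)
    np.savez(path, **arrays)


def load_checkpoint(path) -> Network:
    with np.load(path, allow_pickle=False) as data:
        cfg = _config_from_json(str(data["config_json"]))
        net = build_network(cfg)
        net.pattern_count = int(data["pattern_count"])
        for name, pop in (("inp", net.inp), ("hid", net.hid),
                          ("inprc", net.inprc)):
            pop.v = data[f"{name}/v"].copy()
            pop.pi = data[f"{name}/pi"].copy()
        for p in net.projections:
            t = p.traces
            t.z_pre = data[f"{p.name}/z_pre"].copy()
            t.z_post = data[f"{p.name}/z_post"].copy()
            t.p_pre = data[f"{p.name}/p_pre"].copy()
            t.p_post = data[f"{p.name}/p_post"].copy()
            t.p_joint = data[f"{p.name}/p_joint"].copy()
            p.weights.bias = data[f"{p.name}/bias"].copy()
            p.weights.weight = data[f"{p.name}/weight"].copy()
            p.weights.conn = data[f"{p.name}/conn"].copy()
            p.weights.invalidate()
            p.mask = ConnectivityMask(data[f"{p.name}/patch_mask"].copy(),
                                      p.mask.n_conn)
    return net
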