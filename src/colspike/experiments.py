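"""Experiment drivers: train-and-score a single configuration, the
(f_max, tau_m, tau_z) sensitivity sweep, and the associative-memory task
battery over the model variants.
"""

from __future__ import annotations

import dataclasses
from itertools import product

import numpy as np
import pandas as pd

from .metrics import ReadoutParams, train_linear_readout
from .population import (
    ActivationVariant,
    PopulationShape,
    PopulationState,
    sample_spikes,
    softmax_by_hypercolumn,
    step_membrane,
)
from .network import (
    Network,
    NetworkConfig,
    build_network,
    collect,
    evaluate,
    train,
)

__all__ = [
    "hidden_representations",
    "fit_and_score",
    "sweep_fmax_tau",
    "run_task_battery",
    "as_feedforward",
    "reconstruction_accuracy",
]


def firing_statistics(
    n_hyper: int = 100,
    n_mini: int = 100,
    f_max: float = 100.0,
    dt: float = 0.001,
    duration: float = 100.0,
    seed: int = 0,
    clamp_winner: bool = False,
) -> dict:
    """Long-run spike statistics of one population under fixed drive.

    A fixed external current (random, or a strong current clamping the first
    unit of each hypercolumn to posterior ~1 when ``clamp_winner``) sets the
    softmax beliefs once; spikes are then sampled for ``duration`` seconds.
    Returns empirical mean per-unit rate (Hz), mean spikes per timestep
    across the population, the mean rate of the first unit of each
    hypercolumn, and the analytic expectations with their sampling sigmas.
    """
    shape = PopulationShape(n_hyper, n_mini)
    rng = np.random.default_rng(seed)
    state = PopulationState.zeros(shape)
    if clamp_winner:
        I = np.zeros(shape.size)
        I[0::n_mini] = 50.0
    else:
        I = rng.normal(size=shape.size)
    state.I_ext = I
    step_membrane(state, [], tau_m=dt, dt=dt)  # tau_m = dt: v = I directly
    pi = softmax_by_hypercolumn(state.v, shape)
    variant = ActivationVariant("spiking", f_max)
    n_steps = round(duration / dt)
    counts = np.zeros(shape.size)
    for _ in range(n_steps):
        counts += sample_spikes(pi, variant, dt, rng)
    p = pi * f_max * dt
    total_var = (p * (1 - p)).sum() * n_steps
    mu = f_max * dt
    return {
        "n_steps": n_steps,
        "mean_rate_hz": counts.sum() / (shape.size * duration),
        "mean_rate_expected_hz": f_max / n_mini,
        "mean_rate_sigma_hz": np.sqrt(total_var) / (shape.size * duration),
        "spikes_per_step": counts.sum() / n_steps,
        "spikes_per_step_expected": n_hyper * mu,
        "spikes_per_step_sigma": np.sqrt(total_var) / n_steps,
        "winner_rate_hz": counts[0::n_mini].mean() / duration,
        "winner_rate_expected_hz": pi[0::n_mini].mean() * f_max,
        "winner_rate_sigma_hz": np.sqrt(
            (p[0::n_mini] * (1 - p[0::n_mini])).sum() * n_steps
        ) / (n_hyper * duration),
    }


def as_feedforward(net: Network) -> Network:
    """Feedforward-only sibling of a trained full network.

    During training the recurrent projection propagates no activity, so the
    learned feedforward/feedback state of a full network is identical to what
    the feedforward-only variant would have learned with the same seed; this
    copies that state into a network evaluated under the feedforward-only
    phase schedule (t_overlap = t_recr = 0, no recurrent projection).
    """
    cfg = net.config
    if not cfg.recurrent:
        raise ValueError("network is already feedforward-only")
    ff_variant = cfg.variant.replace("_full", "_ff")
    cfg_ff = NetworkConfig.from_variant(
        ff_variant,
        inp_shape=(cfg.inp_shape.n_hyper, cfg.inp_shape.n_mini),
        hid_shape=(cfg.hid_shape.n_hyper, cfg.hid_shape.n_mini),
        tau_p=cfg.tau_p, eps=cfg.eps, seed=cfg.seed,
        n_conn_ff=cfg.n_conn_ff, n_conn_fb=cfg.n_conn_fb,
        f_max=cfg.f_max, tau_zi=cfg.tau_zi, tau_zj=cfg.tau_zj,
        tau_m=cfg.tau_m, t_no_input=cfg.t_no_input, t_ffwd=cfg.t_ffwd,
        init_noise=cfg.init_noise,
    )
    sibling = build_network(cfg_ff)
    for src, dst in ((net.ff, sibling.ff), (net.fb, sibling.fb)):
        dst.traces = src.traces.copy()
        dst.weights.bias = src.weights.bias.copy()
        dst.weights.weight = src.weights.weight.copy()
        dst.weights.conn = src.weights.conn.copy()
        dst.weights.invalidate()
        dst.mask = src.mask.copy()
    sibling.pattern_count = net.pattern_count
    return sibling


def reconstruction_accuracy(records, prototypes: np.ndarray,
                            labels: np.ndarray) -> float:
    """Fraction of patterns whose INPRC reconstruction at pattern end is
    nearest (by cosine) to the true prototype."""
    from .network import reconstruct_image

    P = np.asarray(prototypes, dtype=float).reshape(len(prototypes), -1)
    P_norm = np.linalg.norm(P, axis=1)
    correct = 0
    for rec, y in zip(records, labels):
        img = reconstruct_image(rec.at["end"]["inprc_z"])
        sims = P @ img / (P_norm * np.linalg.norm(img) + 1e-12)
        correct += int(np.argmax(sims) == y)
    return correct / len(labels)


def hidden_representations(net: Network, images: np.ndarray) -> np.ndarray:
    """HID z-traces (feedforward z_post) at pattern end, one row per image."""
    records = evaluate(net, images)
    return collect(records, "hid_z")


def fit_and_score(
    config: NetworkConfig,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    test_images: np.ndarray,
    test_labels: np.ndarray,
    readout: ReadoutParams | None = None,
) -> tuple[Network, float]:
    """Train the network, then a linear readout on its hidden z-traces;
    return (network, held-out accuracy)."""
    net = build_network(config)
    train(net, train_images)
    reps_train = hidden_representations(net, train_images)
    reps_test = hidden_representations(net, test_images)
    readout = readout or ReadoutParams(seed=config.seed)
    _, acc = train_linear_readout(reps_train, train_labels,
                                  reps_test, test_labels, readout)
    return net, acc


def sweep_fmax_tau(
    base_config: NetworkConfig,
    f_max_values,
    tau_m_values,
    tau_z_values,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    test_images: np.ndarray,
    test_labels: np.ndarray,
) -> pd.DataFrame:
    """Grid sweep over (f_max, tau_m, tau_z); one train/eval run per cell.

    Returns a table with columns f_max, tau_m, tau_z, accuracy.  A 1x1x1
    grid reduces to a single run of :func:`fit_and_score`.
    """
    cells = list(product(f_max_values, tau_m_values, tau_z_values))
    if not cells:
        raise ValueError("empty sweep grid")
    rows = []
    for f_max, tau_m, tau_z in cells:
        cfg = dataclasses.replace(base_config, f_max=f_max, tau_m=tau_m,
                                  tau_zi=tau_z, tau_zj=tau_z)
        _, acc = fit_and_score(cfg, train_images, train_labels,
                               test_images, test_labels)
        rows.append({"f_max": f_max, "tau_m": tau_m, "tau_z": tau_z,
                     "accuracy": acc})
    return pd.DataFrame(rows)


def run_task_battery(
    nets: dict[str, Network],
    train_images: np.ndarray,
    train_labels: np.ndarray,
    task_sets: dict[tuple[str, float], tuple[np.ndarray, np.ndarray]],
    readout: ReadoutParams | None = None,
) -> pd.DataFrame:
    """Readout accuracy per (variant, task, difficulty).

    ``nets`` maps variant name -> trained network; ``task_sets`` maps
    (task, difficulty) -> (images, labels) of the corrupted test set.  The
    readout is trained once per variant on clean training representations.
    """
    if not nets:
        raise ValueError("no trained networks supplied")
    rows = []
    for variant, net in nets.items():
        if net is None:
            raise ValueError(f"missing checkpoint for variant {variant!r}")
        reps_train = hidden_representations(net, train_images)
        model, _ = train_linear_readout(
            reps_train, train_labels,
            params=readout or ReadoutParams(seed=net.config.seed),
        )
        for (task, difficulty), (images, labels) in task_sets.items():
            reps = hidden_representations(net, images)
            acc = model.accuracy(reps, labels)
            rows.append({"variant": variant, "task": task,
                         "difficulty": difficulty, "accuracy": acc})
    return pd.DataFrame(rows)
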