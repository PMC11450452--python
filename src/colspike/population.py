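"""Population dynamics: membrane integration, hypercolumn softmax, spike
sampling, and the pixel-intensity input-current encoding.

A population is a grid of ``n_hyper`` hypercolumn modules, each holding
``n_mini`` minicolumn units that compete through a softmax over the membrane
voltage (soft winner-takes-all lateral inhibition).  Units emit either the
softmax probability itself (rate mode) or independent Bernoulli spikes with
per-step probability ``pi * f_max * dt`` (spiking mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synapse import ProjectionWeights

__all__ = [
    "PopulationShape",
    "PopulationState",
    "ActivationVariant",
    "step_membrane",
    "softmax_by_hypercolumn",
    "sample_spikes",
    "encode_input_current",
]


@dataclass(frozen=True)
class PopulationShape:
    n_hyper: int
    n_mini: int

    def __post_init__(self) -> None:
        if self.n_hyper < 1:
            raise ValueError("n_hyper must be >= 1")
        if self.n_mini < 2:
            raise ValueError("n_mini must be >= 2")

    @property
    def size(self) -> int:
        return self.n_hyper * self.n_mini


@dataclass(frozen=True)
class ActivationVariant:
    """How a population communicates: its softmax output or samples of it."""

    mode: str  # "rate" | "spiking"
    f_max: float = 0.0  # Hz, ignored in rate mode

    def __post_init__(self) -> None:
        if self.mode not in ("rate", "spiking"):
            raise ValueError(f"unknown activation mode {self.mode!r}")


@dataclass
class PopulationState:
    """Membrane voltages, softmax beliefs, spikes, external current."""

    v: np.ndarray
    pi: np.ndarray
    s: np.ndarray
    I_ext: np.ndarray

    @classmethod
    def zeros(cls, shape: PopulationShape) -> "PopulationState":
        n = shape.size
        return cls(
            v=np.zeros(n),
            pi=np.full(n, 1.0 / shape.n_mini),
            s=np.zeros(n),
            I_ext=np.zeros(n),
        )

    def copy(self) -> "PopulationState":
        return PopulationState(self.v.copy(), self.pi.copy(), self.s.copy(),
                               self.I_ext.copy())


def step_membrane(
    state: PopulationState,
    inputs: Sequence[tuple[np.ndarray, ProjectionWeights, bool]],
    tau_m: float,
    dt: float,
) -> PopulationState:
    """One forward-Euler step of the membrane voltage (in place).

    ``inputs`` lists incoming projections as ``(z_pre, weights, gate)``.
    The total drive is ``u = I_ext + sum_gated (bias + z_pre @ (w * conn))``;
    an ungated projection contributes nothing, including its bias.  With
    ``tau_m == dt`` the voltage equals the instantaneous drive after one step.
    """
    u = state.I_ext.copy()
    n = state.v.shape[0]
    for z_pre, w, gate in inputs:
        if not gate:
            continue
        if w.weight.shape[0] != z_pre.shape[0] or w.weight.shape[1] != n:
            raise ValueError(
                f"projection shape {w.weight.shape} incompatible with "
                f"pre size {z_pre.shape[0]} / post size {n}"
            )
        u += w.bias
        u += z_pre @ w.masked_weight()
    state.v += (dt / tau_m) * (u - state.v)
    return state


def softmax_by_hypercolumn(v: np.ndarray, shape: PopulationShape) -> np.ndarray:
    """Softmax within each hypercolumn block of ``n_mini`` entries."""
    vb = v.reshape(shape.n_hyper, shape.n_mini)
    e = np.exp(vb - vb.max(axis=1, keepdims=True))
    return (e / e.sum(axis=1, keepdims=True)).reshape(-1)


def sample_spikes(
    pi: np.ndarray,
    variant: ActivationVariant,
    dt: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Communicated activity for one timestep.

    Rate mode returns ``pi`` unchanged; spiking mode draws independent
    Bernoulli samples with success probability ``pi * f_max * dt``.
    """
    pi = np.asarray(pi, dtype=float)
    if (pi < 0).any() or (pi > 1).any():
        raise ValueError("pi must lie in [0, 1]")
    if variant.mode == "rate":
        return pi.copy()
    mu = variant.f_max * dt
    if not 0.0 < mu <= 1.0:
        raise ValueError(f"f_max*dt = {mu} must lie in (0, 1] for spiking mode")
    if rng is None:
        raise ValueError("spiking mode requires an rng")
    return (rng.random(pi.shape) < pi * mu).astype(float)


def encode_input_current(
    u: np.ndarray, clip: float = 1e-10, log_base: str = "e"
) -> np.ndarray:
    """Map pixel intensities in [0, 1] onto ON/OFF input currents.

    Pixel ``j`` drives a 2-minicolumn hypercolumn with currents
    ``log(max(u_j, clip))`` (ON, index ``2j``) and ``log(max(1-u_j, clip))``
    (OFF, index ``2j+1``); after a softmax with ``tau_m = dt`` and no other
    input this yields ``pi = (u_j, 1-u_j)`` up to clipping.  ``log_base``
    may be "e" (default) or "10".
    """
    u = np.asarray(u, dtype=float).reshape(-1)
    if (u < 0).any() or (u > 1).any():
        raise ValueError("pixel intensities must lie in [0, 1]")
    if clip <= 0:
        raise ValueError("clip must be positive")
    log = np.log if log_base == "e" else np.log10
    if log_base not in ("e", "10"):
        raise ValueError(f"log_base must be 'e' or '10', got {log_base!r}")
    out = np.empty(2 * u.shape[0])
    out[0::2] = log(np.maximum(u, clip))
    out[1::2] = log(np.maximum(1.0 - u, clip))
    return out
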