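"""Bayesian-Hebbian trace plasticity for a single projection.

Each projection between a pre- and a post-synaptic population maintains a
cascade of exponential filters:

* **z-traces** — short-time-constant filters of the pre/post spike trains,
  setting the coincidence window for Hebbian learning.  Spikes are scaled by
  ``1 / mu_spk`` so the filtered trace recovers the underlying firing
  probability regardless of the maximum firing rate.
* **p-traces** — long-time-constant filters of the z-traces and their outer
  product, i.e. running estimates of marginal and joint activation
  probabilities.
* **bias / weight** — log prior of the post-synaptic unit and point-wise
  mutual information between pre/post units, both in nats.

All updates use forward Euler with the global timestep ``dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SynapseParams",
    "TraceState",
    "ProjectionWeights",
    "step_z_traces",
    "step_p_traces",
    "compute_bias_weight",
]


@dataclass(frozen=True)
class SynapseParams:
    """Per-projection trace parameters.

    Parameters
    ----------
    tau_zi, tau_zj : float
        Time constants (s) of the pre-/post-synaptic z-traces.
    tau_p : float
        Time constant (s) of the probability traces.
    f_max : float
        Maximum firing rate (Hz); together with ``dt`` it fixes the spike
        scaling factor ``mu_spk = f_max * dt``.
    dt : float
        Simulation timestep (s).
    eps : float
        Probability floor applied before the log transform.
    """

    tau_zi: float
    tau_zj: float
    tau_p: float
    f_max: float
    dt: float = 0.001
    eps: float = 1e-4

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.tau_zi < self.dt or self.tau_zj < self.dt:
            raise ValueError(
                f"z-trace time constants must be >= dt={self.dt}: "
                f"tau_zi={self.tau_zi}, tau_zj={self.tau_zj}"
            )
        if self.tau_p < self.tau_zi:
            raise ValueError(f"tau_p={self.tau_p} must be >= tau_zi={self.tau_zi}")
        mu = self.f_max * self.dt
        if not 0.0 < mu <= 1.0:
            raise ValueError(f"mu_spk = f_max*dt = {mu} must lie in (0, 1]")
        if not 0.0 < self.eps < 1.0:
            raise ValueError(f"eps={self.eps} must lie in (0, 1)")

    @property
    def mu_spk(self) -> float:
        """Spike scaling factor ``f_max * dt`` (dimensionless)."""
        return self.f_max * self.dt


@dataclass
class TraceState:
    """z- and p-trace state of one projection.

    ``p_joint`` has shape ``(n_pre, n_post)``; the marginals are vectors over
    the respective minicolumn units.
    """

    z_pre: np.ndarray
    z_post: np.ndarray
    p_pre: np.ndarray
    p_post: np.ndarray
    p_joint: np.ndarray

    @classmethod
    def uniform(cls, n_pre: int, n_post: int, m_pre: int, m_post: int) -> "TraceState":
        """Initialize with a uniform prior.

        Marginals start at ``1/M`` of their population (the softmax average)
        and the joint at the product of the marginals, so that initial weights
        are exactly zero and biases equal ``log(1/M)``.
        """
        p_pre = np.full(n_pre, 1.0 / m_pre)
        p_post = np.full(n_post, 1.0 / m_post)
        return cls(
            z_pre=np.zeros(n_pre),
            z_post=np.zeros(n_post),
            p_pre=p_pre,
            p_post=p_post,
            p_joint=np.outer(p_pre, p_post),
        )

    def copy(self) -> "TraceState":
        return TraceState(
            self.z_pre.copy(), self.z_post.copy(),
            self.p_pre.copy(), self.p_post.copy(), self.p_joint.copy(),
        )


@dataclass
class ProjectionWeights:
    """Learned bias/weight plus the binary minicolumn-level connectivity.

    ``conn`` is constant within each (sending hypercolumn, receiving
    hypercolumn) patch: structural plasticity acts at patch granularity and
    the patch state is inherited by every minicolumn pair inside it.
    """

    bias: np.ndarray            # (n_post,), nats
    weight: np.ndarray          # (n_pre, n_post), nats
    conn: np.ndarray            # (n_pre, n_post), 0/1
    _w_eff: np.ndarray | None = field(default=None, repr=False)

    def masked_weight(self) -> np.ndarray:
        """``weight * conn`` — the transmitting weights (cached)."""
        if self._w_eff is None:
            self._w_eff = self.weight * self.conn
        return self._w_eff

    def invalidate(self) -> None:
        self._w_eff = None


def _check_spikes(s: np.ndarray, n: int, name: str) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if s.shape != (n,):
        raise ValueError(f"{name} has shape {s.shape}, expected ({n},)")
    if not np.isin(s, (0.0, 1.0)).all():
        raise ValueError(f"{name} must be a 0/1 vector")
    return s


def step_z_traces(
    state: TraceState,
    s_pre: np.ndarray,
    s_post: np.ndarray,
    params: SynapseParams,
    *,
    require_binary: bool = True,
) -> TraceState:
    """One forward-Euler step of the z-trace filters (in place).

    ``z <- z + (dt/tau_z) * (s/mu_spk - z)`` on both sides.  Spike vectors
    must be binary unless ``require_binary`` is False (rate-based variants
    communicate the continuous softmax output, already in [0, 1], with
    ``mu_spk = 1``).
    """
    if require_binary:
        s_pre = _check_spikes(s_pre, state.z_pre.shape[0], "s_pre")
        s_post = _check_spikes(s_post, state.z_post.shape[0], "s_post")
    mu = params.mu_spk
    state.z_pre += (params.dt / params.tau_zi) * (s_pre / mu - state.z_pre)
    state.z_post += (params.dt / params.tau_zj) * (s_post / mu - state.z_post)
    return state


def step_p_traces(state: TraceState, params: SynapseParams) -> TraceState:
    """One forward-Euler step of the probability traces (in place).

    Marginals track the z-traces; the joint tracks the outer product of the
    pre/post z-traces.
    """
    k = params.dt / params.tau_p
    state.p_pre += k * (state.z_pre - state.p_pre)
    state.p_post += k * (state.z_post - state.p_post)
    state.p_joint += k * (np.outer(state.z_pre, state.z_post) - state.p_joint)
    return state


def compute_bias_weight(
    state: TraceState, params: SynapseParams
) -> tuple[np.ndarray, np.ndarray]:
    """Map p-traces onto (bias, weight).

    ``bias_j = log max(p_j, eps)`` and
    ``w_ij = log( max(p_ij, eps^2) / (max(p_i, eps) * max(p_j, eps)) )``,
    natural log.  Flooring keeps every entry finite.
    """
    eps = params.eps
    pi = np.maximum(state.p_pre, eps)
    pj = np.maximum(state.p_post, eps)
    pij = np.maximum(state.p_joint, eps * eps)
    bias = np.log(pj)
    # grouping the marginal terms keeps the weight bitwise symmetric for
    # recurrent projections (p_i == p_j, p_ij symmetric)
    weight = np.log(pij) - (np.log(pi)[:, None] + np.log(pj)[None, :])
    return bias, weight
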