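"""Activity-dependent structural plasticity.

Connectivity between two populations is patchy: a binary mask over
(sending hypercolumn, receiving hypercolumn) pairs, inherited by every
minicolumn pair inside a patch.  Each receiving hypercolumn keeps exactly
``n_conn`` active incoming patches.  Rewiring greedily maximizes a
normalized mutual-information score per patch by flipping the
lowest-scoring active patch with the highest-scoring silent one.  Silent
patches transmit no current but keep updating their traces, so they stay
scoreable candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import PopulationShape
from .synapse import ProjectionWeights, TraceState

__all__ = [
    "ConnectivityMask",
    "init_random_connectivity",
    "patch_scores",
    "rewire_step",
]


@dataclass
class ConnectivityMask:
    """Patch-level connectivity: ``patch[s, r]`` is True when the patch from
    sending hypercolumn ``s`` to receiving hypercolumn ``r`` is active."""

    patch: np.ndarray  # bool, (h_pre, h_post)
    n_conn: int

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=bool)
        counts = self.patch.sum(axis=0)
        if not (counts == self.n_conn).all():
            raise ValueError(
                "every receiving hypercolumn must have exactly "
                f"n_conn={self.n_conn} active incoming patches; got {counts}"
            )

    def expand(self, m_pre: int, m_post: int) -> np.ndarray:
        """Minicolumn-level 0/1 connectivity: patch state repeated over all
        (m_pre x m_post) minicolumn pairs of each patch."""
        return np.repeat(
            np.repeat(self.patch.astype(float), m_pre, axis=0), m_post, axis=1
        )

    def copy(self) -> "ConnectivityMask":
        return ConnectivityMask(self.patch.copy(), self.n_conn)


def init_random_connectivity(
    shape_pre: PopulationShape,
    shape_post: PopulationShape,
    n_conn: int,
    rng: np.random.Generator,
) -> ConnectivityMask:
    """Each receiving hypercolumn draws ``n_conn`` distinct incoming patches
    uniformly without replacement."""
    h_pre, h_post = shape_pre.n_hyper, shape_post.n_hyper
    if not 1 <= n_conn <= h_pre:
        raise ValueError(f"n_conn={n_conn} out of range [1, {h_pre}]")
    patch = np.zeros((h_pre, h_post), dtype=bool)
    for r in range(h_post):
        patch[rng.choice(h_pre, size=n_conn, replace=False), r] = True
    return ConnectivityMask(patch, n_conn)


def patch_scores(
    state: TraceState,
    weights: ProjectionWeights,
    mask: ConnectivityMask,
    shape_pre: PopulationShape,
    shape_post: PopulationShape,
) -> np.ndarray:
    """Normalized mutual-information score per (sending, receiving) patch.

    The numerator sums ``p_ij * w_ij`` over the minicolumn pairs of the
    patch; the denominator is the sending hypercolumn's count of outgoing
    connections.  Silent connections are physically present (they keep
    updating their traces), so every patch slot counts and the denominator
    is the constant number of receiving hypercolumns.  Normalizing by the
    *active* out-degree instead couples a sender's score to its own degree
    and makes the greedy flips oscillate forever even on converged
    statistics, so flip counts could never decay.  Silent patches are scored
    too — they are the rewiring candidates.
    """
    h_pre, m_pre = shape_pre.n_hyper, shape_pre.n_mini
    h_post, m_post = shape_post.n_hyper, shape_post.n_mini
    pw = (state.p_joint * weights.weight).reshape(h_pre, m_pre, h_post, m_post)
    mi = pw.sum(axis=(1, 3))
    return mi / h_post


def rewire_step(
    mask: ConnectivityMask, scores: np.ndarray, n_flips: int
) -> tuple[ConnectivityMask, int]:
    """Greedy flip step on frozen scores.

    Per receiving hypercolumn, pair its silent incoming patches (best first)
    with its active ones (worst first); every pair with a positive score gain
    is a flip candidate.  Candidates are executed globally in order of
    decreasing gain until ``n_flips`` flips are spent.  Ties break on the
    lowest sender index.  The active-count invariant is preserved exactly.
    """
    patch = mask.patch.copy()
    h_pre, h_post = patch.shape
    candidates: list[tuple[float, int, int, int, int]] = []
    for r in range(h_post):
        act = np.flatnonzero(patch[:, r])
        sil = np.flatnonzero(~patch[:, r])
        if act.size == 0 or sil.size == 0:
            continue
        # active ascending by (score, index); silent descending by score,
        # ascending by index on ties
        act = act[np.lexsort((act, scores[act, r]))]
        sil = sil[np.lexsort((sil, -scores[sil, r]))]
        for k in range(min(act.size, sil.size)):
            gain = scores[sil[k], r] - scores[act[k], r]
            if gain <= 0:
                break
            candidates.append((gain, r, int(sil[k]), int(act[k]), k))
    # largest gain first across receivers, deterministic tie-break
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    n_done = 0
    for gain, r, s_on, s_off, _k in candidates:
        if n_done >= n_flips:
            break
        patch[s_on, r] = True
        patch[s_off, r] = False
        n_done += 1
    return ConnectivityMask(patch, mask.n_conn), n_done
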