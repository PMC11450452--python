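"""Evaluation computations: Gaussian-kernel firing-rate estimation,
cosine-similarity matrices, the orthogonality ratio, prototype extraction
with attraction indices, and a multinomial-logistic readout trained with
minibatch Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SimilarityResult",
    "PrototypeResult",
    "ReadoutParams",
    "LinearReadout",
    "firing_rate_estimate",
    "cosine_similarity_matrix",
    "orthogonality_ratio",
    "similarity_result",
    "extract_prototypes",
    "train_linear_readout",
]


@dataclass
class SimilarityResult:
    matrix: np.ndarray                 # (n, n) pairwise cosine similarity
    labels: np.ndarray | None = None
    s_ortho: float | None = None


@dataclass
class PrototypeResult:
    s_min: float
    n_prototypes: int
    assignment: np.ndarray             # pattern -> prototype id
    attraction: np.ndarray             # prototype -> member count
    reconstruction: np.ndarray | None  # prototype -> mean reconstruction


def firing_rate_estimate(spike_train: np.ndarray, sigma: float,
                         dt: float) -> np.ndarray:
    """Firing rate (Hz) by convolving the 0/1 train, taken as ``1/dt``
    impulses, with a normalized Gaussian kernel of width ``sigma`` seconds.

    The kernel integrates to one, so the time-integral of the rate equals
    the spike count (up to edge truncation).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    train = np.asarray(spike_train, dtype=float) / dt
    return gaussian_filter1d(train, sigma=sigma / dt, mode="constant")


def cosine_similarity_matrix(representations: np.ndarray) -> SimilarityResult:
    """Pairwise cosine similarities; zero vectors score 0 against anything."""
    X = np.asarray(representations, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (n_patterns >= 2, n_features) matrix")
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    sim = (X / safe[:, None]) @ (X / safe[:, None]).T
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    return SimilarityResult(matrix=sim)


def orthogonality_ratio(sim: SimilarityResult | np.ndarray,
                        labels: np.ndarray) -> float:
    """Mean within-class similarity over mean overall similarity, both taken
    over off-diagonal pairs.  Returns NaN when the denominator is zero."""
    matrix = sim.matrix if isinstance(sim, SimilarityResult) else np.asarray(sim)
    labels = np.asarray(labels)
    n = matrix.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length must match similarity matrix")
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 classes")
    off = ~np.eye(n, dtype=bool)
    same = (labels[:, None] == labels[None, :]) & off
    denom = matrix[off].mean()
    if denom == 0:
        return float("nan")
    return float(matrix[same].mean() / denom)


def similarity_result(representations: np.ndarray,
                      labels: np.ndarray) -> SimilarityResult:
    """Convenience: similarity matrix plus its orthogonality ratio."""
    res = cosine_similarity_matrix(representations)
    res.labels = np.asarray(labels)
    res.s_ortho = orthogonality_ratio(res, labels)
    return res


def extract_prototypes(
    attractor_reps: np.ndarray,
    s_min: float,
    reconstructions: np.ndarray | None = None,
) -> PrototypeResult:
    """Group attractor representations into prototypes.

    Two patterns are linked when their cosine similarity is strictly above
    ``s_min``; prototypes are the connected components of this graph (i.e.
    single-linkage clusters).  ``reconstructions`` (e.g. INPRC z-traces at
    pattern end) are averaged per component when given.
    """
    if not 0.0 <= s_min <= 1.0:
        raise ValueError("s_min must lie in [0, 1]")
    sim = cosine_similarity_matrix(attractor_reps).matrix
    n = sim.shape[0]
    adj = (sim > s_min) & ~np.eye(n, dtype=bool)
    n_comp, assignment = connected_components(
        csr_matrix(adj), directed=False
    )
    attraction = np.bincount(assignment, minlength=n_comp)
    recon = None
    if reconstructions is not None:
        reconstructions = np.asarray(reconstructions, dtype=float)
        recon = np.stack([
            reconstructions[assignment == c].mean(axis=0)
            for c in range(n_comp)
        ])
    return PrototypeResult(
        s_min=s_min, n_prototypes=n_comp, assignment=assignment,
        attraction=attraction, reconstruction=recon,
    )


@dataclass(frozen=True)
class ReadoutParams:
    """Adam hyperparameters for the linear readout."""

    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-7
    batch_size: int = 64
    n_epochs: int = 10
    seed: int = 0


@dataclass
class LinearReadout:
    W: np.ndarray
    b: np.ndarray

    def logits(self, X: np.ndarray) -> np.ndarray:
        return X @ self.W + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.logits(X).argmax(axis=1)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def train_linear_readout(
    reps: np.ndarray,
    labels: np.ndarray,
    test_reps: np.ndarray | None = None,
    test_labels: np.ndarray | None = None,
    params: ReadoutParams = ReadoutParams(),
) -> tuple[LinearReadout, float]:
    """Multinomial-logistic readout trained with cross-entropy + Adam.

    Returns the trained model and its accuracy on the held-out set (or the
    training set when none is given).  Deterministic per ``params.seed``.
    """
    X = np.asarray(reps, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train a readout")
    n_class = int(classes.max()) + 1
    n, d = X.shape
    rng = np.random.default_rng(params.seed)
    model = LinearReadout(W=np.zeros((d, n_class)), b=np.zeros(n_class))
    onehot = np.eye(n_class)[y]
    mW = np.zeros_like(model.W); vW = np.zeros_like(model.W)
    mb = np.zeros_like(model.b); vb = np.zeros_like(model.b)
    t = 0
    for _epoch in range(params.n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, params.batch_size):
            idx = order[start:start + params.batch_size]
            Xb, Yb = X[idx], onehot[idx]
            P = _softmax_rows(model.logits(Xb))
            G = (P - Yb) / idx.size
            gW = Xb.T @ G
            gb = G.sum(axis=0)
            t += 1
            for g, m, v, p in ((gW, mW, vW, model.W), (gb, mb, vb, model.b)):
                m *= params.beta1; m += (1 - params.beta1) * g
                v *= params.beta2; v += (1 - params.beta2) * g * g
                mhat = m / (1 - params.beta1 ** t)
                vhat = v / (1 - params.beta2 ** t)
                p -= params.lr * mhat / (np.sqrt(vhat) + params.adam_eps)
    if test_reps is not None and test_labels is not None:
        acc = model.accuracy(np.asarray(test_reps, dtype=float), test_labels)
    else:
        acc = model.accuracy(X, y)
    return model, acc
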