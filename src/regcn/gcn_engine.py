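"""Two-layer graph convolutional classifier, trained on pseudo-labels.

The forward pass is the standard symmetric-normalized propagation

    Z = softmax(Â · ReLU(Â X W0) · W1),

row i of Z giving node i's affiliation strength over the K communities.
Training minimizes the summed cross-entropy over the pseudo-labeled
nodes, -Σ_k Σ_{i in S_k} log z_{i,k}, with Adam.  The model is small
(hidden width 16 by default, two layers) and desk-scale, so everything
runs as dense NumPy linear algebra with an explicit backward pass; a
fixed seed reproduces the full trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from regcn.errors import ParameterError, ShapeError, SupervisionError

logger = logging.getLogger(__name__)


@dataclass
class GCNParams:
    """Weights of the two graph convolution layers: W0 (F x D), W1 (D x K)."""

    W0: np.ndarray
    W1: np.ndarray

    def copy(self) -> "GCNParams":
        return GCNParams(W0=self.W0.copy(), W1=self.W1.copy())


@dataclass
class TrainConfig:
    """Training hyperparameters for the classifier.

    Defaults follow the canonical two-layer GCN configuration: hidden
    width 16, Adam at learning rate 0.01, 200 epochs, L2 weight decay
    5e-4 on both layers.  Dropout is omitted so that a fixed seed gives
    run-to-run identical results.
    """

    hidden_dim: int = 16
    learning_rate: float = 0.01
    epochs: int = 200
    weight_decay: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim < 1:
            raise ParameterError("hidden_dim must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if self.epochs < 0:
            raise ParameterError("epochs must be >= 0")
        if self.weight_decay < 0:
            raise ParameterError("weight_decay must be >= 0")


def init_params(n_features: int, hidden_dim: int, k: int, seed: int) -> GCNParams:
    """Glorot-uniform initialization from a seeded generator."""
    if min(n_features, hidden_dim, k) < 1:
        raise ParameterError("all dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    lim0 = np.sqrt(6.0 / (n_features + hidden_dim))
    lim1 = np.sqrt(6.0 / (hidden_dim + k))
    return GCNParams(
        W0=rng.uniform(-lim0, lim0, size=(n_features, hidden_dim)),
        W1=rng.uniform(-lim1, lim1, size=(hidden_dim, k)),
    )


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def forward(a_hat: np.ndarray, x: np.ndarray, params: GCNParams) -> np.ndarray:
    """Soft assignment Z = softmax(Â ReLU(Â X W0) W1); rows sum to 1."""
    if x.shape[0] != a_hat.shape[0]:
        raise ShapeError("feature rows != adjacency size")
    if x.shape[1] != params.W0.shape[0]:
        raise ShapeError(
            f"feature dim {x.shape[1]} != W0 input dim {params.W0.shape[0]}"
        )
    h1 = np.maximum(a_hat @ (x @ params.W0), 0.0)
    return _softmax_rows(a_hat @ (h1 @ params.W1))


def _as_supervision(pseudo, k: int, n: int):
    """Normalize a SeedSet / PseudoLabelSet / (idx, label) pair into arrays.

    Labels are 0-based community indices internally.
    """
    if hasattr(pseudo, "sets"):  # PseudoLabelSet
        idx, lab = [], []
        for j, nodes in enumerate(pseudo.sets):
            idx.extend(int(v) for v in nodes)
            lab.extend([j] * len(nodes))
    elif hasattr(pseudo, "centers"):  # SeedSet
        idx = [int(v) for v in pseudo.centers]
        lab = list(range(len(idx)))
    else:
        idx, lab = (list(pseudo[0]), list(pseudo[1]))
    idx = np.asarray(idx, dtype=np.int64)
    lab = np.asarray(lab, dtype=np.int64)
    if idx.size == 0:
        raise SupervisionError("empty supervision set")
    if idx.min() < 0 or idx.max() >= n:
        raise SupervisionError("supervised node index out of range")
    present = np.bincount(lab, minlength=k)
    if np.any(present == 0):
        empty = int(np.flatnonzero(present == 0)[0]) + 1
        raise SupervisionError(f"community {empty} has no supervised node")
    return idx, lab


def train(
    a_hat: np.ndarray,
    x: np.ndarray,
    pseudo,
    k: int,
    config: TrainConfig,
) -> tuple[GCNParams, np.ndarray]:
    """Fit the classifier on pseudo-labeled nodes; return params and Z.

    ``pseudo`` may be a SeedSet (one center per community), a
    PseudoLabelSet, or an ``(indices, zero_based_labels)`` pair.  The
    loss is the plain sum of -log z over supervised nodes; weight decay
    enters as an L2 gradient term on both layers.  Returns the final
    parameters and the final soft assignment.
    """
    n = a_hat.shape[0]
    idx, lab = _as_supervision(pseudo, k, n)
    params = init_params(x.shape[1], config.hidden_dim, k, config.seed)
    if config.epochs == 0:
        return params, forward(a_hat, x, params)

    ax = a_hat @ x  # constant across epochs
    lr, wd = config.learning_rate, config.weight_decay
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m0 = np.zeros_like(params.W0)
    v0 = np.zeros_like(params.W0)
    m1 = np.zeros_like(params.W1)
    v1 = np.zeros_like(params.W1)

    z = None
    for t in range(1, config.epochs + 1):
        pre1 = ax @ params.W0
        h1 = np.maximum(pre1, 0.0)
        ah1 = a_hat @ h1
        z = _softmax_rows(ah1 @ params.W1)

        loss = -np.sum(np.log(np.clip(z[idx, lab], 1e-300, None)))
        if t == 1 or t % 50 == 0:
            logger.debug("epoch %d loss %.6f", t, loss)

        g_logits = np.zeros_like(z)
        g_logits[idx] = z[idx]
        g_logits[idx, lab] -= 1.0
        gW1 = ah1.T @ g_logits + wd * params.W1
        g_h1 = (a_hat @ g_logits) @ params.W1.T
        g_pre1 = g_h1 * (pre1 > 0)
        gW0 = ax.T @ g_pre1 + wd * params.W0

        m0 = beta1 * m0 + (1 - beta1) * gW0
        v0 = beta2 * v0 + (1 - beta2) * gW0**2
        m1 = beta1 * m1 + (1 - beta1) * gW1
        v1 = beta2 * v1 + (1 - beta2) * gW1**2
        bc1 = 1 - beta1**t
        bc2 = 1 - beta2**t
        params.W0 = params.W0 - lr * (m0 / bc1) / (np.sqrt(v0 / bc2) + eps)
        params.W1 = params.W1 - lr * (m1 / bc1) / (np.sqrt(v1 / bc2) + eps)

    return params, forward(a_hat, x, params)


def predict_partition(z: np.ndarray) -> np.ndarray:
    """Hard community labels 1..K by per-row argmax (ties -> smaller k)."""
    z = np.asarray(z)
    if z.ndim != 2:
        raise ShapeError("soft assignment must be a 2-D matrix")
    return (z.argmax(axis=1) + 1).astype(np.int64)
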