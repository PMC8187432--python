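"""Model components: per-omics GCN classifiers and the integration heads.

Each omics view gets a graph convolutional classifier whose layers
propagate sample features through the renormalized similarity adjacency,

    H^(l+1) = sigma(A_tilde H^(l) W^(l)),

followed by a linear head producing c class logits.  The per-view softmax
probability rows are fused either through the view-correlation discovery
head (VCDN) — a fully connected network on the flattened c^m outer-product
tensor of the m probability rows, which exposes cross-view label
correlations — or, in the concatenation ablation, on the stacked m*c
vector of the rows themselves.

Losses are class-weighted cross-entropy with weights set to the inverse
class frequency in the training data (normalised to mean 1), which
counteracts label imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, gather_rows, leaky_relu, log_softmax, softmax

__all__ = [
    "GCNModel",
    "VCDNModel",
    "CrossOmicsTensor",
    "cross_omics_tensor",
    "concat_predictions",
    "probabilities",
    "class_weights",
    "weighted_cross_entropy",
]


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)


class _MLPBase:
    """Shared parameter handling for the small dense/graph networks."""

    weights: list[Tensor]
    biases: list[Tensor]

    def parameters(self) -> list[Tensor]:
        return self.weights + self.biases

    def state(self) -> dict:
        return {
            "weights": [w.data.copy() for w in self.weights],
            "biases": [b.data.copy() for b in self.biases],
        }

    def load_state(self, state: dict) -> None:
        for w, d in zip(self.weights, state["weights"]):
            w.data = d.copy()
        for b, d in zip(self.biases, state["biases"]):
            b.data = d.copy()


class GCNModel(_MLPBase):
    """Graph convolutional classifier for one omics view.

    ``hidden`` graph-convolution layers with a leaky-rectifier nonlinearity
    and dropout, then a linear head to ``n_classes`` logits.  With the
    identity adjacency every layer collapses to an ordinary fully connected
    layer, which is exactly the k=1 degeneracy of the similarity graph.
    """

    def __init__(
        self,
        in_dim: int,
        hidden: list[int],
        n_classes: int,
        rng: np.random.Generator,
        slope: float = 0.25,
        dropout: float = 0.5,
    ):
        if not hidden:
            raise ValueError("need at least one hidden layer")
        self.slope = slope
        self.dropout = dropout
        dims = [in_dim, *hidden]
        self.weights = [
            Tensor(_xavier(rng, dims[i], dims[i + 1]), requires_grad=True)
            for i in range(len(hidden))
        ]
        self.weights.append(Tensor(_xavier(rng, dims[-1], n_classes), requires_grad=True))
        self.biases = [Tensor(np.zeros(d), requires_grad=True) for d in dims[1:]]
        self.biases.append(Tensor(np.zeros(n_classes), requires_grad=True))

    def forward(
        self,
        X: np.ndarray,
        A_tilde: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Differentiable forward pass; returns an n x c logits Tensor."""
        A = Tensor(A_tilde)
        H: Tensor = Tensor(X)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            H = leaky_relu(A @ (H @ W) + b, self.slope)
            if training and self.dropout > 0:
                if rng is None:
                    raise ValueError("training forward needs an rng for dropout")
                H = H * _dropout_mask(rng, H.shape, self.dropout)
        return H @ self.weights[-1] + self.biases[-1]

    def forward_numpy(self, X: np.ndarray, A_tilde: np.ndarray) -> np.ndarray:
        """Evaluation-mode forward on ndarrays; supports stacked batches of
        graphs (A_tilde of shape (..., n, n) with X of shape (..., n, d))."""
        H = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            H = A_tilde @ (H @ W.data) + b.data
            H = np.where(H > 0, H, self.slope * H)
        return H @ self.weights[-1].data + self.biases[-1].data


class VCDNModel(_MLPBase):
    """Fully connected integration head.

    In ``vcdn`` mode the input is the flattened c^m cross-omics tensor; in
    ``concat`` mode it is the m*c stacked probability vector.  One hidden
    layer of the input width by default.
    """

    def __init__(
        self,
        in_dim: int,
        n_classes: int,
        rng: np.random.Generator,
        hidden: list[int] | None = None,
        slope: float = 0.25,
    ):
        self.slope = slope
        hidden = list(hidden) if hidden else [in_dim]
        dims = [in_dim, *hidden, n_classes]
        self.weights = [
            Tensor(_xavier(rng, dims[i], dims[i + 1]), requires_grad=True)
            for i in range(len(dims) - 1)
        ]
        self.biases = [Tensor(np.zeros(d), requires_grad=True) for d in dims[1:]]
        self.in_dim = in_dim

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"expected input length {self.in_dim}, got {x.shape[-1]}")
        H = x
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            H = leaky_relu(H @ W + b, self.slope)
        return H @ self.weights[-1] + self.biases[-1]

    def forward_numpy(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.in_dim:
            raise ValueError(f"expected input length {self.in_dim}, got {x.shape[-1]}")
        H = x
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            H = H @ W.data + b.data
            H = np.where(H > 0, H, self.slope * H)
        return H @ self.weights[-1].data + self.biases[-1].data


@dataclass
class CrossOmicsTensor:
    """The order-m label-space tensor of one sample (or a batch of samples)."""

    tensor: np.ndarray  # (..., c, c, ..., c) with m trailing class axes
    flat: np.ndarray  # (..., c**m), first view slowest-varying


def _outer_flatten(rows: list[np.ndarray]) -> np.ndarray:
    """Batched outer product of probability rows, flattened C-order
    (first view slowest-varying, last view fastest)."""
    z = rows[0]
    for y in rows[1:]:
        z = z[..., :, None] * y[..., None, :]
        z = z.reshape(*z.shape[:-2], -1)
    return z


def cross_omics_tensor(preds: list[np.ndarray]) -> CrossOmicsTensor:
    """Build the cross-omics discovery tensor from m probability rows.

    Entry (a_1, ..., a_m) is the product of view i's probability for class
    a_i; for probability inputs the entries sum to 1.  Accepts 1-D rows or
    batches of rows (n x c per view).
    """
    if len(preds) < 2:
        raise ValueError("need at least two views")
    preds = [np.asarray(p, dtype=float) for p in preds]
    c = preds[0].shape[-1]
    for p in preds:
        if p.shape[-1] != c:
            raise ValueError("class dimension differs across views")
    flat = _outer_flatten(preds)
    tensor = flat.reshape(*flat.shape[:-1], *([c] * len(preds)))
    return CrossOmicsTensor(tensor=tensor, flat=flat)


def concat_predictions(preds: list[np.ndarray]) -> np.ndarray:
    """Concatenate the m probability rows into a length m*c vector (batched)."""
    return np.concatenate([np.asarray(p, dtype=float) for p in preds], axis=-1)


def probabilities(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax turning logits into class-probability rows."""
    return softmax(np.asarray(logits, dtype=float))


def class_weights(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Inverse-class-frequency loss weights, normalised to mean 1.

    Raises if any class is absent from the training labels.
    """
    counts = np.bincount(np.asarray(labels, dtype=int), minlength=n_classes)
    if np.any(counts == 0):
        missing = np.where(counts == 0)[0].tolist()
        raise ValueError(f"classes absent from training labels: {missing}")
    w = len(labels) / counts
    return w / w.mean()


def weighted_cross_entropy(
    logits: Tensor | np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None
) -> Tensor:
    """Mean class-weighted cross-entropy of logits against integer labels."""
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    labels = np.asarray(labels, dtype=int)
    logp = gather_rows(log_softmax(logits), labels)
    if weights is None:
        weights = np.ones(int(labels.max()) + 1)
    w = np.asarray(weights, dtype=float)[labels]
    if np.any(w <= 0):
        raise ValueError("class weights must be positive")
    return -(logp * w).mean()
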