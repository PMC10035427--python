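"""Two-layer spectral GCN for graph-level binary classification.

The node-embedding map is

    F = ReLU( Â · ReLU( Â X W0 ) · W1 ),

with Â the symmetric degree-normalized adjacency (self-loops included),
X the n x d node-feature matrix, and W0, W1 the two layers of weights.
A graph-level representation is read out as the concatenation of average
and maximum pooling over nodes,

    H_G = mean_i f_i  ‖  max_i f_i,

and a single linear layer maps H_G to two class logits trained with
softmax cross-entropy.

The whole model is implemented directly in NumPy: forward, hand-derived
backward pass, Glorot-uniform initialization, and an Adam optimizer with
L2 weight decay.  Training is full-batch by default (cohorts here are at
most a few hundred graphs) and fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bfn import AdjacencyMatrix
from .features import NodeFeatureMatrix

__all__ = [
    "GraphSample",
    "GCNParams",
    "TrainConfig",
    "gcn_forward",
    "readout",
    "train",
    "predict",
    "predict_proba",
]


@dataclass
class GraphSample:
    """One subject as a graph: adjacency + node features + binary label."""

    adjacency: AdjacencyMatrix
    features: NodeFeatureMatrix
    label: int
    subject_id: str = ""

    def __post_init__(self):
        if self.adjacency.n != self.features.n:
            raise ValueError(
                f"{self.subject_id or 'sample'}: adjacency has {self.adjacency.n} "
                f"nodes but features have {self.features.n}"
            )
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.adjacency.normalized is None:
            raise ValueError("adjacency must be normalized before model input")


@dataclass
class GCNParams:
    """Model weights: two graph-convolution layers plus the linear head."""

    W0: np.ndarray  # d x h
    W1: np.ndarray  # h x d'
    head_W: np.ndarray  # 2d' x 2
    head_b: np.ndarray  # 2

    def as_list(self) -> list[np.ndarray]:
        return [self.W0, self.W1, self.head_W, self.head_b]

    def copy(self) -> "GCNParams":
        return GCNParams(*(p.copy() for p in self.as_list()))


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the study protocol."""

    embedding_dim: int = 32
    epochs: int = 100
    learning_rate: float = 0.001
    weight_decay: float = 1e-3
    optimizer: str = "adam"
    batch_size: int | None = None  # None = full batch
    seed: int = 0


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(d: int, cfg: TrainConfig) -> GCNParams:
    """Glorot-uniform weights for input width d and the configured embedding."""
    rng = np.random.default_rng(cfg.seed)
    h = cfg.embedding_dim
    return GCNParams(
        W0=_glorot(rng, d, h),
        W1=_glorot(rng, h, h),
        head_W=_glorot(rng, 2 * h, 2),
        head_b=np.zeros(2),
    )


# ---------------------------------------------------------------------------
# batched forward/backward on stacked arrays (B, n, n) and (B, n, d)


def _stack(samples: list[GraphSample]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = np.stack([s.adjacency.normalized for s in samples])
    x = np.stack([s.features.values for s in samples])
    y = np.array([s.label for s in samples], dtype=int)
    return a, x, y


def _forward(a, x, p: GCNParams):
    z0 = a @ (x @ p.W0)
    h1 = np.maximum(z0, 0.0)
    z1 = a @ (h1 @ p.W1)
    f = np.maximum(z1, 0.0)  # (B, n, d')
    mean_part = f.mean(axis=1)
    argmax = f.argmax(axis=1)  # (B, d'), first max per column
    max_part = np.take_along_axis(f, argmax[:, None, :], axis=1)[:, 0, :]
    hg = np.concatenate([mean_part, max_part], axis=1)  # (B, 2d')
    logits = hg @ p.head_W + p.head_b
    cache = (a, x, z0, h1, z1, f, argmax, hg)
    return logits, cache


def _softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _backward(dlogits, cache, p: GCNParams) -> list[np.ndarray]:
    a, x, z0, h1, z1, f, argmax, hg = cache
    B, n, dp = f.shape
    d_head_W = hg.reshape(B, -1, 1) * dlogits[:, None, :]
    d_head_W = d_head_W.sum(axis=0)
    d_head_b = dlogits.sum(axis=0)
    dhg = dlogits @ p.head_W.T  # (B, 2d')
    dmean, dmax = dhg[:, :dp], dhg[:, dp:]
    df = np.broadcast_to(dmean[:, None, :] / n, f.shape).copy()
    np.put_along_axis(
        df, argmax[:, None, :],
        np.take_along_axis(df, argmax[:, None, :], axis=1) + dmax[:, None, :],
        axis=1,
    )
    dz1 = df * (z1 > 0)
    # z1 = a @ h1 @ W1 ; a symmetric
    dh1W1 = a.transpose(0, 2, 1) @ dz1
    dW1 = (h1.transpose(0, 2, 1) @ dh1W1).sum(axis=0)
    dh1 = dh1W1 @ p.W1.T
    dz0 = dh1 * (z0 > 0)
    dxW0 = a.transpose(0, 2, 1) @ dz0
    dW0 = (x.transpose(0, 2, 1) @ dxW0).sum(axis=0)
    return [dW0, dW1, d_head_W, d_head_b]


def batch_loss_and_grads(a, x, y, p: GCNParams):
    """Mean cross-entropy over the batch and its parameter gradients."""
    logits, cache = _forward(a, x, p)
    probs = _softmax(logits)
    B = len(y)
    eps = 1e-12
    loss = -np.log(probs[np.arange(B), y] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads = _backward(dlogits, cache, p)
    return loss, grads


# ---------------------------------------------------------------------------
# public single-sample API


def gcn_forward(sample: GraphSample, params: GCNParams) -> np.ndarray:
    """Node embeddings F = ReLU(Â·ReLU(ÂXW0)·W1) for one graph, shape (n, d')."""
    a = sample.adjacency.normalized[None]
    x = sample.features.values[None]
    if x.shape[2] != params.W0.shape[0]:
        raise ValueError(
            f"feature width {x.shape[2]} does not match W0 input {params.W0.shape[0]}"
        )
    z0 = a @ (x @ params.W0)
    h1 = np.maximum(z0, 0.0)
    f = np.maximum(a @ (h1 @ params.W1), 0.0)
    return f[0]


def readout(f: np.ndarray) -> np.ndarray:
    """Graph embedding: mean over nodes concatenated with max over nodes."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 2 or f.shape[0] < 1:
        raise ValueError("readout needs a nonempty (n, d') embedding matrix")
    return np.concatenate([f.mean(axis=0), f.max(axis=0)])


def predict_proba(samples: list[GraphSample], params: GCNParams) -> np.ndarray:
    """Class probabilities, shape (B, 2); rows sum to 1."""
    a, x, _ = _stack(samples)
    if x.shape[2] != params.W0.shape[0]:
        raise ValueError(
            f"feature width {x.shape[2]} does not match W0 input {params.W0.shape[0]}"
        )
    logits, _ = _forward(a, x, params)
    return _softmax(logits)


def predict(samples: list[GraphSample], params: GCNParams) -> np.ndarray:
    """Hard 0/1 labels (argmax of the class probabilities)."""
    return predict_proba(samples, params).argmax(axis=1)


def train(
    samples: list[GraphSample], cfg: TrainConfig
) -> tuple[GCNParams, list[float]]:
    """Fit the model by Adam on softmax cross-entropy.

    Weight decay enters as an L2 term added to the gradient before the
    Adam update.  Returns the fitted parameters and the per-epoch loss
    log.  Deterministic given ``cfg.seed``.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 training samples")
    labels = {s.label for s in samples}
    if labels != {0, 1}:
        raise ValueError(f"training set must contain both classes, got labels {labels}")
    if cfg.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    a, x, y = _stack(samples)
    p = init_params(x.shape[2], cfg)
    params = p.as_list()
    m = [np.zeros_like(w) for w in params]
    v = [np.zeros_like(w) for w in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    rng = np.random.default_rng(cfg.seed + 1)
    B = len(samples)
    bs = cfg.batch_size or B
    losses: list[float] = []
    t = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(B) if bs < B else np.arange(B)
        epoch_loss = 0.0
        for start in range(0, B, bs):
            idx = order[start : start + bs]
            loss, grads = batch_loss_and_grads(a[idx], x[idx], y[idx], p)
            epoch_loss += loss * len(idx)
            t += 1
            for k, (w, g) in enumerate(zip(params, grads)):
                g = g + cfg.weight_decay * w
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**t)
                vhat = v[k] / (1 - beta2**t)
                w -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        losses.append(epoch_loss / B)
    return p, losses
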