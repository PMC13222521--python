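"""Paired-sample contrastive training.

Each epoch pairs every training sample with a distinct random partner (a
seeded derangement, re-drawn every epoch). Both pair members pass through
the shared network; the objective is

    total = MSE(stream 1) + MSE(stream 2) + λ · contrastive,

where the contrastive term is the mean squared gap between the Euclidean
distance of the paired embeddings and the absolute difference ``diff`` of
their standardized phenotypes. Optimisation uses Adam with its customary
moment defaults; everything is seeded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .network import ClcnetNetwork, ModelConfig

__all__ = [
    "LR_GRID", "BATCH_GRID", "EPOCH_GRID", "default_grid",
    "PairBatch", "TrainConfig", "TrainHistory", "Adam",
    "make_pairs", "loss_mse", "loss_contrastive", "composite_loss",
    "train_model", "grid_search",
]

LR_GRID = (0.01, 0.001, 0.0001)
BATCH_GRID = (16, 32, 64)
EPOCH_GRID = (20, 50, 100)


@dataclass
class PairBatch:
    """One mini-batch of sample pairs."""

    idx1: np.ndarray
    idx2: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    diff: np.ndarray    # |y1 - y2|, the 1-D contrastive reference


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 50
    contrastive_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.contrastive_weight < 0:
            raise ValueError("contrastive_weight must be >= 0")


def default_grid() -> list:
    """The full 27-point grid of candidate learning rates / batches / epochs."""
    return [
        TrainConfig(learning_rate=lr, batch_size=b, epochs=e)
        for lr, b, e in itertools.product(LR_GRID, BATCH_GRID, EPOCH_GRID)
    ]


@dataclass
class TrainHistory:
    mse1: list = field(default_factory=list)
    mse2: list = field(default_factory=list)
    contrastive: list = field(default_factory=list)
    val_pcc: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def make_pairs(train_indices, epoch_seed) -> tuple:
    """Seeded derangement pairing: (idx1, idx2) with idx1 the full index set
    in random order and idx2 a partner permutation with no self-pairs."""
    idx = np.asarray(train_indices)
    n = len(idx)
    if n < 2:
        raise ValueError("need at least two samples to form pairs")
    rng = np.random.default_rng(epoch_seed)
    order = rng.permutation(n)
    perm = rng.permutation(n)
    fixed = np.flatnonzero(perm == np.arange(n))
    if len(fixed) == 1:
        j = int(fixed[0])
        k = (j + 1) % n
        perm[j], perm[k] = perm[k], perm[j]
    elif len(fixed) > 1:
        perm[fixed] = perm[np.roll(fixed, 1)]
    return idx[order], idx[perm[order]]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def loss_mse(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 1:
        raise ValueError("y and y_hat must be equal-length, non-empty")
    return float(np.mean((y - y_hat) ** 2))


def loss_contrastive(emb1: np.ndarray, emb2: np.ndarray, diff: np.ndarray) -> float:
    """Mean squared gap between pair embedding distance and |Δy|."""
    emb1 = np.atleast_2d(emb1)
    emb2 = np.atleast_2d(emb2)
    diff = np.asarray(diff, dtype=float)
    dist = np.linalg.norm(emb1 - emb2, axis=1)
    return float(np.mean((dist - diff) ** 2))


def composite_loss(y1, yh1, y2, yh2, emb1, emb2, diff, contrastive_weight: float = 1.0):
    """Total objective and its components as a dict."""
    c1 = loss_mse(y1, yh1)
    c2 = loss_mse(y2, yh2)
    cc = loss_contrastive(emb1, emb2, diff)
    total = c1 + c2 + contrastive_weight * cc
    return total, {"mse1": c1, "mse2": c2, "contrastive": cc}


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment estimation over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) <= 0 or np.std(b) <= 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def train_model(net: ClcnetNetwork, X: np.ndarray, y: np.ndarray,
                config: TrainConfig | None = None,
                X_valid: np.ndarray | None = None,
                y_valid: np.ndarray | None = None) -> TrainHistory:
    """Train *net* in place on standardized phenotypes; returns the history.

    X holds the selected-SNP inputs of the training rows only; validation
    data, if given, is used purely for per-epoch monitoring.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    opt = Adam(net.params, lr=config.learning_rate)
    history = TrainHistory()
    lam = config.contrastive_weight
    for epoch in range(config.epochs):
        i1, i2 = make_pairs(np.arange(n), epoch_seed=[config.seed, epoch])
        ep = {"mse1": 0.0, "mse2": 0.0, "contrastive": 0.0}
        n_batches = 0
        for s in range(0, n, config.batch_size):
            b1, b2 = i1[s:s + config.batch_size], i2[s:s + config.batch_size]
            B = len(b1)
            y1, y2 = y[b1], y[b2]
            diff = np.abs(y1 - y2)
            out1, cache1 = net.forward(X[b1], want_cache=True)
            out2, cache2 = net.forward(X[b2], want_cache=True)
            total, comps = composite_loss(
                y1, out1.y_hat, y2, out2.y_hat,
                out1.embedding, out2.embedding, diff, lam,
            )
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {s // config.batch_size}: "
                    f"{comps} (learning rate {config.learning_rate} likely too large)"
                )
            d_y1 = 2.0 * (out1.y_hat - y1) / B
            d_y2 = 2.0 * (out2.y_hat - y2) / B
            if lam > 0:
                delta = out1.embedding - out2.embedding
                dist = np.linalg.norm(delta, axis=1)
                safe = np.where(dist > 0, dist, 1.0)
                coef = lam * 2.0 * (dist - diff) / B / safe
                coef = np.where(dist > 0, coef, 0.0)
                d_e1 = coef[:, None] * delta
                d_e2 = -d_e1
            else:
                d_e1 = d_e2 = None
            grads = net.backward(cache1, d_y1, d_e1)
            g2 = net.backward(cache2, d_y2, d_e2)
            for k in grads:
                grads[k] += g2[k]
            opt.step(net.params, grads)
            for k in ep:
                ep[k] += comps[k]
            n_batches += 1
        history.mse1.append(ep["mse1"] / n_batches)
        history.mse2.append(ep["mse2"] / n_batches)
        history.contrastive.append(ep["contrastive"] / n_batches)
        if X_valid is not None and y_valid is not None and len(y_valid) >= 3:
            pred = net.forward(np.asarray(X_valid, dtype=float)).y_hat
            history.val_pcc.append(_pcc(pred, np.asarray(y_valid, dtype=float)))
        else:
            history.val_pcc.append(float("nan"))
    return history


def grid_search(X_train, y_train, X_valid, y_valid, grid=None,
                model_config: ModelConfig | None = None) -> TrainConfig:
    """Exhaustive search on one designated train/validation split.

    Best = highest final validation PCC; ties broken by lower learning rate
    then smaller batch. Configs that diverge (non-finite loss) score −inf.
    """
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    model_config = model_config or ModelConfig(
        input_dim=np.asarray(X_train).shape[1], scale=0.125
    )
    scored = []
    for cfg in grid:
        net = ClcnetNetwork(model_config)
        try:
            hist = train_model(net, X_train, y_train, cfg, X_valid, y_valid)
            pcc = hist.val_pcc[-1]
        except RuntimeError:
            pcc = float("-inf")
        if not np.isfinite(pcc):
            pcc = float("-inf")
        scored.append((pcc, -cfg.learning_rate, -cfg.batch_size, cfg))
    scored.sort(key=lambda t: (t[0], t[1], t[2]), reverse=True)
    return scored[0][3]
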