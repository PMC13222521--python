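"""The dual-pathway multi-task network, implemented directly on numpy.

Architecture (full scale): a nonlinear pathway of three fully connected
layers with ReLU activations and widths {4096, 2048, 1024}; a parallel
single linear layer mapping the input straight to 1024 units. The two
pathway outputs are summed (a residual connection that preserves additive
marker effects) and fed to two task heads, each two ReLU layers plus an
output layer: the trait head {4096, 2048, 1} yields the scalar phenotype
prediction, the embedding head {4096, 2048, 1024} yields the sample
embedding used by the contrastive objective. No dropout or normalisation
layers are present. A width multiplier ``scale`` shrinks every hidden
dimension (ceil(scale·d)) for desk-scale runs; the trait output stays 1.

Forward and backward passes are hand-written; the parameter set is a flat
dict of arrays so an optimiser can update it in place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["BASE_BACKBONE", "BASE_TRAIT_HEAD", "BASE_EMBED_HEAD",
           "ModelConfig", "ClcnetNetwork", "ForwardOutput", "build_model", "forward"]

BASE_BACKBONE = (4096, 2048, 1024)
BASE_TRAIT_HEAD = (4096, 2048, 1)
BASE_EMBED_HEAD = (4096, 2048, 1024)


def _scaled(dims: tuple, scale: float, keep_last: bool = False) -> tuple:
    out = []
    for k, d in enumerate(dims):
        if keep_last and k == len(dims) - 1:
            out.append(d)
            continue
        s = math.ceil(scale * d)
        if s < 1:
            raise ValueError(f"scale {scale} yields a zero-width layer for dim {d}")
        out.append(s)
    return tuple(out)


@dataclass
class ModelConfig:
    """Network dimensions and the parameter seed."""

    input_dim: int
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if not 0.0 < self.scale <= 1.0:
            raise ValueError("scale must lie in (0, 1]")

    @property
    def backbone_dims(self) -> tuple:
        return _scaled(BASE_BACKBONE, self.scale)

    @property
    def trait_head_dims(self) -> tuple:
        return _scaled(BASE_TRAIT_HEAD, self.scale, keep_last=True)

    @property
    def embed_head_dims(self) -> tuple:
        return _scaled(BASE_EMBED_HEAD, self.scale)

    @property
    def embedding_dim(self) -> int:
        return self.embed_head_dims[-1]

    def layer_shapes(self) -> dict:
        """Weight shapes of every layer, keyed by parameter name."""
        shapes = {}
        d_in = self.input_dim
        for k, d in enumerate(self.backbone_dims):
            shapes[f"nl{k}"] = (d_in, d)
            d_in = d
        shared = self.backbone_dims[-1]
        shapes["lin"] = (self.input_dim, shared)
        d_in = shared
        for k, d in enumerate(self.trait_head_dims):
            shapes[f"trait{k}"] = (d_in, d)
            d_in = d
        d_in = shared
        for k, d in enumerate(self.embed_head_dims):
            shapes[f"emb{k}"] = (d_in, d)
            d_in = d
        return shapes

    def n_parameters(self) -> int:
        return sum(i * o + o for i, o in self.layer_shapes().values())


@dataclass
class ForwardOutput:
    """Per-sample scalar predictions and embedding vectors."""

    y_hat: np.ndarray        # (batch,)
    embedding: np.ndarray    # (batch, D)


# layers with ReLU on their output; the remaining layers are linear
_RELU_LAYERS = frozenset(
    ["nl0", "nl1", "nl2", "trait0", "trait1", "emb0", "emb1"]
)


class ClcnetNetwork:
    """Parameter container with forward and backward passes."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        for name, (fan_in, fan_out) in config.layer_shapes().items():
            # fan-in (He) scheme for rectified layers, Glorot-like otherwise
            std = math.sqrt(2.0 / fan_in) if name in _RELU_LAYERS else math.sqrt(1.0 / fan_in)
            self.params[f"{name}_W"] = rng.normal(0.0, std, size=(fan_in, fan_out))
            self.params[f"{name}_b"] = np.zeros(fan_out)

    # -- introspection ------------------------------------------------------
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward ------------------------------------------------------------
    def _affine(self, name: str, h: np.ndarray) -> np.ndarray:
        return h @ self.params[f"{name}_W"] + self.params[f"{name}_b"]

    def forward(self, X: np.ndarray, want_cache: bool = False):
        """Forward pass; returns ForwardOutput (and a cache for backward)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input width {X.shape[1]} != configured input_dim {self.config.input_dim}"
            )
        cache: dict = {"X": X}
        h = X
        for k in range(3):
            z = self._affine(f"nl{k}", h)
            cache[f"nl{k}_in"], cache[f"nl{k}_z"] = h, z
            h = np.maximum(z, 0.0)
        lin = self._affine("lin", X)
        shared = h + lin
        cache["shared"] = shared

        def head(prefix: str, n_layers: int) -> np.ndarray:
            hh = shared
            for k in range(n_layers):
                z = self._affine(f"{prefix}{k}", hh)
                cache[f"{prefix}{k}_in"], cache[f"{prefix}{k}_z"] = hh, z
                hh = np.maximum(z, 0.0) if f"{prefix}{k}" in _RELU_LAYERS else z
            return hh

        y_hat = head("trait", 3)[:, 0]
        emb = head("emb", 3)
        out = ForwardOutput(y_hat=y_hat, embedding=emb)
        if want_cache:
            return out, cache
        return out

    # -- backward -----------------------------------------------------------
    def backward(self, cache: dict, d_yhat: np.ndarray, d_emb: np.ndarray | None = None) -> dict:
        """Gradients of a scalar loss given d loss/d y_hat and d loss/d emb."""
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        d_shared = np.zeros_like(cache["shared"])

        def back_head(prefix: str, delta: np.ndarray) -> np.ndarray:
            for k in range(2, -1, -1):
                name = f"{prefix}{k}"
                if name in _RELU_LAYERS:
                    delta = delta * (cache[f"{name}_z"] > 0)
                h_in = cache[f"{name}_in"]
                grads[f"{name}_W"] += h_in.T @ delta
                grads[f"{name}_b"] += delta.sum(axis=0)
                delta = delta @ self.params[f"{name}_W"].T
            return delta

        d_shared += back_head("trait", np.asarray(d_yhat, dtype=float)[:, None])
        if d_emb is not None:
            d_shared += back_head("emb", np.asarray(d_emb, dtype=float))

        # linear pathway
        X = cache["X"]
        grads["lin_W"] += X.T @ d_shared
        grads["lin_b"] += d_shared.sum(axis=0)
        # nonlinear pathway
        delta = d_shared
        for k in range(2, -1, -1):
            delta = delta * (cache[f"nl{k}_z"] > 0)
            grads[f"nl{k}_W"] += cache[f"nl{k}_in"].T @ delta
            grads[f"nl{k}_b"] += delta.sum(axis=0)
            delta = delta @ self.params[f"nl{k}_W"].T
        return grads


def build_model(cfg: ModelConfig) -> ClcnetNetwork:
    """Deterministically initialised network from a config."""
    return ClcnetNetwork(cfg)


def forward(model: ClcnetNetwork, X: np.ndarray) -> ForwardOutput:
    """Functional alias for ``model.forward``."""
    return model.forward(X)
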