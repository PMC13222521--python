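"""Model/Results interface over the network and training loop.

``CLCNet`` is constructed from the (already selected, already standardized)
training arrays, mirroring how statistical modelling packages bind data at
model construction; ``fit`` trains a freshly initialised network and
returns a ``CLCNetResults`` carrying the trained parameters, the training
history and prediction/embedding methods plus a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ClcnetNetwork, ModelConfig
from .training import TrainConfig, TrainHistory, train_model

__all__ = ["CLCNet", "CLCNetResults"]


class CLCNet:
    """Dual-pathway contrastive genomic-prediction model bound to data.

    Parameters
    ----------
    X, y : training inputs (n × selected-SNP dosage codes) and standardized
        trait values.
    X_valid, y_valid : optional monitoring split (never trained on).
    scale : width multiplier for the network (1.0 = full-size dims).
    seed : parameter-initialisation seed.
    """

    def __init__(self, X, y, X_valid=None, y_valid=None, scale: float = 0.125,
                 seed: int = 0):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D and aligned with y")
        self.X_valid = None if X_valid is None else np.asarray(X_valid, dtype=float)
        self.y_valid = None if y_valid is None else np.asarray(y_valid, dtype=float)
        self.config = ModelConfig(input_dim=self.X.shape[1], scale=scale, seed=seed)

    def fit(self, train_config: TrainConfig | None = None) -> "CLCNetResults":
        net = ClcnetNetwork(self.config)
        train_config = train_config or TrainConfig()
        history = train_model(net, self.X, self.y, train_config,
                              self.X_valid, self.y_valid)
        return CLCNetResults(self, net, history, train_config)


@dataclass
class CLCNetResults:
    """Trained network plus history; prediction and embedding interface."""

    model: CLCNet
    network: ClcnetNetwork
    history: TrainHistory
    train_config: TrainConfig

    def predict(self, X) -> np.ndarray:
        return self.network.forward(np.asarray(X, dtype=float)).y_hat

    def embed(self, X) -> np.ndarray:
        return self.network.forward(np.asarray(X, dtype=float)).embedding

    def summary(self) -> str:
        cfg = self.network.config
        h = self.history
        lines = [
            "CLCNet results",
            "=" * 46,
            f"input SNPs:          {cfg.input_dim}",
            f"width scale:         {cfg.scale}",
            f"backbone dims:       {cfg.backbone_dims}",
            f"trait head dims:     {cfg.trait_head_dims}",
            f"embedding head dims: {cfg.embed_head_dims}",
            f"parameters:          {self.network.n_parameters()}",
            f"epochs trained:      {len(h.mse1)}",
            f"final mse1/mse2:     {h.mse1[-1]:.4f} / {h.mse2[-1]:.4f}",
            f"final contrastive:   {h.contrastive[-1]:.4f}",
            f"final valid PCC:     {h.val_pcc[-1]:.4f}",
            f"lr/batch/epochs:     {self.train_config.learning_rate}/"
            f"{self.train_config.batch_size}/{self.train_config.epochs}",
            f"contrastive weight:  {self.train_config.contrastive_weight}",
        ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        cfg = self.network.config
        np.savez(
            path,
            __input_dim=cfg.input_dim, __scale=cfg.scale, __seed=cfg.seed,
            **self.network.params,
        )

    @staticmethod
    def load_network(path) -> ClcnetNetwork:
        data = np.load(path)
        cfg = ModelConfig(int(data["__input_dim"]), float(data["__scale"]),
                          int(data["__seed"]))
        net = ClcnetNetwork(cfg)
        for k in net.params:
            net.params[k] = data[k]
        return net
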