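"""Heart-rate correction network.

A fully connected regression network maps nine features (eight condition
factors plus the radar-measured heart rate) to a corrected heart rate, with
the reference (oximeter) heart rate as the training label.  Architecture:
9 -> 64 -> 128 -> 256 -> 128 -> 1 with PReLU activations and dropout rates
0.2 / 0.3 / 0.4 on the three hidden layers; MSE loss; Adagrad updates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import nn
from .exceptions import (
    DivergenceError,
    InvalidConfigError,
    ShapeError,
    ValidationError,
)
from .synth import ANGLE_VALUES

FEATURES = (
    "direction",
    "angle",
    "gender",
    "height",
    "weight",
    "age",
    "distance",
    "motion_status",
    "radar_hr",
)
TARGET = "oximeter_hr"

#: Ordinal features fed as scaled integers; the rest are z-scored.
_ORDINAL_SCALE = {"direction": 5.0, "angle": 4.0, "gender": 1.0, "motion_status": 3.0}
_CONTINUOUS = ("height", "weight", "age", "distance", "radar_hr")

HR_CLAMP = (30.0, 220.0)

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class CorrectionNetConfig:
    input_dim: int = 9
    layer_widths: Tuple[int, ...] = (64, 128, 256, 128)
    dropout_rates: Tuple[float, ...] = (0.0, 0.2, 0.3, 0.4)
    prelu_slope: float = 0.25
    learning_rate: float = 0.01
    epsilon: float = 1e-8
    epochs: int = 200
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_widths) != len(self.dropout_rates):
            raise InvalidConfigError("layer_widths and dropout_rates must align")
        if any(not (0 <= r < 1) for r in self.dropout_rates):
            raise InvalidConfigError("dropout rates must be in [0, 1)")
        if self.learning_rate <= 0 or self.epsilon <= 0:
            raise InvalidConfigError("learning_rate and epsilon must be positive")


# ---------------------------------------------------------------------------
# spec-level primitive operations
# ---------------------------------------------------------------------------


def mse_loss(predicted, true) -> float:
    """Mean squared error (1/n) * sum (y - yhat)^2."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(true, dtype=float)
    if p.shape != y.shape or p.size == 0:
        raise ShapeError(f"shape mismatch or empty: {p.shape} vs {y.shape}")
    return float(np.mean((y - p) ** 2))


@dataclass
class AdagradState:
    """Parameters plus per-parameter accumulated squared gradients."""

    params: List[np.ndarray]
    accum: List[np.ndarray]
    t: int = 0

    @classmethod
    def init(cls, params: Sequence[np.ndarray]) -> "AdagradState":
        ps = [np.asarray(p, dtype=float) for p in params]
        return cls(params=ps, accum=[np.zeros_like(p) for p in ps], t=0)


def adagrad_step(
    state: AdagradState, gradients: Sequence[np.ndarray], lr: float, eps: float
) -> AdagradState:
    """One Adagrad update: G <- G + g^2; theta <- theta - lr*g/sqrt(G + eps)."""
    new_params, new_accum = [], []
    for idx, (p, acc, g) in enumerate(zip(state.params, state.accum, gradients)):
        g = np.asarray(g, dtype=float)
        if not np.all(np.isfinite(g)):
            raise DivergenceError(f"non-finite gradient for parameter {idx}")
        if g.shape != p.shape:
            raise ShapeError(f"gradient shape {g.shape} != parameter shape {p.shape}")
        acc2 = acc + g * g
        new_params.append(p - lr * g / np.sqrt(acc2 + eps))
        new_accum.append(acc2)
    return AdagradState(params=new_params, accum=new_accum, t=state.t + 1)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def _build_net(config: CorrectionNetConfig, rng: np.random.Generator) -> nn.Sequential:
    drop_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    widths = config.layer_widths
    layers: List[nn.Layer] = [nn.Dense(config.input_dim, widths[0], rng)]
    if config.dropout_rates[0] > 0:
        layers.append(nn.Dropout(config.dropout_rates[0], drop_rng))
    for k in range(1, len(widths)):
        layers.append(nn.Dense(widths[k - 1], widths[k], rng))
        layers.append(nn.PReLU(config.prelu_slope))
        if config.dropout_rates[k] > 0:
            layers.append(nn.Dropout(config.dropout_rates[k], drop_rng))
    layers.append(nn.Dense(widths[-1], 1, rng))
    return nn.Sequential(layers)


class CorrectionModel:
    """Trained corrector: network plus feature/target scalers."""

    def __init__(
        self,
        net: nn.Sequential,
        config: CorrectionNetConfig,
        feature_stats: Dict[str, Tuple[float, float]],
        target_stats: Tuple[float, float],
    ) -> None:
        self.net = net
        self.config = config
        self.feature_stats = feature_stats
        self.target_stats = target_stats

    def _design_matrix(self, records: pd.DataFrame) -> np.ndarray:
        for col in FEATURES:
            if col not in records.columns:
                raise ValidationError(f"missing feature column: {col!r}")
        cols = []
        for col in FEATURES:
            v = records[col].to_numpy(dtype=float)
            if col in _ORDINAL_SCALE:
                if col == "angle":
                    # degrees -> ordinal rank index
                    v = np.searchsorted(ANGLE_VALUES, v).astype(float)
                cols.append(v / _ORDINAL_SCALE[col])
            else:
                mean, sd = self.feature_stats[col]
                cols.append((v - mean) / sd)
        return np.column_stack(cols)

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        """Corrected heart rates, deterministic (dropout off), clamped."""
        x = self._design_matrix(records)
        z = self.net.forward(x, train=False)[:, 0]
        mean, sd = self.target_stats
        return np.clip(z * sd + mean, *HR_CLAMP)

    # -- checkpointing (JSON, text-only) ------------------------------------

    def save(self, path) -> None:
        payload = {
            "version": CHECKPOINT_VERSION,
            "kind": "correction",
            "config": {
                "input_dim": self.config.input_dim,
                "layer_widths": list(self.config.layer_widths),
                "dropout_rates": list(self.config.dropout_rates),
                "prelu_slope": self.config.prelu_slope,
                "learning_rate": self.config.learning_rate,
                "epsilon": self.config.epsilon,
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "seed": self.config.seed,
            },
            "feature_stats": self.feature_stats,
            "target_stats": list(self.target_stats),
            "state": self.net.state_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "CorrectionModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("version") != CHECKPOINT_VERSION or payload.get("kind") != "correction":
            raise ValidationError(f"unsupported checkpoint: {path}")
        cfg = payload["config"]
        config = CorrectionNetConfig(
            input_dim=cfg["input_dim"],
            layer_widths=tuple(cfg["layer_widths"]),
            dropout_rates=tuple(cfg["dropout_rates"]),
            prelu_slope=cfg["prelu_slope"],
            learning_rate=cfg["learning_rate"],
            epsilon=cfg["epsilon"],
            epochs=cfg["epochs"],
            batch_size=cfg["batch_size"],
            seed=cfg["seed"],
        )
        net = _build_net(config, np.random.default_rng(config.seed))
        net.load_state_dict(payload["state"])
        stats = {k: (float(v[0]), float(v[1])) for k, v in payload["feature_stats"].items()}
        return cls(net, config, stats, tuple(payload["target_stats"]))


def train_corrector(
    records: pd.DataFrame, config: Optional[CorrectionNetConfig] = None
) -> Tuple[CorrectionModel, dict]:
    """Train the correction network on a table of correction records.

    Returns the trained model plus a log with per-epoch training loss.
    Continuous features and the target are standardized with statistics of
    the provided records; ordinal features are fed as scaled integers.
    """
    if config is None:
        config = CorrectionNetConfig()
    if len(records) < 2:
        raise ValidationError("need at least 2 records to train")
    for col in FEATURES + (TARGET,):
        if col not in records.columns:
            raise ValidationError(f"missing column: {col!r}")

    feature_stats = {}
    for col in _CONTINUOUS:
        v = records[col].to_numpy(dtype=float)
        sd = float(np.std(v))
        feature_stats[col] = (float(np.mean(v)), sd if sd > 0 else 1.0)
    y_raw = records[TARGET].to_numpy(dtype=float)
    t_sd = float(np.std(y_raw))
    target_stats = (float(np.mean(y_raw)), t_sd if t_sd > 0 else 1.0)

    rng = np.random.default_rng(config.seed)
    net = _build_net(config, rng)
    model = CorrectionModel(net, config, feature_stats, target_stats)

    x = model._design_matrix(records)
    y = ((y_raw - target_stats[0]) / target_stats[1])[:, None]

    opt = nn.AdagradOptimizer(net, lr=config.learning_rate, eps=config.epsilon)
    n = len(x)
    log = {"epoch_loss": []}
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred = net.forward(x[idx], train=True)
            loss, grad = nn.mse_value_and_grad(pred, y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(
                    "training loss became non-finite; try a lower learning rate"
                )
            net.backward(grad)
            opt.step()
            losses.append(loss)
        log["epoch_loss"].append(float(np.mean(losses)))
    return model, log


def correct(model: CorrectionModel, records: pd.DataFrame) -> np.ndarray:
    """Apply a trained model; one finite corrected BPM per record."""
    return model.predict(records)
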