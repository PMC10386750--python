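"""CNN RR-interval anomaly detector, sliding-window inference and latency.

The classifier consumes 1024 consecutive RR intervals and outputs whether
the *last* interval of the window is abnormal.  Sliding the window one
interval at a time over a sequence of n intervals yields n - 1023 flags,
one per end index e in [1024, n].

For an annotated abnormal segment [i, j] (1-based, j > i >= 1024) the
latency value k is defined from the first flagged end index e* >= i as
k = e* - i, clamped to a minimum of 1 (a flag at the very first abnormal
interval counts as k = 1 since k is a positive integer).  Flags strictly
before i are false alarms, counted separately.
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
    ClassBalanceError,
    DivergenceError,
    InsufficientDataError,
    InvalidConfigError,
    RangeError,
    ShapeError,
    ValidationError,
)
from .synth import AbnormalSegment, RRSequence, generate_rr_sequence, insert_abnormal_segments, label_windows

WINDOW = 1024

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class DetectorNetConfig:
    window: int = WINDOW
    channels: Tuple[int, int] = (16, 32)
    kernels: Tuple[int, int] = (7, 5)
    pool: int = 4
    fc_hidden: Tuple[int, int] = (64, 32)
    fc_dropout: float = 0.3
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    epochs: int = 15
    batch_size: int = 32
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.decision_threshold < 1):
            raise InvalidConfigError("decision_threshold must be in (0, 1)")
        if self.window % (self.pool * self.pool) != 0:
            raise InvalidConfigError("window must be divisible by pool^2")
        if not (0 <= self.fc_dropout < 1):
            raise InvalidConfigError("fc_dropout must be in [0, 1)")


# ---------------------------------------------------------------------------
# spec-level primitive operations
# ---------------------------------------------------------------------------


def cross_entropy_loss(probabilities, labels) -> float:
    """Binary cross entropy -(1/N) sum [y log p + (1-y) log(1-p)].

    Probabilities are clipped into (0, 1) at 1e-12 before taking logs.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape or p.size == 0:
        raise ShapeError(f"shape mismatch or empty: {p.shape} vs {y.shape}")
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class AdamState:
    """Adam moment estimates for a list of parameter arrays."""

    params: List[np.ndarray]
    m: List[np.ndarray]
    v: List[np.ndarray]
    t: int = 0
    alpha: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    @classmethod
    def init(
        cls,
        params: Sequence[np.ndarray],
        alpha: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> "AdamState":
        ps = [np.asarray(p, dtype=float) for p in params]
        return cls(
            params=ps,
            m=[np.zeros_like(p) for p in ps],
            v=[np.zeros_like(p) for p in ps],
            t=0,
            alpha=alpha,
            beta1=beta1,
            beta2=beta2,
            eps=eps,
        )


def adam_step(state: AdamState, gradients: Sequence[np.ndarray]) -> AdamState:
    """One Adam update with bias-corrected first and second moments."""
    t = state.t + 1
    b1, b2 = state.beta1, state.beta2
    new_params, new_m, new_v = [], [], []
    for idx, (p, m, v, g) in enumerate(zip(state.params, state.m, state.v, gradients)):
        g = np.asarray(g, dtype=float)
        if not np.all(np.isfinite(g)):
            raise DivergenceError(f"non-finite gradient for parameter {idx}")
        if g.shape != p.shape:
            raise ShapeError(f"gradient shape {g.shape} != parameter shape {p.shape}")
        m2 = b1 * m + (1 - b1) * g
        v2 = b2 * v + (1 - b2) * g * g
        mhat = m2 / (1 - b1**t)
        vhat = v2 / (1 - b2**t)
        new_params.append(p - state.alpha * mhat / (np.sqrt(vhat) + state.eps))
        new_m.append(m2)
        new_v.append(v2)
    return AdamState(
        params=new_params,
        m=new_m,
        v=new_v,
        t=t,
        alpha=state.alpha,
        beta1=state.beta1,
        beta2=state.beta2,
        eps=state.eps,
    )


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


def _build_net(config: DetectorNetConfig, rng: np.random.Generator) -> nn.Sequential:
    drop_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    c1, c2 = config.channels
    k1, k2 = config.kernels
    flat = c2 * config.window // (config.pool * config.pool)
    h1, h2 = config.fc_hidden
    layers: List[nn.Layer] = [
        nn.Conv1d(1, c1, k1, rng),
        nn.BatchNorm1d(c1),
        nn.ReLU(),
        nn.AvgPool1d(config.pool),
        nn.Conv1d(c1, c2, k2, rng),
        nn.BatchNorm1d(c2),
        nn.ReLU(),
        nn.AvgPool1d(config.pool),
        nn.Flatten(),
        nn.Dense(flat, h1, rng),
        nn.ReLU(),
        nn.Dropout(config.fc_dropout, drop_rng),
        nn.Dense(h1, h2, rng),
        nn.ReLU(),
        nn.Dense(h2, 2, rng),
    ]
    return nn.Sequential(layers)


class DetectorModel:
    """Trained detector: network, window length and input scaler."""

    def __init__(self, net: nn.Sequential, config: DetectorNetConfig, global_sd: float) -> None:
        self.net = net
        self.config = config
        self.global_sd = global_sd

    def _standardize(self, windows: np.ndarray) -> np.ndarray:
        # per-window mean removal, global training sd
        x = windows - windows.mean(axis=1, keepdims=True)
        return (x / self.global_sd)[:, None, :]

    def predict_proba(self, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Abnormal-class probability for each 1024-interval window."""
        windows = np.asarray(windows, dtype=float)
        if windows.ndim != 2 or windows.shape[1] != self.config.window:
            raise ShapeError(
                f"expected (m, {self.config.window}) windows, got {windows.shape}"
            )
        out = np.empty(len(windows))
        for start in range(0, len(windows), batch_size):
            batch = self._standardize(windows[start : start + batch_size])
            logits = self.net.forward(batch, train=False)
            out[start : start + len(batch)] = nn.softmax(logits)[:, 1]
        return out

    def save(self, path) -> None:
        c = self.config
        payload = {
            "version": CHECKPOINT_VERSION,
            "kind": "detector",
            "config": {
                "window": c.window,
                "channels": list(c.channels),
                "kernels": list(c.kernels),
                "pool": c.pool,
                "fc_hidden": list(c.fc_hidden),
                "fc_dropout": c.fc_dropout,
                "learning_rate": c.learning_rate,
                "beta1": c.beta1,
                "beta2": c.beta2,
                "epsilon": c.epsilon,
                "epochs": c.epochs,
                "batch_size": c.batch_size,
                "seed": c.seed,
                "decision_threshold": c.decision_threshold,
            },
            "global_sd": self.global_sd,
            "state": self.net.state_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "DetectorModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("version") != CHECKPOINT_VERSION or payload.get("kind") != "detector":
            raise ValidationError(f"unsupported checkpoint: {path}")
        cfg = payload["config"]
        config = DetectorNetConfig(
            window=cfg["window"],
            channels=tuple(cfg["channels"]),
            kernels=tuple(cfg["kernels"]),
            pool=cfg["pool"],
            fc_hidden=tuple(cfg["fc_hidden"]),
            fc_dropout=cfg["fc_dropout"],
            learning_rate=cfg["learning_rate"],
            beta1=cfg["beta1"],
            beta2=cfg["beta2"],
            epsilon=cfg["epsilon"],
            epochs=cfg["epochs"],
            batch_size=cfg["batch_size"],
            seed=cfg["seed"],
            decision_threshold=cfg["decision_threshold"],
        )
        net = _build_net(config, np.random.default_rng(config.seed))
        net.load_state_dict(payload["state"])
        return cls(net, config, float(payload["global_sd"]))


def build_training_corpus(
    n_sequences: int = 48,
    seq_len: int = 1600,
    segments_per_seq: int = 6,
    mean_rr_range: Tuple[float, float] = (280.0, 520.0),
    length_range: Tuple[int, int] = (20, 60),
    normal_mean: float = 900.0,
    normal_sd: float = 40.0,
    stride: int = 8,
    window: int = WINDOW,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Class-balanced window corpus from generated RR sequences.

    Windows are sampled with the given stride from each sequence's sliding
    windows and labeled by their last interval; per sequence, all abnormal
    stride windows are kept and an equal number of normal stride windows is
    subsampled.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_sequences)
    xs, ys = [], []
    for child in children:
        rng = np.random.default_rng(child)
        s1, s2 = rng.integers(0, 2**31 - 1, size=2)
        seq = generate_rr_sequence(seq_len, normal_mean, normal_sd, seed=int(s1))
        specs = [
            (float(rng.uniform(*mean_rr_range)), int(rng.integers(length_range[0], length_range[1] + 1)))
            for _ in range(segments_per_seq)
        ]
        seq = insert_abnormal_segments(seq, specs, min_start=window, seed=int(s2))
        labels = label_windows(seq, window=window)
        sub = labels.iloc[::stride]
        views = np.lib.stride_tricks.sliding_window_view(seq.intervals, window)
        idx = sub["end_index"].to_numpy() - window  # window start, 0-based
        w = views[idx]
        lab = sub["label"].to_numpy()
        ab = np.flatnonzero(lab == 1)
        norm = np.flatnonzero(lab == 0)
        keep_norm = rng.choice(norm, size=min(len(ab), len(norm)), replace=False)
        keep = np.concatenate([ab, keep_norm])
        xs.append(w[keep])
        ys.append(lab[keep])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    order = np.random.default_rng(ss.spawn(1)[0]).permutation(len(x))
    return x[order].copy(), y[order].copy()


def train_detector(
    windows: np.ndarray,
    labels: np.ndarray,
    config: Optional[DetectorNetConfig] = None,
    val_fraction: float = 0.2,
) -> Tuple[DetectorModel, dict]:
    """Train the CNN classifier on labeled windows.

    Returns the trained model and a log with per-epoch training loss and
    validation accuracy on a held-out fraction.
    """
    if config is None:
        config = DetectorNetConfig()
    windows = np.asarray(windows, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if windows.ndim != 2 or windows.shape[1] != config.window:
        raise ShapeError(f"expected (m, {config.window}) windows, got {windows.shape}")
    if len(windows) != len(labels):
        raise ShapeError("windows and labels length mismatch")
    if len(np.unique(labels)) < 2:
        raise ClassBalanceError("training data must contain both classes")

    rng = np.random.default_rng(config.seed)
    net = _build_net(config, rng)
    centered = windows - windows.mean(axis=1, keepdims=True)
    global_sd = float(np.std(centered))
    if global_sd == 0:
        global_sd = 1.0
    model = DetectorModel(net, config, global_sd)

    n = len(windows)
    order = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if val_fraction > 0 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(np.unique(labels[train_idx])) < 2:
        raise ClassBalanceError("training split must contain both classes")

    x_train = model._standardize(windows[train_idx])
    y_train = labels[train_idx]
    opt = nn.AdamOptimizer(
        net, lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2, eps=config.epsilon
    )
    log = {"epoch_loss": [], "val_accuracy": []}
    m = len(train_idx)
    for _epoch in range(config.epochs):
        perm = rng.permutation(m)
        losses = []
        for start in range(0, m, config.batch_size):
            idx = perm[start : start + config.batch_size]
            logits = net.forward(x_train[idx], train=True)
            loss, grad = nn.softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise DivergenceError("training loss became non-finite")
            net.backward(grad)
            opt.step()
            losses.append(loss)
        log["epoch_loss"].append(float(np.mean(losses)))
        if n_val:
            probs = model.predict_proba(windows[val_idx])
            acc = float(np.mean((probs >= 0.5).astype(int) == labels[val_idx]))
            log["val_accuracy"].append(acc)
    return model, log


# ---------------------------------------------------------------------------
# sliding-window inference and latency
# ---------------------------------------------------------------------------


@dataclass
class SegmentDetection:
    """Latency outcome for one abnormal segment."""

    segment: AbnormalSegment
    k: Optional[int]  # None when not detected
    false_alarms_before: int = 0

    @property
    def detected(self) -> bool:
        return self.k is not None


@dataclass
class DetectionResult:
    """Per-window flags plus (optionally) per-segment latency outcomes."""

    flags: pd.DataFrame  # columns: end_index, prob, flag
    window: int
    per_segment: List[SegmentDetection] = field(default_factory=list)


def sliding_window_detect(
    model: DetectorModel, seq: RRSequence, threshold: Optional[float] = None
) -> DetectionResult:
    """Evaluate every 1024-interval subsequence of ``seq``.

    Emits exactly n - window + 1 flags at end indices window..n; a window is
    flagged iff its abnormal-class probability is >= threshold.
    """
    w = model.config.window
    n = len(seq)
    if n < w:
        raise InsufficientDataError(
            f"the detector needs at least {w} consecutive RR intervals, got {n}"
        )
    if threshold is None:
        threshold = model.config.decision_threshold
    views = np.lib.stride_tricks.sliding_window_view(seq.intervals, w)
    probs = model.predict_proba(views)
    ends = np.arange(w, n + 1)
    flags = pd.DataFrame(
        {"end_index": ends, "prob": probs, "flag": (probs >= threshold).astype(int)}
    )
    return DetectionResult(flags=flags, window=w)


def latency_k(result: DetectionResult, segment: AbnormalSegment) -> SegmentDetection:
    """Latency value k of a segment under a detection result.

    k = max(e* - i, 1) where e* is the smallest flagged end index >= i;
    a segment with no such flag is reported as not detected.  Flags at end
    indices strictly before i count as false alarms.
    """
    ends = result.flags["end_index"].to_numpy()
    if segment.i < ends.min() or segment.j > ends.max():
        raise RangeError(
            f"segment ({segment.i}, {segment.j}) outside detected range "
            f"[{ends.min()}, {ends.max()}]"
        )
    flagged = ends[result.flags["flag"].to_numpy() == 1]
    false_alarms = int(np.sum(flagged < segment.i))
    at_or_after = flagged[flagged >= segment.i]
    if len(at_or_after) == 0:
        return SegmentDetection(segment=segment, k=None, false_alarms_before=false_alarms)
    e_star = int(at_or_after[0])
    return SegmentDetection(
        segment=segment, k=max(e_star - segment.i, 1), false_alarms_before=false_alarms
    )


def evaluate_latency_experiment(
    model: DetectorModel,
    seq: RRSequence,
    max_k: int = 10,
    threshold: Optional[float] = None,
) -> Tuple[pd.DataFrame, dict]:
    """Latency table for every annotated segment of ``seq``.

    One row per segment (ordered by start index): average RR, latency k and
    success (k <= max_k); plus a summary with the success count and the
    maximum k over detected segments.
    """
    if not seq.segments:
        raise InvalidConfigError("sequence carries no annotated abnormal segments")
    result = sliding_window_detect(model, seq, threshold=threshold)
    rows = []
    detections = []
    for num, seg in enumerate(sorted(seq.segments, key=lambda s: s.i), start=1):
        det = latency_k(result, seg)
        detections.append(det)
        success = det.detected and det.k <= max_k
        rows.append(
            {
                "segment": num,
                "start_index": seg.i,
                "end_index": seg.j,
                "average_rr_ms": seg.mean_rr,
                "latency_k": det.k if det.detected else None,
                "result": "success" if success else ("failure" if det.detected else "not_detected"),
            }
        )
    result.per_segment = detections
    table = pd.DataFrame(rows)
    detected_ks = [d.k for d in detections if d.detected]
    summary = {
        "n_segments": len(rows),
        "n_success": int(sum(r["result"] == "success" for r in rows)),
        "max_k": max(detected_ks) if detected_ks else None,
        "min_k": min(detected_ks) if detected_ks else None,
        "max_k_allowed": max_k,
    }
    return table, summary
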