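"""Shared file I/O, experiment orchestration, and the end-to-end pipeline.

A single top-level seed is split into independent per-stage substreams with
``numpy.random.SeedSequence.spawn`` in a fixed documented order:

    0: dependence calibration     3: RR sequence + segment insertion
    1: correction-record dataset  4: detector training corpus
    2: corrector training         5: detector training

so every stage is reproducible in isolation and the whole pipeline is
reproducible end to end.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import anomaly, correction, metrics, synth
from .exceptions import ValidationError

#: Average RR (ms) of the six inserted abnormal segments in the reference
#: latency experiment.
REFERENCE_SEGMENT_MEANS = (350.0, 315.0, 450.0, 350.0, 299.5, 502.0)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def read_table(path, required_columns: Sequence[str]) -> pd.DataFrame:
    """Read a CSV with schema validation.

    Raises :class:`ValidationError` naming the first missing column, on
    non-numeric cells in required columns, or on an empty file.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise ValidationError(f"empty input file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty input file: {path}") from exc
    for col in required_columns:
        if col not in df.columns:
            raise ValidationError(f"missing column: {col!r} in {path}")
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric values in column {col!r} of {path}") from exc
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a canonical CSV: comma-separated, UTF-8, header row, '.' decimals."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# experiment helpers
# ---------------------------------------------------------------------------


def train_test_split_indices(
    n: int, test_fraction: float, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    return order[n_test:], order[:n_test]


def run_correction_experiment(
    records: pd.DataFrame,
    config: Optional[correction.CorrectionNetConfig] = None,
    test_fraction: float = 0.2,
    split_seed: Optional[int] = None,
) -> Tuple[correction.CorrectionModel, dict]:
    """Train/test-split correction experiment with before/after metrics."""
    if config is None:
        config = correction.CorrectionNetConfig()
    if split_seed is None:
        split_seed = config.seed
    train_idx, test_idx = train_test_split_indices(len(records), test_fraction, split_seed)
    train_df = records.iloc[train_idx].reset_index(drop=True)
    test_df = records.iloc[test_idx].reset_index(drop=True)

    model, log = correction.train_corrector(train_df, config)
    corrected = correction.correct(model, test_df)
    y_true = test_df[correction.TARGET].to_numpy(dtype=float)
    measured = test_df["radar_hr"].to_numpy(dtype=float)
    before = metrics.error_metrics(y_true, measured)
    after = metrics.error_metrics(y_true, corrected)
    report = {
        "n_train": len(train_df),
        "n_test": len(test_df),
        "measured": before.as_dict(),
        "corrected": after.as_dict(),
        "reduction_pct": metrics.percent_reduction(before, after),
        "final_epoch_loss": log["epoch_loss"][-1],
    }
    return model, report


def build_reference_sequence(
    seed: int,
    n: int = 1600,
    normal_mean: float = 900.0,
    normal_sd: float = 40.0,
    segment_means: Sequence[float] = REFERENCE_SEGMENT_MEANS,
    length_range: Tuple[int, int] = (20, 60),
    min_start: int = 1024,
) -> synth.RRSequence:
    """1600-interval sequence with the six reference abnormal segments."""
    rng = np.random.default_rng(seed)
    s_norm, s_place = rng.integers(0, 2**31 - 1, size=2)
    seq = synth.generate_rr_sequence(n, normal_mean, normal_sd, seed=int(s_norm))
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=len(segment_means))
    specs = [(float(m), int(l)) for m, l in zip(segment_means, lengths)]
    return synth.insert_abnormal_segments(seq, specs, min_start=min_start, seed=int(s_place))


def run_anomaly_experiment(
    config: Optional[anomaly.DetectorNetConfig] = None,
    corpus_seed: int = 0,
    sequence_seed: int = 1,
    max_k: int = 10,
    segment_means: Sequence[float] = REFERENCE_SEGMENT_MEANS,
) -> Tuple[anomaly.DetectorModel, pd.DataFrame, dict]:
    """Train the detector and run the six-segment latency experiment."""
    if config is None:
        config = anomaly.DetectorNetConfig()
    windows, labels = anomaly.build_training_corpus(seed=corpus_seed, window=config.window)
    model, log = anomaly.train_detector(windows, labels, config)
    seq = build_reference_sequence(sequence_seed, min_start=config.window, segment_means=segment_means)
    table, summary = anomaly.evaluate_latency_experiment(model, seq, max_k=max_k)
    summary["final_val_accuracy"] = log["val_accuracy"][-1] if log["val_accuracy"] else None
    return model, table, summary


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    seed: int = 0
    n_records: int = 10_400
    corrector: Dict = field(default_factory=dict)
    detector: Dict = field(default_factory=dict)
    detector_corpus: Dict = field(default_factory=dict)
    rr_length: int = 1600
    segment_means: Tuple[float, ...] = REFERENCE_SEGMENT_MEANS
    segment_length_range: Tuple[int, int] = (20, 60)
    max_k: int = 10


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute both experiment chains and write artifacts plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    subs = [int(s.generate_state(1)[0]) for s in ss.spawn(6)]

    stage = "calibration"
    try:
        calibration = synth.calibrate_dependence(seed=subs[0])

        stage = "gen-data"
        records = synth.generate_correction_dataset(config.n_records, calibration, seed=subs[1])
        write_table(records, out / "correction_records.csv")

        stage = "train-corrector"
        net_config = correction.CorrectionNetConfig(seed=subs[2] % 2**31, **config.corrector)
        model, report = run_correction_experiment(records, net_config)
        model.save(out / "corrector.json")
        (out / "correction_report.json").write_text(json.dumps(report, indent=2))

        stage = "train-detector-config"
        det_config = anomaly.DetectorNetConfig(seed=subs[5] % 2**31, **config.detector)

        stage = "gen-rr"
        seq = build_reference_sequence(
            subs[3],
            n=config.rr_length,
            segment_means=config.segment_means,
            length_range=config.segment_length_range,
            min_start=det_config.window,
        )
        write_table(seq.to_frame(), out / "rr_sequence.csv")
        (out / "rr_segments.json").write_text(
            json.dumps(
                [{"i": s.i, "j": s.j, "mean_rr": s.mean_rr} for s in seq.segments], indent=2
            )
        )

        stage = "train-detector"
        windows, labels = anomaly.build_training_corpus(
            seed=subs[4], window=det_config.window, **config.detector_corpus
        )
        detector, _log = anomaly.train_detector(windows, labels, det_config)
        detector.save(out / "detector.json")

        stage = "eval-latency"
        table, summary = anomaly.evaluate_latency_experiment(detector, seq, max_k=config.max_k)
        write_table(table, out / "latency_table.csv")
        (out / "latency_summary.json").write_text(json.dumps(summary, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "files": {p.name: file_sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
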