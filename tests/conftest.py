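"""Shared fixtures.

Heavy artifacts (trained models, calibrations) are session-scoped and built
at reduced scale; full-scale runs live in test_acceptance.py only.
"""

from __future__ import annotations

import numpy as np
import pytest

from radarvitals import anomaly, correction, pipeline, synth


@pytest.fixture(scope="session")
def default_calibration():
    """Default dependence calibration (used by several modules)."""
    return synth.calibrate_dependence(seed=0)


@pytest.fixture(scope="session")
def small_records(default_calibration):
    """4,000 correction records from the default calibration."""
    return synth.generate_correction_dataset(4000, default_calibration, seed=11)


@pytest.fixture(scope="session")
def small_correction_run(small_records):
    """Reduced-scale corrector training run shared across assertions."""
    config = correction.CorrectionNetConfig(seed=0, epochs=60)
    model, report = pipeline.run_correction_experiment(small_records, config)
    return {"model": model, "report": report, "records": small_records, "config": config}


TINY_WINDOW = 64


@pytest.fixture(scope="session")
def tiny_detector():
    """Fast window-64 detector trained on a tiny matched corpus."""
    config = anomaly.DetectorNetConfig(window=TINY_WINDOW, epochs=8, batch_size=16, seed=0)
    windows, labels = anomaly.build_training_corpus(
        n_sequences=24,
        seq_len=200,
        segments_per_seq=2,
        length_range=(5, 12),
        stride=2,
        window=TINY_WINDOW,
        seed=0,
    )
    model, log = anomaly.train_detector(windows, labels, config)
    return {"model": model, "log": log, "config": config}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
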