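import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radarvitals import (
    AbnormalSegment,
    AdamState,
    DetectorModel,
    DetectorNetConfig,
    RRSequence,
    adam_step,
    cross_entropy_loss,
    evaluate_latency_experiment,
    generate_rr_sequence,
    insert_abnormal_segments,
    latency_k,
    sliding_window_detect,
    train_detector,
)
from radarvitals.anomaly import DetectionResult, build_training_corpus
from radarvitals.exceptions import (
    ClassBalanceError,
    InsufficientDataError,
    InvalidConfigError,
    RangeError,
    ShapeError,
)

W = 64  # tiny window used throughout (config default 1024 is exercised in acceptance)


class TestCrossEntropyLoss:
    def test_perfect_prediction(self):
        assert cross_entropy_loss([1.0, 0.0], [1, 0]) == pytest.approx(0.0, abs=1e-10)

    def test_hand_value_ln2(self):
        assert cross_entropy_loss([0.5, 0.5], [1, 0]) == pytest.approx(np.log(2.0))

    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_label_swap_symmetry(self, probs):
        labels = [1 if p > 0.5 else 0 for p in probs]
        swapped = cross_entropy_loss([1 - p for p in probs], [1 - y for y in labels])
        assert cross_entropy_loss(probs, labels) == pytest.approx(swapped)

    def test_nonnegative(self, rng):
        p = rng.uniform(0.01, 0.99, 30)
        y = rng.integers(0, 2, 30)
        assert cross_entropy_loss(p, y) >= 0.0

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            cross_entropy_loss([0.5], [1, 0])


class TestAdamStep:
    def test_zero_gradient_cold_start(self):
        state = AdamState.init([np.array([3.0])], alpha=0.1)
        out = adam_step(state, [np.zeros(1)])
        np.testing.assert_array_equal(out.params[0], state.params[0])

    def test_first_step_hand_value(self):
        # g=1, alpha=0.1, eps=0: mhat = vhat = 1 at t=1 -> step is exactly alpha
        state = AdamState.init([np.array([0.0])], alpha=0.1, eps=0.0)
        out = adam_step(state, [np.array([1.0])])
        assert out.params[0][0] == pytest.approx(-0.1)
        assert out.t == 1

    def test_step_size_bounded_under_constant_gradient(self):
        state = AdamState.init([np.array([0.0])], alpha=0.05)
        for _ in range(20):
            before = state.params[0][0]
            state = adam_step(state, [np.array([2.5])])
            assert abs(state.params[0][0] - before) <= 0.05 * 1.1

    def test_moment_shapes_and_nonneg_v(self, rng):
        state = AdamState.init([rng.normal(size=(3, 2))])
        state = adam_step(state, [rng.normal(size=(3, 2))])
        assert state.m[0].shape == (3, 2)
        assert np.all(state.v[0] >= 0)

    def test_nonfinite_rejected(self):
        state = AdamState.init([np.array([0.0])])
        from radarvitals.exceptions import DivergenceError

        with pytest.raises(DivergenceError):
            adam_step(state, [np.array([np.inf])])


def _separable_corpus(n_per_class=24, window=W, seed=0):
    rng = np.random.default_rng(seed)
    normal = np.full((n_per_class, window), 900.0) + rng.normal(0, 1, (n_per_class, window))
    abnormal = np.full((n_per_class, window), 900.0)
    abnormal[:, -5:] = 350.0
    abnormal += rng.normal(0, 1, abnormal.shape)
    x = np.vstack([normal, abnormal])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return x, y


@pytest.fixture(scope="module")
def separable_model():
    x, y = _separable_corpus()
    config = DetectorNetConfig(window=W, epochs=10, batch_size=8, seed=0)
    model, log = train_detector(x, y, config)
    return model, log


class TestTrainDetector:
    def test_separable_reaches_full_accuracy(self, separable_model):
        _model, log = separable_model
        assert log["val_accuracy"][-1] == 1.0

    def test_single_class_rejected(self):
        x = np.full((10, W), 900.0)
        with pytest.raises(ClassBalanceError):
            train_detector(x, np.zeros(10, dtype=int), DetectorNetConfig(window=W))

    def test_seed_determinism(self):
        x, y = _separable_corpus()
        config = DetectorNetConfig(window=W, epochs=3, batch_size=8, seed=7)
        _m1, log1 = train_detector(x, y, config)
        _m2, log2 = train_detector(x, y, config)
        assert log1["epoch_loss"] == log2["epoch_loss"]
        assert log1["val_accuracy"] == log2["val_accuracy"]

    def test_generated_corpus_learnable(self, tiny_detector):
        # oracle: thresholding the last interval already separates the classes,
        # so the CNN must reach high validation accuracy too
        assert tiny_detector["log"]["val_accuracy"][-1] > 0.95

    def test_corpus_is_balanced_and_labeled(self):
        x, y = build_training_corpus(
            n_sequences=6, seq_len=200, segments_per_seq=2, length_range=(5, 12),
            stride=2, window=W, seed=1,
        )
        assert x.shape[1] == W
        assert 0.3 <= y.mean() <= 0.7
        # labels match the last-interval rule: abnormal windows end low
        assert x[y == 1, -1].mean() < x[y == 0, -1].mean()


def _sequence_with_segment(n, i, j, mean_rr=350.0, seed=0):
    seq = generate_rr_sequence(n, seed=seed)
    out = RRSequence(intervals=seq.intervals.copy())
    rng = np.random.default_rng(seed + 1)
    vals = rng.normal(mean_rr, 5.0, j - i + 1)
    out.intervals[i - 1 : j] = vals - vals.mean() + mean_rr
    out.segments.append(AbnormalSegment(i=i, j=j, mean_rr=mean_rr))
    return out


class TestSlidingWindowDetect:
    def test_single_window(self, separable_model):
        model, _ = separable_model
        seq = RRSequence(intervals=np.full(W, 900.0))
        result = sliding_window_detect(model, seq)
        assert len(result.flags) == 1
        assert result.flags["end_index"].iloc[0] == W

    @pytest.mark.parametrize("n", [W, W + 1, W + 37, 3 * W])
    def test_window_count_conservation(self, separable_model, n):
        model, _ = separable_model
        seq = RRSequence(intervals=np.full(n, 900.0))
        result = sliding_window_detect(model, seq)
        assert len(result.flags) == n - W + 1

    def test_all_normal_constant_yields_no_flags(self, separable_model):
        model, _ = separable_model
        seq = RRSequence(intervals=np.full(200, 900.0))
        result = sliding_window_detect(model, seq)
        assert result.flags["flag"].sum() == 0

    def test_too_short_rejected(self, separable_model):
        model, _ = separable_model
        with pytest.raises(InsufficientDataError):
            sliding_window_detect(model, RRSequence(intervals=np.full(W - 1, 900.0)))


def _result_from_flags(flag_ends, window=W, n=300, probs=None):
    ends = np.arange(window, n + 1)
    flags = np.isin(ends, flag_ends).astype(int)
    if probs is None:
        probs = flags.astype(float)
    return DetectionResult(
        flags=pd.DataFrame({"end_index": ends, "prob": probs, "flag": flags}),
        window=window,
    )


def brute_force_latency(flag_ends, i, n):
    """Oracle: scan windows in order, first flagged end >= i."""
    for e in range(i, n + 1):
        if e in flag_ends:
            return max(e - i, 1)
    return None


class TestLatencyK:
    def test_flag_five_after_start(self):
        seg = AbnormalSegment(i=100, j=140, mean_rr=350.0)
        det = latency_k(_result_from_flags([105, 120]), seg)
        assert det.k == 5

    def test_flag_at_start_clamps_to_one(self):
        seg = AbnormalSegment(i=100, j=140, mean_rr=350.0)
        det = latency_k(_result_from_flags([100]), seg)
        assert det.k == 1

    def test_not_detected(self):
        seg = AbnormalSegment(i=100, j=140, mean_rr=350.0)
        det = latency_k(_result_from_flags([90]), seg)
        assert det.k is None and not det.detected
        assert det.false_alarms_before == 1

    def test_false_alarms_counted_not_used(self):
        seg = AbnormalSegment(i=100, j=140, mean_rr=350.0)
        det = latency_k(_result_from_flags([70, 80, 110]), seg)
        assert det.k == 10
        assert det.false_alarms_before == 2

    @given(
        flag_ends=st.sets(st.integers(W, 300), max_size=20),
        i=st.integers(W, 250),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_scan(self, flag_ends, i):
        j = min(i + 20, 299) + 1
        seg = AbnormalSegment(i=i, j=j, mean_rr=350.0)
        det = latency_k(_result_from_flags(sorted(flag_ends)), seg)
        assert det.k == brute_force_latency(flag_ends, i, 300)

    def test_segment_outside_range_rejected(self):
        seg = AbnormalSegment(i=400, j=420, mean_rr=350.0)
        with pytest.raises(RangeError):
            latency_k(_result_from_flags([100]), seg)

    def test_threshold_monotonicity(self, rng):
        # lowering the decision threshold never increases k
        ends = np.arange(W, 301)
        probs = rng.uniform(0, 1, len(ends))
        seg = AbnormalSegment(i=150, j=180, mean_rr=350.0)
        ks = []
        for threshold in (0.9, 0.6, 0.3, 0.1):
            flags = (probs >= threshold).astype(int)
            result = DetectionResult(
                flags=pd.DataFrame({"end_index": ends, "prob": probs, "flag": flags}),
                window=W,
            )
            det = latency_k(result, seg)
            ks.append(det.k if det.detected else np.inf)
        assert all(a >= b for a, b in zip(ks, ks[1:]))


class TestEvaluateLatencyExperiment:
    def test_six_segments_tabulated(self, tiny_detector):
        model = tiny_detector["model"]
        seq = generate_rr_sequence(400, seed=3)
        specs = [(350.0, 10), (315.0, 8), (450.0, 12), (350.0, 9), (299.5, 11), (502.0, 10)]
        seq = insert_abnormal_segments(seq, specs, min_start=W, seed=4)
        table, summary = evaluate_latency_experiment(model, seq, max_k=10)
        assert len(table) == 6
        assert summary["n_segments"] == 6
        assert set(table["result"]).issubset({"success", "failure", "not_detected"})

    def test_max_k_zero_means_all_failures(self, tiny_detector):
        model = tiny_detector["model"]
        seq = _sequence_with_segment(300, 150, 170)
        table, summary = evaluate_latency_experiment(model, seq, max_k=0)
        assert (table["result"] != "success").all()

    def test_never_flagging_detector_reports_not_detected(self, tiny_detector):
        model = tiny_detector["model"]
        seq = _sequence_with_segment(300, 150, 170)
        table, summary = evaluate_latency_experiment(model, seq, threshold=2.0)
        assert (table["result"] == "not_detected").all()
        assert summary["max_k"] is None

    def test_no_segments_rejected(self, tiny_detector):
        with pytest.raises(InvalidConfigError):
            evaluate_latency_experiment(tiny_detector["model"], generate_rr_sequence(300, seed=0))

    def test_severity_ordering_on_average(self, tiny_detector):
        # more extreme (lower mean RR) segments are caught no later, on average
        model = tiny_detector["model"]
        ks = {300.0: [], 700.0: []}
        for seed in range(3):
            seq = generate_rr_sequence(400, seed=10 + seed)
            seq = insert_abnormal_segments(
                seq, [(300.0, 10), (700.0, 10)], min_start=W, seed=20 + seed
            )
            result = sliding_window_detect(model, seq)
            for seg in seq.segments:
                det = latency_k(result, seg)
                ks[seg.mean_rr].append(det.k if det.detected else 400)
        assert np.mean(ks[300.0]) <= np.mean(ks[700.0])


class TestDetectorCheckpoint:
    def test_roundtrip(self, tiny_detector, tmp_path):
        model = tiny_detector["model"]
        path = tmp_path / "detector.json"
        model.save(path)
        loaded = DetectorModel.load(path)
        x, _y = _separable_corpus(n_per_class=4)
        np.testing.assert_allclose(loaded.predict_proba(x), model.predict_proba(x))
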