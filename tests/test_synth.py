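import numpy as np
import pandas as pd
import pytest

from radarvitals import (
    AbnormalSegment,
    RRSequence,
    calibrate_dependence,
    generate_correction_dataset,
    generate_rr_sequence,
    insert_abnormal_segments,
    kendall_tau_b,
    label_windows,
)
from radarvitals.exceptions import (
    CalibrationError,
    InsufficientDataError,
    InvalidConfigError,
    PlacementError,
)
from radarvitals.synth import DEFAULT_TARGET_TAU, FACTOR_NAMES

TABLE_SEGMENT_MEANS = [350.0, 315.0, 450.0, 350.0, 299.5, 502.0]


def _abs_error(df: pd.DataFrame) -> np.ndarray:
    return np.abs(df["radar_hr"].to_numpy() - df["oximeter_hr"].to_numpy())


class TestCalibrateDependence:
    def test_all_zero_targets_give_zero_weights(self):
        cal = calibrate_dependence(
            target_tau={f: 0.0 for f in FACTOR_NAMES}, n_pilot=2000, seed=0
        )
        assert all(w == 0.0 for w in cal.loading_weights.values())
        df = generate_correction_dataset(10_400, cal, seed=1)
        err = _abs_error(df)
        for f in ("weight", "motion_status"):
            assert abs(kendall_tau_b(df[f].to_numpy(), err)) < 0.02

    def test_single_factor_hits_target(self):
        cal = calibrate_dependence(target_tau={"weight": -0.274}, n_pilot=10_400, seed=2)
        df = generate_correction_dataset(10_400, cal, seed=3)
        tau = kendall_tau_b(df["weight"].to_numpy(), _abs_error(df))
        assert abs(tau - (-0.274)) < 0.02

    def test_gaussian_copula_closed_form_for_continuous_factors(self, default_calibration):
        # for untied continuous factors tau = (2/pi) arcsin(rho) exactly
        for f in ("height", "weight", "distance"):
            rho = default_calibration.rho[f]
            closed_form = (2.0 / np.pi) * np.arcsin(rho)
            assert abs(closed_form - DEFAULT_TARGET_TAU[f]) < 0.03

    def test_sign_invariant(self, default_calibration):
        for f, t in DEFAULT_TARGET_TAU.items():
            assert np.sign(default_calibration.loading_weights[f]) == np.sign(t)

    def test_unreachable_target_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_dependence(target_tau={"weight": 1.0}, n_pilot=500, seed=0)


class TestGenerateCorrectionDataset:
    def test_degenerate_constant_bias(self):
        cal = calibrate_dependence(
            target_tau={f: 0.0 for f in FACTOR_NAMES},
            n_pilot=100,
            seed=0,
            residual_sd=0.0,
        )
        df = generate_correction_dataset(200, cal, seed=4)
        err = df["radar_hr"] - df["oximeter_hr"]
        np.testing.assert_allclose(err, err.iloc[0], rtol=1e-12)
        assert err.iloc[0] == pytest.approx(21.5, abs=1e-6)

    def test_mean_absolute_error_anchor(self, default_calibration):
        df = generate_correction_dataset(10_400, default_calibration, seed=5)
        assert _abs_error(df).mean() == pytest.approx(21.5, abs=2.0)

    def test_determinism(self, default_calibration):
        a = generate_correction_dataset(500, default_calibration, seed=6)
        b = generate_correction_dataset(500, default_calibration, seed=6)
        pd.testing.assert_frame_equal(a, b)

    def test_tau_signs_match_targets(self, small_records):
        err = _abs_error(small_records)
        for f, t in DEFAULT_TARGET_TAU.items():
            tau = kendall_tau_b(small_records[f].to_numpy(), err)
            assert np.sign(tau) == np.sign(t), f

    def test_physiological_ranges(self, small_records):
        assert small_records["radar_hr"].between(30, 220).all()
        assert small_records["oximeter_hr"].between(30, 220).all()
        assert (small_records["weight"] > 0).all()
        assert (small_records["distance"] > 0).all()
        assert set(small_records["direction"].unique()) <= set(range(6))
        assert set(small_records["angle"].unique()) <= {0.0, 35.0, 45.0, 90.0, 180.0}
        assert set(small_records["motion_status"].unique()) <= set(range(4))

    def test_identifiability_nearest_neighbor(self, small_records):
        # the 9 features determine the true HR up to ~residual_sd noise
        from sklearn.neighbors import KNeighborsRegressor

        df = small_records
        feats = list(FACTOR_NAMES) + ["radar_hr"]
        x = (df[feats] - df[feats].mean()) / df[feats].std()
        y = df["oximeter_hr"].to_numpy()
        half = len(df) // 2
        knn = KNeighborsRegressor(n_neighbors=10).fit(x[:half], y[:half])
        pred = knn.predict(x[half:])
        knn_mae = np.mean(np.abs(pred - y[half:]))
        measured_mae = _abs_error(df[half:]).mean()
        assert knn_mae < 5.0  # ~ residual_sd plus approximation error
        assert knn_mae < 0.25 * measured_mae


class TestGenerateRRSequence:
    def test_degenerate_constant(self):
        seq = generate_rr_sequence(100, normal_mean=900.0, normal_sd=0.0, seed=0)
        assert np.all(seq.intervals == 900.0)

    def test_mean_within_clt_bound(self):
        seq = generate_rr_sequence(1600, normal_mean=900.0, normal_sd=40.0, seed=7)
        assert abs(seq.intervals.mean() - 900.0) < 3.0 * 40.0 / np.sqrt(1600)

    def test_determinism(self):
        a = generate_rr_sequence(500, seed=8)
        b = generate_rr_sequence(500, seed=8)
        np.testing.assert_array_equal(a.intervals, b.intervals)

    def test_nonpositive_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            seq = generate_rr_sequence(2000, normal_mean=5.0, normal_sd=40.0, seed=9)
        assert np.all(seq.intervals > 0)

    def test_hrv_drift_present(self):
        seq = generate_rr_sequence(2000, seed=10)
        x = seq.intervals - seq.intervals.mean()
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert lag1 > 0.05  # slow wander induces positive autocorrelation


class TestInsertAbnormalSegments:
    def test_empty_specs_is_noop(self):
        seq = generate_rr_sequence(1600, seed=0)
        out = insert_abnormal_segments(seq, [], seed=1)
        np.testing.assert_array_equal(out.intervals, seq.intervals)
        assert out.segments == []

    def test_six_reference_segments(self):
        seq = generate_rr_sequence(1600, seed=0)
        specs = [(m, 40) for m in TABLE_SEGMENT_MEANS]
        out = insert_abnormal_segments(seq, specs, seed=2)
        assert len(out.segments) == 6
        ordered = sorted(out.segments, key=lambda s: s.i)
        for seg in ordered:
            assert seg.i >= 1024
            assert seg.j > seg.i
            assert seg.j <= 1600
        for a, b in zip(ordered, ordered[1:]):
            assert b.i > a.j + 1  # at least one normal separator

    def test_segment_mean_recomputed_from_sequence(self):
        seq = generate_rr_sequence(1600, seed=0)
        out = insert_abnormal_segments(seq, [(299.5, 50)], seed=3)
        seg = out.segments[0]
        stretch = out.intervals[seg.i - 1 : seg.j]
        assert stretch.mean() == pytest.approx(299.5, abs=10.0)

    def test_infeasible_packing_rejected(self):
        seq = generate_rr_sequence(1100, seed=0)
        with pytest.raises(PlacementError):
            insert_abnormal_segments(seq, [(350.0, 60), (315.0, 60)], seed=0)

    def test_input_not_mutated(self):
        seq = generate_rr_sequence(1600, seed=0)
        original = seq.intervals.copy()
        insert_abnormal_segments(seq, [(350.0, 30)], seed=4)
        np.testing.assert_array_equal(seq.intervals, original)

    def test_invalid_specs_rejected(self):
        seq = generate_rr_sequence(1600, seed=0)
        with pytest.raises(InvalidConfigError):
            insert_abnormal_segments(seq, [(-5.0, 30)])
        with pytest.raises(InvalidConfigError):
            insert_abnormal_segments(seq, [(350.0, 1)])


class TestLabelWindows:
    def test_minimal_window(self):
        seq = generate_rr_sequence(1024, seed=0)
        labels = label_windows(seq)
        assert len(labels) == 1
        assert labels["label"].iloc[0] == 0

    def test_row_count_1600(self):
        seq = generate_rr_sequence(1600, seed=0)
        labels = label_windows(seq)
        assert len(labels) == 577  # n - window + 1

    def test_segment_rows_flagged(self):
        seq = generate_rr_sequence(1600, seed=0)
        seq.segments.append(AbnormalSegment(i=1100, j=1150, mean_rr=350.0))
        labels = label_windows(seq).set_index("end_index")["label"]
        assert (labels.loc[1100:1150] == 1).all()
        assert labels.loc[labels.index.difference(range(1100, 1151))].eq(0).all()

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            label_windows(generate_rr_sequence(100, seed=0))


class TestDomainTypes:
    def test_segment_invariants(self):
        with pytest.raises(InvalidConfigError):
            AbnormalSegment(i=100, j=100, mean_rr=300.0)
        with pytest.raises(InvalidConfigError):
            AbnormalSegment(i=1024, j=1060, mean_rr=-1.0)

    def test_rr_sequence_invariants(self):
        with pytest.raises(InvalidConfigError):
            RRSequence(intervals=np.array([900.0, -5.0]))
        with pytest.raises(InvalidConfigError):
            RRSequence(intervals=np.array([]))
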