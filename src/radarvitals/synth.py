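"""Calibrated synthetic data: correction records and RR-interval sequences.

Two generators live here.

**Correction records.** Each record couples eight measurement-condition
factors (direction, angle, gender, height, weight, age, distance, motion
status) with a reference heart rate and a radar-measured heart rate whose
absolute error depends monotonically on the factors.  The dependence is a
latent Gaussian one-factor-per-variable construction: independent standard
normals ``Z_f`` drive the factors through monotone quantile transforms, and
the signed error is a strictly monotone (softplus) transform of

    S = sum_f rho_f * Z_f + sqrt(1 - sum_f rho_f^2) * Z_resid

so that the Kendall tau-b between a factor and the absolute error is fully
determined by its latent correlation ``rho_f``.  ``calibrate_dependence``
solves each ``rho_f`` by root finding on a pilot simulation so the generated
tau-b values match requested targets.  Because tau is invariant under
strictly monotone transforms, the calibration never needs to know the final
error scale.

**RR sequences.** Normal sequences are white noise around a configurable
mean with a slow AR(1) drift emulating heart-rate variability; abnormal
(tachyarrhythmia-like) segments of prescribed mean RR are spliced in at
random non-overlapping positions at or beyond a minimum start index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.signal import lfilter

from .exceptions import (
    CalibrationError,
    InsufficientDataError,
    InvalidConfigError,
    PlacementError,
)
from .metrics import kendall_tau_b

# ---------------------------------------------------------------------------
# correction records
# ---------------------------------------------------------------------------

FACTOR_NAMES = (
    "direction",
    "angle",
    "gender",
    "height",
    "weight",
    "age",
    "distance",
    "motion_status",
)

#: Kendall tau-b targets between each factor and the absolute heart-rate
#: error.  Negative: error shrinks as the factor grows.
DEFAULT_TARGET_TAU: Dict[str, float] = {
    "distance": -0.102,
    "angle": 0.112,
    "direction": 0.187,
    "weight": -0.274,
    "gender": -0.043,
    "height": -0.043,
    "age": -0.106,
    "motion_status": 0.219,
}

ANGLE_VALUES = np.array([0.0, 35.0, 45.0, 90.0, 180.0])
N_DIRECTIONS = 6  # front, upper-right, upper-left, right-side, left-side, back
N_MOTION_STATUSES = 4


def _phi(z: np.ndarray) -> np.ndarray:
    """Standard normal CDF."""
    return special.ndtr(z)


def _factor_from_latent(name: str, z: np.ndarray) -> np.ndarray:
    """Monotone quantile transform from a standard normal latent to a factor.

    Every transform is nondecreasing in ``z`` so the sign of the latent
    correlation carries through to the tau-b sign.
    """
    u = _phi(z)
    if name == "direction":
        return np.minimum((u * N_DIRECTIONS).astype(int), N_DIRECTIONS - 1).astype(float)
    if name == "angle":
        idx = np.minimum((u * len(ANGLE_VALUES)).astype(int), len(ANGLE_VALUES) - 1)
        return ANGLE_VALUES[idx]
    if name == "gender":
        return (z > 0).astype(float)
    if name == "height":
        return 170.0 + 8.0 * z
    if name == "weight":
        return 65.0 + 12.0 * z
    if name == "age":
        return np.minimum(18 + (u * 48).astype(int), 65).astype(float)
    if name == "distance":
        return 0.5 + 2.5 * u
    if name == "motion_status":
        return np.minimum((u * N_MOTION_STATUSES).astype(int), N_MOTION_STATUSES - 1).astype(
            float
        )
    raise InvalidConfigError(f"unknown factor {name!r}")


@dataclass
class DependenceCalibration:
    """Calibrated latent-model parameters for the correction-record generator.

    ``rho`` holds the latent correlation solved per factor; ``loading_weights``
    is the same information on the output (BPM) scale, ``rho * sigma_total``.
    ``sigma_total`` and ``shift`` parameterize the softplus error transform
    ``error = softplus(shift + sigma_total * S)`` with ``S`` standard normal.
    """

    target_tau: Dict[str, float]
    rho: Dict[str, float]
    residual_sd: float
    mean_abs_error: float
    sigma_total: float
    shift: float

    @property
    def loading_weights(self) -> Dict[str, float]:
        return {f: r * self.sigma_total for f, r in self.rho.items()}

    @property
    def residual_rho(self) -> float:
        """Latent weight of the unobservable residual component."""
        return float(np.sqrt(max(0.0, 1.0 - sum(r * r for r in self.rho.values()))))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _solve_error_shift(sigma: float, mean_abs_error: float) -> float:
    """Shift b with E[softplus(b + sigma*Z)] = mean_abs_error, Z ~ N(0,1)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / np.sqrt(2.0 * np.pi)

    def expected(b: float) -> float:
        return float(np.sum(weights * _softplus(b + sigma * nodes))) - mean_abs_error

    lo, hi = -1000.0, 1000.0
    return float(optimize.brentq(expected, lo, hi, xtol=1e-10))


def _pilot_tau(name: str, rho: float, z_factor: np.ndarray, z_other: np.ndarray) -> float:
    """Tau-b between a factor and the latent error score at correlation rho."""
    s = rho * z_factor + np.sqrt(max(0.0, 1.0 - rho * rho)) * z_other
    return kendall_tau_b(_factor_from_latent(name, z_factor), s)


def calibrate_dependence(
    target_tau: Optional[Dict[str, float]] = None,
    n_pilot: int = 60_000,
    seed: int = 0,
    residual_sd: float = 1.5,
    mean_abs_error: float = 21.5,
    tol: float = 0.02,
) -> DependenceCalibration:
    """Solve per-factor latent correlations matching tau-b targets.

    For each factor an independent pilot sample of latent pairs is drawn and
    the latent correlation ``rho`` is solved by Brent root finding so the
    simulated tau-b hits the target.  Because factors are mutually
    independent in the latent model, the per-factor problems decouple: the
    tau between factor f and the error depends on ``rho_f`` only.

    Raises
    ------
    CalibrationError
        If a target is unreachable, the solved ``rho`` disagrees in sign with
        its target beyond tolerance, or ``sum rho^2 >= 1``.
    """
    if target_tau is None:
        target_tau = dict(DEFAULT_TARGET_TAU)
    for f, t in target_tau.items():
        if not abs(t) < 1:
            raise CalibrationError(f"target tau for {f!r} must satisfy |tau| < 1")
        if f not in FACTOR_NAMES:
            raise InvalidConfigError(f"unknown factor {f!r}")
    if residual_sd < 0:
        raise InvalidConfigError("residual_sd must be nonnegative")

    ss = np.random.SeedSequence(seed)
    rho: Dict[str, float] = {}
    for f, child in zip(FACTOR_NAMES, ss.spawn(len(FACTOR_NAMES))):
        target = target_tau.get(f, 0.0)
        if target == 0.0:
            rho[f] = 0.0
            continue
        rng = np.random.default_rng(child)
        z_factor = rng.standard_normal(n_pilot)
        z_other = rng.standard_normal(n_pilot)

        def objective(r: float, f=f, z1=z_factor, z2=z_other, t=target) -> float:
            return _pilot_tau(f, r, z1, z2) - t

        lo, hi = -0.999, 0.999
        try:
            solved = float(optimize.brentq(objective, lo, hi, xtol=1e-4))
        except ValueError as exc:  # pragma: no cover - unreachable targets
            raise CalibrationError(f"cannot reach tau target for {f!r}") from exc
        achieved = _pilot_tau(f, solved, z_factor, z_other)
        if abs(achieved - target) > tol:
            raise CalibrationError(
                f"calibration for {f!r} off target: {achieved:.4f} vs {target:.4f}"
            )
        rho[f] = solved

    sq = sum(r * r for r in rho.values())
    if sq >= 1.0:
        raise CalibrationError(f"latent correlations overdetermined: sum rho^2 = {sq:.3f}")
    for f in rho:
        t = target_tau.get(f, 0.0)
        if t != 0.0 and np.sign(rho[f]) != np.sign(t):
            raise CalibrationError(f"solved rho sign disagrees with target for {f!r}")

    # residual_sd is the BPM-scale spread of the unpredictable part; the
    # latent residual weight sqrt(1 - sum rho^2) times sigma_total equals it.
    if residual_sd == 0.0 and sq == 0.0:
        sigma_total = 0.0
    else:
        sigma_total = residual_sd / np.sqrt(1.0 - sq)
    shift = _solve_error_shift(sigma_total, mean_abs_error)
    return DependenceCalibration(
        target_tau=dict(target_tau),
        rho=rho,
        residual_sd=residual_sd,
        mean_abs_error=mean_abs_error,
        sigma_total=float(sigma_total),
        shift=shift,
    )


def generate_correction_dataset(
    n: int, calibration: DependenceCalibration, seed: int = 0
) -> pd.DataFrame:
    """Generate ``n`` correction records under a calibrated dependence model.

    Columns: the eight factors, ``radar_hr`` and ``oximeter_hr``.  The
    reference (oximeter) heart rate is drawn from N(75, 10) clipped to
    [50, 120]; the radar heart rate adds a positive error that is a monotone
    function of the latent factor score plus residual noise.
    """
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, len(FACTOR_NAMES)))
    z_resid = rng.standard_normal(n)
    oximeter = np.clip(rng.normal(75.0, 10.0, size=n), 50.0, 120.0)

    data = {}
    score = np.zeros(n)
    for k, f in enumerate(FACTOR_NAMES):
        data[f] = _factor_from_latent(f, z[:, k])
        score += calibration.rho.get(f, 0.0) * z[:, k]
    score += calibration.residual_rho * z_resid

    error = _softplus(calibration.shift + calibration.sigma_total * score)
    radar = oximeter + error
    if np.any(radar > 220.0) or np.any(radar < 30.0):
        warnings.warn("clipping radar heart rates to the physiological range [30, 220]")
        radar = np.clip(radar, 30.0, 220.0)

    data["radar_hr"] = radar
    data["oximeter_hr"] = oximeter
    cols = list(FACTOR_NAMES) + ["radar_hr", "oximeter_hr"]
    return pd.DataFrame(data, columns=cols)


# ---------------------------------------------------------------------------
# RR-interval sequences
# ---------------------------------------------------------------------------

#: Minimum start index for an abnormal segment (detector window length).
MIN_SEGMENT_START = 1024


@dataclass(frozen=True)
class AbnormalSegment:
    """One annotated abnormal stretch, 1-based inclusive indices [i, j]."""

    i: int
    j: int
    mean_rr: float

    def __post_init__(self) -> None:
        if not (self.j > self.i >= 1):
            raise InvalidConfigError(f"segment must satisfy j > i >= 1, got ({self.i}, {self.j})")
        if self.mean_rr <= 0:
            raise InvalidConfigError("segment mean RR must be positive")

    def contains(self, index: int) -> bool:
        return self.i <= index <= self.j


@dataclass
class RRSequence:
    """Ordered RR intervals (ms) with optional abnormal-segment annotations."""

    intervals: np.ndarray
    segments: List[AbnormalSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1 or self.intervals.size < 1:
            raise InvalidConfigError("intervals must be a nonempty 1-D array")
        if np.any(self.intervals <= 0):
            raise InvalidConfigError("all RR intervals must be positive")

    def __len__(self) -> int:
        return len(self.intervals)

    def is_abnormal(self, index: int) -> bool:
        """Whether the 1-based interval ``index`` lies inside any segment."""
        return any(seg.contains(index) for seg in self.segments)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.intervals)
        flags = np.zeros(n, dtype=int)
        for seg in self.segments:
            flags[seg.i - 1 : seg.j] = 1
        return pd.DataFrame(
            {"index": np.arange(1, n + 1), "rr_ms": self.intervals, "is_abnormal": flags}
        )


def generate_rr_sequence(
    n: int,
    normal_mean: float = 900.0,
    normal_sd: float = 40.0,
    seed: int = 0,
    drift_coef: float = 0.9,
) -> RRSequence:
    """Normal (healthy) RR-interval sequence with slow autocorrelated drift.

    intervals = normal_mean + AR(1) drift + white noise.  The AR(1) drift
    has coefficient ``drift_coef`` and innovation sd ``normal_sd / 8``, giving
    tens-of-milliseconds slow wander typical of heart-rate variability.  With
    ``normal_sd = 0`` the sequence is exactly constant.
    """
    if n < 1:
        raise InvalidConfigError("n must be >= 1")
    if normal_mean <= 0:
        raise InvalidConfigError("normal_mean must be positive")
    if normal_sd < 0:
        raise InvalidConfigError("normal_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    white = rng.normal(0.0, normal_sd, size=n) if normal_sd > 0 else np.zeros(n)
    innov_sd = normal_sd / 8.0
    if innov_sd > 0:
        innovations = rng.normal(0.0, innov_sd, size=n)
        drift = lfilter([1.0], [1.0, -drift_coef], innovations)
    else:
        drift = np.zeros(n)
    intervals = normal_mean + drift + white
    if np.any(intervals <= 0):
        warnings.warn("clipping nonpositive RR intervals to 1 ms")
        intervals = np.maximum(intervals, 1.0)
    return RRSequence(intervals=intervals, segments=[])


def insert_abnormal_segments(
    seq: RRSequence,
    specs: Sequence[Tuple[float, int]],
    min_start: int = MIN_SEGMENT_START,
    seed: int = 0,
    jitter_sd: float = 10.0,
) -> RRSequence:
    """Splice abnormal segments into a copy of ``seq``.

    ``specs`` is a list of ``(mean_rr_ms, length_intervals)`` pairs.  Segments
    are placed left to right in the given order at random non-overlapping
    positions with 1-based start indices >= ``min_start`` and at least one
    untouched normal interval between consecutive segments.  Each spliced
    stretch is Gaussian jitter recentred to have sample mean exactly
    ``mean_rr_ms``.
    """
    if not specs:
        return RRSequence(intervals=seq.intervals.copy(), segments=list(seq.segments))
    n = len(seq)
    m = len(specs)
    lengths = []
    for mean_rr, length in specs:
        if mean_rr <= 0:
            raise InvalidConfigError("segment mean RR must be positive")
        if length < 2:
            raise InvalidConfigError("segment length must be >= 2 (j > i)")
        lengths.append(int(length))
    if min_start < 1:
        raise InvalidConfigError("min_start must be >= 1")
    capacity = n - min_start + 1
    required = sum(lengths) + (m - 1)
    if required > capacity:
        raise PlacementError(
            f"cannot place {m} segments totalling {sum(lengths)} intervals "
            f"(+{m - 1} separators) into {capacity} available positions"
        )
    rng = np.random.default_rng(seed)
    slack = capacity - required
    gaps = rng.multinomial(slack, [1.0 / (m + 1)] * (m + 1))

    intervals = seq.intervals.copy()
    segments = list(seq.segments)
    pos = min_start + int(gaps[0])
    for k, ((mean_rr, _), length) in enumerate(zip(specs, lengths)):
        i, j = pos, pos + length - 1
        values = rng.normal(mean_rr, jitter_sd, size=length)
        values = values - values.mean() + mean_rr  # exact sample mean
        values = np.maximum(values, 1.0)
        intervals[i - 1 : j] = values
        segments.append(AbnormalSegment(i=i, j=j, mean_rr=float(mean_rr)))
        pos = j + 2 + int(gaps[k + 1])  # one mandatory normal separator
    return RRSequence(intervals=intervals, segments=segments)


def label_windows(seq: RRSequence, window: int = 1024) -> pd.DataFrame:
    """Label every sliding window by its last interval.

    One row per window end index ``e`` in ``[window, n]`` with ``label`` 1
    iff interval ``x_e`` lies inside an annotated abnormal segment.
    """
    n = len(seq)
    if n < window:
        raise InsufficientDataError(f"sequence of {n} intervals shorter than window {window}")
    ends = np.arange(window, n + 1)
    flags = np.zeros(n, dtype=int)
    for seg in seq.segments:
        flags[seg.i - 1 : seg.j] = 1
    return pd.DataFrame({"end_index": ends, "label": flags[ends - 1]})
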