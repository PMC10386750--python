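"""Vitals extraction from a slow-time phase series.

Recovers respiration rate and heart rate by band-restricted spectral peak
picking, computes a band-limited motion energy (max spectral modulus times
band width), classifies one of four motion statuses against three energy
thresholds, and converts an echo delay into a target distance R = c*tD/2.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import detrend as _detrend
from scipy.signal.windows import hann

from .exceptions import InsufficientDataError, InvalidConfigError
from .signal_sim import (
    SPEED_OF_LIGHT,
    ChestMotionModel,
    PhaseSeries,
    RadarConfig,
    synthesize_phase_series,
)

RESPIRATION_BAND = (0.1, 0.3)
HEART_BAND = (1.0, 2.0)
#: Band of interest for motion energy (Hz); covers body motion and vitals.
MOTION_BAND = (0.05, 4.0)


class MotionStatus(enum.IntEnum):
    """Four-level ordinal motion status."""

    STILLNESS = 0
    RELATIVE_STILLNESS = 1
    MOTION = 2
    CONTINUOUS_MOTION = 3


@dataclass(frozen=True)
class MotionEnergyConfig:
    """Band of interest plus the three increasing energy thresholds."""

    band_of_interest: Tuple[float, float] = MOTION_BAND
    thresholds: Tuple[float, float, float] = (1.0, 2.0, 4.0)

    def __post_init__(self) -> None:
        low, high = self.band_of_interest
        if not (0 <= low < high):
            raise InvalidConfigError("band must satisfy 0 <= low < high")
        e1, e2, e3 = self.thresholds
        if not (0 <= e1 < e2 < e3):
            raise InvalidConfigError("thresholds must satisfy 0 <= e1 < e2 < e3")


@dataclass
class VitalsEstimate:
    """Vitals recovered from one phase series."""

    respiration_rate: float  # breaths/min
    heart_rate: float  # BPM
    motion_energy: float
    motion_status: MotionStatus
    distance: Optional[float] = None  # m

    def to_json(self) -> str:
        return json.dumps(
            {
                "respiration_rate_bpm": self.respiration_rate,
                "heart_rate_bpm": self.heart_rate,
                "motion_energy": self.motion_energy,
                "motion_status": int(self.motion_status),
                "motion_status_name": self.motion_status.name.lower(),
                "distance_m": self.distance,
            },
            indent=2,
        )


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def _band_peak_frequency(series: PhaseSeries, band: Tuple[float, float]) -> float:
    """Peak frequency (Hz) of the windowed magnitude spectrum inside ``band``.

    Detrended, Hann-windowed, zero-padded to the next power of two; ties
    broken toward the lower frequency (first argmax).
    """
    n = len(series)
    x = _detrend(series.values, type="linear")
    x = x * hann(n, sym=False)
    nfft = _next_pow2(n)
    spectrum = np.abs(np.fft.rfft(x, nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / series.fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mask):
        raise InvalidConfigError(f"band {band} contains no spectral bins")
    idx = np.flatnonzero(mask)
    peak = idx[np.argmax(spectrum[idx])]
    return float(freqs[peak])


def estimate_rates(
    series: PhaseSeries,
    respiration_band: Tuple[float, float] = RESPIRATION_BAND,
    heart_band: Tuple[float, float] = HEART_BAND,
) -> Tuple[float, float]:
    """Respiration rate (breaths/min) and heart rate (BPM) from phase.

    Each rate is 60x the band-restricted spectral peak frequency. The series
    must be long enough to resolve each band: ``len >= 2*fs/band_width``.
    """
    for band in (respiration_band, heart_band):
        low, high = band
        if not (0 <= low < high):
            raise InvalidConfigError(f"invalid band {band}")
        min_len = 2.0 * series.fs / (high - low)
        if len(series) < min_len:
            raise InsufficientDataError(
                f"series of {len(series)} samples too short to resolve band "
                f"{band}; need at least {int(np.ceil(min_len))}"
            )
    resp_hz = _band_peak_frequency(series, respiration_band)
    heart_hz = _band_peak_frequency(series, heart_band)
    return 60.0 * resp_hz, 60.0 * heart_hz


def motion_energy(series: PhaseSeries, config: MotionEnergyConfig) -> float:
    """Band-limited motion energy of a phase series.

    FFT of the mean-removed series (no window, no padding, so the value is
    exactly reproducible by a direct DFT); the maximum modulus inside the
    band of interest is multiplied by the band width in Hz.  Linear in the
    signal amplitude.
    """
    n = len(series)
    if n == 0:
        raise InsufficientDataError("empty series")
    low, high = config.band_of_interest
    x = series.values - np.mean(series.values)
    spectrum = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, d=1.0 / series.fs)
    mask = (freqs >= low) & (freqs <= high)
    if not np.any(mask):
        raise InvalidConfigError(
            f"band {config.band_of_interest} contains no spectral bins at "
            f"fs={series.fs}, n={n}"
        )
    return float(np.max(spectrum[mask]) * (high - low))


def classify_motion_status(energy: float, config: MotionEnergyConfig) -> MotionStatus:
    """Map an energy value to one of four motion statuses.

    Boundaries are half-open with the threshold itself belonging to the
    higher-motion class: energy < e1 -> stillness; e1 <= energy < e2 ->
    relative stillness; e2 <= energy < e3 -> motion; energy >= e3 ->
    continuous motion.
    """
    if energy < 0:
        raise InvalidConfigError("energy must be nonnegative")
    e1, e2, e3 = config.thresholds
    if energy < e1:
        return MotionStatus.STILLNESS
    if energy < e2:
        return MotionStatus.RELATIVE_STILLNESS
    if energy < e3:
        return MotionStatus.MOTION
    return MotionStatus.CONTINUOUS_MOTION


def delay_to_distance(t_delay: float) -> float:
    """Target distance R = c*tD/2 from a round-trip delay tD (s)."""
    if t_delay < 0:
        raise InvalidConfigError(f"delay must be nonnegative, got {t_delay}")
    return 0.5 * SPEED_OF_LIGHT * t_delay


def calibrate_thresholds(
    n_trials: int = 200,
    seed: int = 0,
    band: Tuple[float, float] = MOTION_BAND,
) -> MotionEnergyConfig:
    """Derive default motion-energy thresholds from still-subject simulations.

    e1 is the 95th percentile of the energy distribution of simulated still
    subjects with physiological parameters drawn from their typical ranges;
    e2 = 2*e1, e3 = 4*e1.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_trials)
    energies = np.empty(n_trials)
    for k in range(n_trials):
        model = ChestMotionModel(
            d0=rng.uniform(0.5, 2.0),
            mb=rng.uniform(4e-3, 12e-3),
            mh=rng.uniform(0.2e-3, 0.5e-3),
            fb=rng.uniform(0.1, 0.3),
            fh=rng.uniform(1.0, 2.0),
        )
        config = RadarConfig(noise_sd=0.02, duration=30.0)
        series = synthesize_phase_series(model, config, seed=int(seeds[k]))
        energies[k] = motion_energy(
            series, MotionEnergyConfig(band_of_interest=band, thresholds=(1, 2, 4))
        )
    e1 = float(np.percentile(energies, 95))
    return MotionEnergyConfig(band_of_interest=band, thresholds=(e1, 2 * e1, 4 * e1))


def extract_vitals(
    series: PhaseSeries,
    respiration_band: Tuple[float, float] = RESPIRATION_BAND,
    heart_band: Tuple[float, float] = HEART_BAND,
    energy_config: Optional[MotionEnergyConfig] = None,
    t_delay: Optional[float] = None,
) -> VitalsEstimate:
    """One-call extraction of all vitals from a phase series."""
    if energy_config is None:
        energy_config = MotionEnergyConfig()
    resp, heart = estimate_rates(series, respiration_band, heart_band)
    energy = motion_energy(series, energy_config)
    status = classify_motion_status(energy, energy_config)
    distance = delay_to_distance(t_delay) if t_delay is not None else None
    return VitalsEstimate(
        respiration_rate=resp,
        heart_rate=heart,
        motion_energy=energy,
        motion_status=status,
        distance=distance,
    )
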