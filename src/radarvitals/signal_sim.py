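"""Synthetic chest-displacement and slow-time radar phase signals.

The chest surface of a monitored subject oscillates around a baseline
distance ``d0`` with two superimposed sinusoids (respiration and heartbeat):

    d(t) = d0 + mb*sin(2*pi*fb*t) + mh*sin(2*pi*fh*t)

A radar observing that surface sees the displacement as a phase modulation
of its echo, ``theta = 4*pi*x/lambda``, where ``x`` is displacement from the
baseline and ``lambda`` the carrier wavelength.  This module composes the
two relations into a seedable slow-time phase simulator with additive
Gaussian phase noise and an optional gross body-motion transient.

Phase is kept unwrapped (no modulo 2*pi); this is a deliberate simulator
idealization that keeps downstream spectral analysis simple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .exceptions import InvalidConfigError, InvalidModelError, SamplingError

#: Speed of light in vacuum (m/s).
SPEED_OF_LIGHT = 299_792_458.0


@dataclass(frozen=True)
class ChestMotionModel:
    """Two-sinusoid model of chest displacement.

    Parameters
    ----------
    d0 : float
        Baseline chest-radar distance in metres. Must be positive.
    mb, mh : float
        Respiration and heartbeat displacement amplitudes in metres
        (typical: respiration 4-12 mm, heartbeat 0.2-0.5 mm).
    fb, fh : float
        Respiration and heartbeat frequencies in Hz
        (typical: respiration 0.1-0.3 Hz, heartbeat 1-2 Hz).
    """

    d0: float = 0.6
    mb: float = 8e-3
    mh: float = 0.35e-3
    fb: float = 0.2
    fh: float = 1.2

    def __post_init__(self) -> None:
        params = (self.d0, self.mb, self.mh, self.fb, self.fh)
        if not all(math.isfinite(p) for p in params):
            raise InvalidModelError("all chest-motion parameters must be finite")
        if self.d0 <= 0:
            raise InvalidModelError(f"baseline distance d0 must be > 0, got {self.d0}")
        if self.mb < 0 or self.mh < 0:
            raise InvalidModelError("displacement amplitudes must be nonnegative")
        if self.fb <= 0 or self.fh <= 0:
            raise InvalidModelError("respiration/heartbeat frequencies must be > 0")


@dataclass(frozen=True)
class RadarConfig:
    """Radar and slow-time sampling configuration.

    ``motion_transient`` is an optional ``(start_s, duration_s, amplitude_m)``
    triple describing a raised-cosine gross body-motion displacement pulse
    added to the chest displacement.
    """

    carrier_frequency: float = 7.3e9
    sampling_rate: float = 20.0
    duration: float = 60.0
    noise_sd: float = 0.0
    motion_transient: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if not (6e9 <= self.carrier_frequency <= 10e9):
            # the hardware band is 6.5-8.1 GHz; allow a little slack
            if self.carrier_frequency <= 0:
                raise InvalidConfigError("carrier frequency must be positive")
        if self.sampling_rate <= 0:
            raise InvalidConfigError("sampling rate must be positive")
        if self.duration <= 0:
            raise InvalidConfigError("duration must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be nonnegative")
        if self.motion_transient is not None:
            start, dur, _amp = self.motion_transient
            if dur <= 0 or start < 0:
                raise InvalidConfigError("transient must have start >= 0 and duration > 0")

    @property
    def wavelength(self) -> float:
        """Carrier wavelength lambda = c / f (m)."""
        return SPEED_OF_LIGHT / self.carrier_frequency

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class PhaseSeries:
    """Uniformly sampled slow-time phase series (radians)."""

    values: np.ndarray
    fs: float
    wavelength: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise InvalidModelError("phase series must be finite")
        if self.fs <= 0:
            raise InvalidConfigError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.fs


def chest_displacement(model: ChestMotionModel, times) -> np.ndarray:
    """Evaluate the two-sinusoid chest displacement d(t) at ``times`` (s).

    Returns absolute chest-radar distance in metres:
    ``d0 + mb*sin(2 pi fb t) + mh*sin(2 pi fh t)``.
    """
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidModelError("times must be finite")
    return (
        model.d0
        + model.mb * np.sin(2.0 * np.pi * model.fb * t)
        + model.mh * np.sin(2.0 * np.pi * model.fh * t)
    )


def phase_modulation(displacement_from_baseline, wavelength: float) -> np.ndarray:
    """Phase modulation theta = 4*pi*x/lambda (radians), elementwise.

    ``displacement_from_baseline`` is in metres, ``wavelength`` in metres.
    """
    if not (wavelength > 0):
        raise InvalidConfigError(f"wavelength must be > 0, got {wavelength}")
    x = np.asarray(displacement_from_baseline, dtype=float)
    return 4.0 * np.pi * x / wavelength


def _transient_displacement(config: RadarConfig, t: np.ndarray) -> np.ndarray:
    """Raised-cosine displacement pulse for the gross-motion transient."""
    start, dur, amp = config.motion_transient
    out = np.zeros_like(t)
    mask = (t >= start) & (t <= start + dur)
    u = (t[mask] - start) / dur
    out[mask] = 0.5 * amp * (1.0 - np.cos(2.0 * np.pi * u))
    return out


def synthesize_phase_series(
    model: ChestMotionModel, config: RadarConfig, seed: int = 0
) -> PhaseSeries:
    """Simulate a slow-time phase series for ``model`` under ``config``.

    phase = 4*pi*(d(t) - d0 + transient(t))/lambda + N(0, noise_sd^2)

    Raises
    ------
    SamplingError
        If the sampling rate violates Nyquist for the model frequencies.
    """
    fmax = max(model.fb, model.fh)
    if config.sampling_rate <= 2.0 * fmax:
        raise SamplingError(
            f"sampling rate {config.sampling_rate} Hz must exceed twice the "
            f"highest model frequency ({fmax} Hz)"
        )
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate
    disp = chest_displacement(model, t) - model.d0
    if config.motion_transient is not None:
        disp = disp + _transient_displacement(config, t)
    phase = phase_modulation(disp, config.wavelength)
    if config.noise_sd > 0:
        rng = np.random.default_rng(seed)
        phase = phase + rng.normal(0.0, config.noise_sd, size=n)
    return PhaseSeries(values=phase, fs=config.sampling_rate, wavelength=config.wavelength)
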