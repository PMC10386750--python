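"""Exception hierarchy shared across the package."""


class RadarVitalsError(Exception):
    """Base class for all package-specific errors."""


class InvalidModelError(RadarVitalsError, ValueError):
    """A physiological motion model has non-finite or out-of-range parameters."""


class InvalidConfigError(RadarVitalsError, ValueError):
    """A configuration object violates one of its invariants."""


class SamplingError(RadarVitalsError, ValueError):
    """Sampling rate incompatible with the signal content (Nyquist violation)."""


class InsufficientDataError(RadarVitalsError, ValueError):
    """Input series too short for the requested analysis."""


class ShapeError(RadarVitalsError, ValueError):
    """Mismatched input lengths or array shapes."""


class ValidationError(RadarVitalsError, ValueError):
    """Tabular input fails schema validation (missing/invalid columns)."""


class CalibrationError(RadarVitalsError, RuntimeError):
    """Dependence calibration failed to converge for at least one factor."""


class PlacementError(RadarVitalsError, ValueError):
    """Abnormal segments cannot be packed into the requested index range."""


class ClassBalanceError(RadarVitalsError, ValueError):
    """Training data does not contain both classes."""


class DivergenceError(RadarVitalsError, RuntimeError):
    """Training produced a non-finite loss."""


class UndefinedStatisticError(RadarVitalsError, ValueError):
    """A statistic is undefined for the given input (e.g. all-tied tau-b)."""


class RangeError(RadarVitalsError, ValueError):
    """Requested indices fall outside the available result range."""
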