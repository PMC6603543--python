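"""Exception hierarchy for the analysis pipeline."""

from __future__ import annotations


class FingertapError(ValueError):
    """Base class for all package-specific errors."""


class ParseError(FingertapError):
    """A signal or model file could not be parsed (names the offending row/column)."""


class NoMotionError(FingertapError):
    """All gyro channels are (numerically) zero: no movement recorded."""


class NoTappingError(FingertapError):
    """No spectral peak above the noise floor in the tapping band."""


class InsufficientTapsError(FingertapError):
    """Too few taps / markers for a meaningful analysis."""


class DegenerateSignalError(FingertapError):
    """Signal degenerate for the requested operation (all-zero, constant, ...)."""


class CalibrationError(FingertapError):
    """Reference feature table unsuitable for calibration."""


class StageError(FingertapError):
    """Pipeline failure, wrapped with the name of the failing stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}': {original}")
        self.stage = stage
        self.original = original
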