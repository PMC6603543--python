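"""Tapping angle, per-tap apertures and the amplitude-decrement index.

The tapping angle is the cumulative trapezoidal integral of the dominant
relative angular velocity.  Gyro bias turns into a slow drift of the
integrated angle; it is removed by fitting a cubic polynomial through the
zero-posture markers (where the true angle is zero) and subtracting the fit.
The aperture of tap *i* is the largest absolute angle inside the tap segment,
and the decrement index ``i_dec`` is the 1-based index of the first tap whose
aperture falls below ``th_alpha`` (default 75 %) of the running maximum of all
preceding apertures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import DegenerateSignalError
from .segmentation import TapMarkers

#: Default decrement threshold: fraction of the previously achieved maximum.
TH_ALPHA = 0.75

#: Tap segments whose peak angle is below this fraction of the overall maximum
#: are treated as flat (no tap) and skipped.
FLAT_SEGMENT_FRACTION = 0.01


@dataclass
class AngleTrace:
    """Drift-corrected angle series with per-tap apertures (degrees)."""

    alpha_t: np.ndarray
    apertures: np.ndarray   # alpha(i), 1-based tap order
    alpha_av: float
    drift_poly_degree: int


@dataclass
class DecrementResult:
    """First significantly decremented tap (sentinel ``n_taps + 1`` if none)."""

    i_dec: int
    th_alpha: float
    flagged: list[int]


def integrate_angle(omega_rd: np.ndarray, fs: float) -> np.ndarray:
    """Cumulative trapezoidal integral of the angular velocity, starting at 0°."""
    omega_rd = np.asarray(omega_rd, dtype=float)
    return cumulative_trapezoid(omega_rd, dx=1.0 / fs, initial=0.0)


def remove_drift(raw_angle: np.ndarray, zero_posture: np.ndarray) -> tuple[np.ndarray, int]:
    """Subtract a cubic fitted through the zero-posture samples of ``raw_angle``.

    With fewer than 4 markers the highest fittable degree is used instead and
    a warning is emitted.  Returns the corrected series and the degree used.
    """
    raw_angle = np.asarray(raw_angle, dtype=float)
    markers = np.asarray(zero_posture, dtype=int)
    if markers.size < 2:
        raise DegenerateSignalError("drift removal needs at least 2 zero-posture markers")
    if np.any(markers < 0) or np.any(markers >= raw_angle.size):
        raise ValueError("zero-posture markers outside the angle series")
    degree = min(3, markers.size - 1)
    if degree < 3:
        warnings.warn(
            f"only {markers.size} markers: falling back to degree-{degree} drift fit",
            stacklevel=2,
        )
    poly = np.polynomial.Polynomial.fit(markers.astype(float), raw_angle[markers], degree)
    return raw_angle - poly(np.arange(raw_angle.size, dtype=float)), degree


def per_tap_apertures(
    alpha_t: np.ndarray,
    markers: TapMarkers,
    flat_fraction: float = FLAT_SEGMENT_FRACTION,
) -> tuple[np.ndarray, float]:
    """Maximal |angle| per tap segment and their mean ``alpha_av`` (degrees).

    Flat segments (peak below ``flat_fraction`` of the overall maximum) are
    skipped with a warning and not counted as taps.
    """
    alpha_t = np.asarray(alpha_t, dtype=float)
    global_max = np.max(np.abs(alpha_t))
    if global_max == 0.0:
        raise DegenerateSignalError("angle series is identically zero")
    apertures = []
    for start, stop in markers.tap_segments:
        amp = float(np.max(np.abs(alpha_t[start : stop + 1])))
        if amp < flat_fraction * global_max:
            warnings.warn(f"flat segment [{start}, {stop}] skipped", stacklevel=2)
            continue
        apertures.append(amp)
    if not apertures:
        raise DegenerateSignalError("no non-flat tap segments")
    apertures = np.asarray(apertures)
    return apertures, float(apertures.mean())


def decrement_index(apertures: np.ndarray, th_alpha: float = TH_ALPHA) -> DecrementResult:
    """First tap whose aperture drops below ``th_alpha`` x the running maximum.

    The first tap is the initial reference, so ``i_dec >= 2``.  When no tap is
    flagged the sentinel ``n_taps + 1`` is returned (no decrement within the
    sequence).
    """
    apertures = np.asarray(apertures, dtype=float)
    if apertures.size == 0:
        raise DegenerateSignalError("empty aperture sequence")
    if not 0.0 < th_alpha < 1.0:
        raise ValueError(f"th_alpha must lie in (0, 1), got {th_alpha}")
    flagged: list[int] = []
    running_max = apertures[0]
    for i in range(2, apertures.size + 1):
        if apertures[i - 1] < th_alpha * running_max:
            flagged.append(i)
        running_max = max(running_max, apertures[i - 1])
    i_dec = flagged[0] if flagged else apertures.size + 1
    return DecrementResult(i_dec=i_dec, th_alpha=th_alpha, flagged=flagged)
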