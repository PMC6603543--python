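"""Relative angular velocity and its dominant rotation component.

The tapping motion is essentially a single-axis rotation of the thumb with
respect to the index finger.  We form the relative angular velocity
``omega_r = omega1 - omega2`` per axis and reduce it to the scalar series
``omega_rd`` carried by the dominant rotation axis.  When no single raw axis
clearly dominates, the signal is re-oriented by projecting onto the principal
rotation axis (largest eigenvector of the channel covariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoMotionError
from .recording import GyroRecording

_AXES = ("x", "y", "z")

#: A single raw axis must carry at least this share of the total rotational
#: power, otherwise the principal-axis re-orientation is applied.
DOMINANCE_THRESHOLD = 0.6


@dataclass
class RelativeVelocity:
    """Relative angular velocity and its dominant scalar component (deg/s)."""

    omega_r: np.ndarray      # (n, 3)
    omega_rd: np.ndarray     # (n,)
    dominant_axis: str
    rotated: bool
    fs: float


def relative_angular_velocity(rec: GyroRecording, rotation: np.ndarray | None = None) -> np.ndarray:
    """Thumb angular velocity minus index-finger angular velocity, per axis.

    ``rotation`` optionally applies a static 3x3 mounting-correction matrix to
    the thumb sensor before subtraction (sensor frames are assumed otherwise
    aligned).
    """
    omega1 = rec.omega1
    if rotation is not None:
        rotation = np.asarray(rotation, dtype=float)
        if rotation.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {rotation.shape}")
        omega1 = omega1 @ rotation.T
    return omega1 - rec.omega2


def select_dominant_component(
    omega_r: np.ndarray,
    fs: float,
    dominance_threshold: float = DOMINANCE_THRESHOLD,
) -> RelativeVelocity:
    """Reduce the 3-channel relative velocity to its dominant scalar component.

    Dominance is judged by per-axis mean-squared value.  If the strongest raw
    axis holds less than ``dominance_threshold`` of the total rotational power,
    the series is projected onto the principal rotation axis (largest
    eigenvector of the 3x3 second-moment matrix) instead, and ``rotated`` is
    set.  The sign of the scalar series is flipped when its largest extrema are
    clearly negative, so that closing peaks come out positive; for symmetric
    signals no flip is applied.
    """
    omega_r = np.asarray(omega_r, dtype=float)
    if omega_r.ndim != 2 or omega_r.shape[1] != 3:
        raise ValueError(f"omega_r must have shape (n, 3), got {omega_r.shape}")
    power = np.mean(omega_r**2, axis=0)
    total = float(power.sum())
    if total == 0.0:
        raise NoMotionError("all relative angular-velocity channels are zero")

    imax = int(np.argmax(power))
    if power[imax] >= dominance_threshold * total:
        omega_rd = omega_r[:, imax].copy()
        axis = _AXES[imax]
        rotated = False
    else:
        moment = omega_r.T @ omega_r / omega_r.shape[0]
        eigvals, eigvecs = np.linalg.eigh(moment)
        v = eigvecs[:, int(np.argmax(eigvals))]
        omega_rd = omega_r @ v
        axis = _AXES[int(np.argmax(np.abs(v)))]
        rotated = True

    omega_rd = _fix_sign(omega_rd)
    return RelativeVelocity(
        omega_r=omega_r, omega_rd=omega_rd, dominant_axis=axis, rotated=rotated, fs=fs
    )


def _fix_sign(x: np.ndarray, rel_tol: float = 0.01) -> np.ndarray:
    """Flip ``x`` when the mean of its top-decile-magnitude samples is clearly
    negative (inverted sensor mounting).  Symmetric signals are left as-is so
    the decision is deterministic under noise."""
    amp = np.abs(x)
    peak = amp.max()
    if peak == 0.0:
        return x
    top = x[amp >= np.quantile(amp, 0.9)]
    if top.mean() < -rel_tol * peak:
        return -x
    return x
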