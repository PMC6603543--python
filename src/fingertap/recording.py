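"""In-memory container for a two-sensor gyroscope recording.

A finger-tapping trial is recorded with one 3-axis gyroscope on the thumb
(``omega1``) and one on the index finger (``omega2``), both in deg/s, sampled
synchronously at ``fs`` Hz.  All downstream analysis operates on this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FingertapError

_HANDS = ("left", "right", "unknown")


@dataclass
class GyroRecording:
    """Two synchronized 3-axis angular-velocity streams.

    Parameters
    ----------
    fs
        Sampling rate in Hz (> 0).
    omega1, omega2
        Thumb / index-finger angular velocity, shape ``(n, 3)``, deg/s.
    t
        Optional sample timestamps in seconds; synthesized from ``fs`` when
        absent.
    subject_id, hand
        Free-text metadata carried through to reports.
    """

    fs: float
    omega1: np.ndarray
    omega2: np.ndarray
    t: np.ndarray | None = None
    subject_id: str = ""
    hand: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise FingertapError(f"sampling rate must be positive, got {self.fs}")
        self.omega1 = np.asarray(self.omega1, dtype=float)
        self.omega2 = np.asarray(self.omega2, dtype=float)
        for name, arr in (("omega1", self.omega1), ("omega2", self.omega2)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise FingertapError(f"{name} must have shape (n, 3), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                bad = int(np.argwhere(~np.isfinite(arr))[0][0])
                raise FingertapError(f"non-finite sample in {name} at row {bad}")
        if self.omega1.shape[0] != self.omega2.shape[0]:
            raise FingertapError(
                "channel length mismatch: omega1 has "
                f"{self.omega1.shape[0]} samples, omega2 has {self.omega2.shape[0]}"
            )
        if self.omega1.shape[0] < 2:
            raise FingertapError("recording must contain at least 2 samples")
        if self.hand not in _HANDS:
            raise FingertapError(f"hand must be one of {_HANDS}, got {self.hand!r}")
        if self.t is not None:
            self.t = np.asarray(self.t, dtype=float)
            if self.t.shape != (self.omega1.shape[0],):
                raise FingertapError("timestamp vector length does not match channels")

    @property
    def n_samples(self) -> int:
        return self.omega1.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def time(self) -> np.ndarray:
        """Sample timestamps (s); synthesized from ``fs`` when not stored."""
        if self.t is not None:
            return self.t
        return np.arange(self.n_samples) / self.fs
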