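"""Segmentation of the tapping signal into individual taps.

The dominant relative angular velocity is smoothed with a moving average whose
span is half the basic tapping period, normalized to its maximum, and scanned
for regions above +0.1 / below -0.1.  One local extremum is kept per region:
positive peaks mark the maximal closing velocity, negative valleys the maximal
opening velocity.  The first zero crossing after each closing peak is the
moment the fingers touch ("zero posture"); those samples, complemented with
the first and last sample, delimit the individual taps and later anchor the
drift-removal fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import DegenerateSignalError, InsufficientTapsError, NoTappingError

#: Spectral search band for the basic tapping frequency, Hz.
F0_BAND = (0.5, 8.0)

#: Threshold on the smoothed, normalized velocity for peak/valley regions.
REGION_THRESHOLD = 0.1

#: Regions shorter than this many samples are treated as noise spurs.
MIN_REGION_SAMPLES = 3


@dataclass
class TapMarkers:
    """Per-tap landmarks on the smoothed, normalized velocity."""

    peaks: np.ndarray         # sample indices of maximal closing velocity
    valleys: np.ndarray       # sample indices of maximal opening velocity
    zero_posture: np.ndarray  # tap boundaries (fingers closed), incl. endpoints
    n_taps: int
    f0: float                 # basic tapping frequency, Hz
    tap_segments: list[tuple[int, int]] = field(default_factory=list)


def estimate_base_frequency(
    omega_rd: np.ndarray,
    fs: float,
    band: tuple[float, float] = F0_BAND,
    min_duration: float = 2.0,
) -> float:
    """Frequency of the highest spectral peak within ``band`` (Hz).

    Uses a zero-padded FFT of the mean-removed signal.  Raises
    :class:`NoTappingError` when the in-band peak does not rise above the
    noise floor (max < 4x the in-band median magnitude).
    """
    x = np.asarray(omega_rd, dtype=float)
    if x.size < min_duration * fs:
        raise InsufficientTapsError(
            f"need at least {min_duration:g} s of signal to estimate the tapping rate"
        )
    xc = x - x.mean()
    if np.max(np.abs(xc)) == 0.0:
        raise NoTappingError("constant signal: no tapping activity")
    nfft = 1 << int(np.ceil(np.log2(4 * x.size)))
    mags = np.abs(np.fft.rfft(xc, nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mask):
        raise NoTappingError(f"no spectral bins inside the band {band}")
    band_mags = mags[mask]
    peak = band_mags.max()
    if peak < 4.0 * np.median(band_mags):
        raise NoTappingError("no spectral peak above the noise floor in the tapping band")
    return float(freqs[mask][int(np.argmax(band_mags))])


def smooth_normalize(omega_rd: np.ndarray, fs: float, f0: float) -> np.ndarray:
    """Moving average with span ``round((fs/f0)/2)``, then unit-max normalization."""
    if f0 <= 0:
        raise ValueError(f"f0 must be positive, got {f0}")
    x = np.asarray(omega_rd, dtype=float)
    window = max(1, int(round((fs / f0) / 2.0)))
    sm = uniform_filter1d(x, size=window, mode="nearest")
    peak = np.max(np.abs(sm))
    if peak == 0.0:
        raise DegenerateSignalError("signal is identically zero after smoothing")
    return sm / peak


def _regions(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Contiguous True runs of ``mask`` as (start, stop) half-open pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    out = []
    for start, stop in zip(idx[::2], idx[1::2]):
        if stop - start >= min_len:
            out.append((int(start), int(stop)))
    return out


def _first_crossings(s: np.ndarray, extrema: list[int], direction: int) -> list[int]:
    """First sample at/through zero scanning forward from each extremum."""
    out = []
    for e in extrema:
        after = np.flatnonzero(direction * s[e:] >= 0.0)
        if after.size:
            out.append(e + int(after[0]))
    return out


def _anchor_rms(integral: np.ndarray, anchors: list[int], n: int) -> float:
    pts = np.unique(np.concatenate(([0], anchors, [n - 1]))).astype(int)
    degree = min(3, pts.size - 1)
    poly = np.polynomial.Polynomial.fit(pts.astype(float), integral[pts], degree)
    return float(np.sqrt(np.mean((integral[pts] - poly(pts.astype(float))) ** 2)))


def detect_tap_markers(
    smoothed: np.ndarray,
    fs: float,
    f0: float = float("nan"),
    threshold: float = REGION_THRESHOLD,
    min_region: int = MIN_REGION_SAMPLES,
) -> TapMarkers:
    """Extract peaks, valleys and zero-posture boundaries from the smoothed,
    normalized velocity.

    Zero-posture markers are the first samples at or below zero scanning
    forward from each positive (closing) peak; the marker list is complemented
    with the first and last sample.  A tap is an inter-boundary interval
    containing at least one extremum.
    """
    s = np.asarray(smoothed, dtype=float)
    n = s.size
    peaks = [start + int(np.argmax(s[start:stop])) for start, stop in _regions(s > threshold, min_region)]
    valleys = [start + int(np.argmin(s[start:stop])) for start, stop in _regions(s < -threshold, min_region)]
    extrema = np.sort(np.asarray(peaks + valleys, dtype=int))
    if extrema.size < 2:
        raise InsufficientTapsError("fewer than two velocity extrema: not enough taps")

    # Two candidate crossing families: after closing peaks (if the signal is
    # closing-positive) the first non-positive sample is a closed posture;
    # with inverted orientation it is the after-valley family instead.  The
    # closed-posture family is the one whose anchor values on the integrated
    # signal (including the resting endpoints) follow a smooth cubic, because
    # closed postures all sit on the slow drift baseline while maximum-aperture
    # instants sit one (variable) aperture above it.
    zeros_p = _first_crossings(s, peaks, direction=-1)
    zeros_v = _first_crossings(s, valleys, direction=+1)
    if zeros_p and zeros_v:
        integral = np.concatenate(([0.0], np.cumsum((s[1:] + s[:-1]) / 2.0)))
        if _anchor_rms(integral, zeros_v, n) < _anchor_rms(integral, zeros_p, n):
            zeros_p = zeros_v
            peaks, valleys = valleys, peaks
    elif zeros_v and not zeros_p:
        zeros_p = zeros_v
        peaks, valleys = valleys, peaks
    boundaries = np.unique(np.concatenate(([0], zeros_p, [n - 1]))).astype(int)
    if boundaries.size < 2:
        raise InsufficientTapsError("fewer than two tap boundaries found")

    segments = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if np.any((extrema > a) & (extrema < b)):
            segments.append((int(a), int(b)))
    if not segments:
        raise InsufficientTapsError("no tap segment contains a velocity extremum")

    return TapMarkers(
        peaks=np.asarray(peaks, dtype=int),
        valleys=np.asarray(valleys, dtype=int),
        zero_posture=boundaries,
        n_taps=len(segments),
        f0=f0,
        tap_segments=segments,
    )


def segment_taps(omega_rd: np.ndarray, fs: float) -> TapMarkers:
    """Convenience pipeline: base frequency -> smoothing -> marker detection."""
    f0 = estimate_base_frequency(omega_rd, fs)
    smoothed = smooth_normalize(omega_rd, fs, f0)
    return detect_tap_markers(smoothed, fs, f0=f0)
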