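"""Time-frequency analysis: complex-Morlet CWT, CSAT, events, tapping rate.

The continuous wavelet transform uses the complex Morlet mother wavelet

    psi(t) = (sigma * sqrt(2*pi))**(-1/2) * exp(-t**2 / (2*sigma**2))
             * exp(2j*pi*f0_w*t)

with center frequency ``f0_w = 1`` Hz and time-frequency resolution
``sigma = 0.7``, scaled by ``a = f0_w / f`` with L2 normalization
(``psi_a(t) = a**-0.5 * psi(t/a)``), and is evaluated as an FFT-based linear
convolution of the signal with the sampled wavelet.

Two characteristics are derived from the coefficient matrix:

* CSAT — the per-sample sum of coefficient magnitudes over all analysis
  frequencies, normalized to a 0–100 % scale.  Runs of samples between 25 %
  and 50 % of the mean CSAT are hesitations; runs below 25 % (or hesitation
  runs lasting longer than three mean tapping periods) are freezes; runs
  shorter than half a mean period are discarded as spurious.
* f(i) — the per-sample dominant frequency (row of the largest coefficient
  magnitude; ties go to the lowest frequency), whose mean is ``f_av``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSignalError

#: Wavelet center frequency (Hz) and time-frequency resolution (s).
F0_WAVELET = 1.0
SIGMA_WAVELET = 0.7

#: Default analysis frequency grid, Hz.
FREQ_MIN = 0.25
FREQ_MAX = 8.0
FREQ_STEP = 0.05

#: Hesitation / freeze thresholds as fractions of the mean CSAT.
TH_HESITATION = 0.50
TH_FREEZE = 0.25

#: Duration rules, in units of the mean tapping period.
LONG_HESITATION_PERIODS = 3.0
MIN_EVENT_PERIODS = 0.5

#: Half-support of the sampled wavelet, in units of the scaled Gaussian width.
_SUPPORT_SIGMAS = 8.0


def default_freq_grid() -> np.ndarray:
    n = int(round((FREQ_MAX - FREQ_MIN) / FREQ_STEP)) + 1
    return FREQ_MIN + FREQ_STEP * np.arange(n)


@dataclass
class CwtMatrix:
    """Complex CWT coefficients, one row per analysis frequency."""

    coefficients: np.ndarray  # (n_freqs, n_samples), complex
    freqs: np.ndarray         # Hz, strictly increasing
    fs: float
    f0_w: float = F0_WAVELET
    sigma: float = SIGMA_WAVELET


@dataclass
class CsatSeries:
    """Cross-sectional area of the CWT, percent of its own maximum."""

    csat: np.ndarray
    mean_csat: float
    th50: float
    th25: float
    fs: float


@dataclass
class IrregularitySet:
    """Detected hesitation/freeze segments (inclusive sample ranges)."""

    segments: list[tuple[int, int, str]]
    h_num: int
    f_num: int
    mean_period: float  # s


@dataclass
class FrequencyCharacteristic:
    """Per-sample dominant tapping frequency and its mean (Hz)."""

    f_i: np.ndarray
    f_av: float


def morlet_kernel(f: float, fs: float, f0_w: float = F0_WAVELET,
                  sigma: float = SIGMA_WAVELET) -> np.ndarray:
    """Sampled, L2-normalized complex Morlet wavelet at analysis frequency ``f``."""
    a = f0_w / f
    half = int(np.ceil(_SUPPORT_SIGMAS * a * sigma * fs))
    t = np.arange(-half, half + 1) / fs
    u = t / a
    envelope = (sigma * np.sqrt(2.0 * np.pi)) ** -0.5 * np.exp(-(u**2) / (2.0 * sigma**2))
    return a**-0.5 * envelope * np.exp(2j * np.pi * f0_w * u)


def cwt_morlet(
    omega_rd: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    f0_w: float = F0_WAVELET,
    sigma: float = SIGMA_WAVELET,
) -> CwtMatrix:
    """FFT-based complex-Morlet CWT of ``omega_rd`` on the frequency grid.

    Each row is the linear convolution of the signal with the sampled scaled
    wavelet (times the sampling interval), computed through zero-padded FFTs
    at the next power of two, and cropped to 'same' alignment.
    """
    x = np.asarray(omega_rd, dtype=float)
    n = x.size
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    if freqs[0] <= 0 or freqs[-1] >= fs / 2:
        raise ValueError(f"analysis frequencies must lie in (0, {fs / 2:g}) Hz")

    kernels = [morlet_kernel(f, fs, f0_w, sigma) for f in freqs]
    m_max = max(k.size for k in kernels)
    nfft = 1 << int(np.ceil(np.log2(n + m_max - 1)))
    x_hat = np.fft.fft(x, nfft)
    dt = 1.0 / fs

    coef = np.empty((freqs.size, n), dtype=complex)
    for row, kernel in enumerate(kernels):
        full = np.fft.ifft(x_hat * np.fft.fft(kernel, nfft))
        start = (kernel.size - 1) // 2
        coef[row] = full[start : start + n] * dt
    return CwtMatrix(coefficients=coef, freqs=freqs, fs=fs, f0_w=f0_w, sigma=sigma)


def csat(cwt: CwtMatrix) -> CsatSeries:
    """Sum of coefficient magnitudes over frequency, as percent of its maximum."""
    total = np.abs(cwt.coefficients).sum(axis=0)
    peak = total.max()
    if peak == 0.0:
        raise DegenerateSignalError("all CWT coefficients are zero")
    series = 100.0 * total / peak
    mean = float(series.mean())
    return CsatSeries(
        csat=series,
        mean_csat=mean,
        th50=TH_HESITATION * mean,
        th25=TH_FREEZE * mean,
        fs=cwt.fs,
    )


def frequency_characteristic(cwt: CwtMatrix) -> FrequencyCharacteristic:
    """Per-sample dominant frequency f(i) and its mean f_av (Hz)."""
    rows = np.argmax(np.abs(cwt.coefficients), axis=0)  # ties -> lowest frequency
    f_i = cwt.freqs[rows]
    return FrequencyCharacteristic(f_i=f_i, f_av=float(f_i.mean()))


def detect_irregularities(cs: CsatSeries, fs: float, mean_period: float) -> IrregularitySet:
    """Classify sub-threshold CSAT runs into hesitations and freezes.

    Per-sample labels: normal (>= th50), hesitation (th25 < v < th50), freeze
    (<= th25).  Runs shorter than half the mean tapping period are discarded;
    hesitation runs lasting more than three mean periods become freezes.
    """
    if mean_period <= 0:
        raise ValueError(f"mean_period must be positive, got {mean_period}")
    v = cs.csat
    labels = np.zeros(v.size, dtype=np.int8)
    labels[(v > cs.th25) & (v < cs.th50)] = 1
    labels[v <= cs.th25] = 2

    segments: list[tuple[int, int, str]] = []
    start = 0
    for stop in range(1, v.size + 1):
        if stop == v.size or labels[stop] != labels[start]:
            label = labels[start]
            if label:
                duration = (stop - start) / fs
                if duration >= MIN_EVENT_PERIODS * mean_period:
                    kind = "freeze" if (
                        label == 2 or duration > LONG_HESITATION_PERIODS * mean_period
                    ) else "hesitation"
                    segments.append((start, stop - 1, kind))
            start = stop
    h_num = sum(1 for seg in segments if seg[2] == "hesitation")
    f_num = len(segments) - h_num
    return IrregularitySet(segments=segments, h_num=h_num, f_num=f_num, mean_period=mean_period)
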