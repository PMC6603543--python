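"""Synthetic two-sensor tapping recordings with known ground truth.

Each tap is a raised-sine angle pulse ``alpha(t) = A * sin(pi*t/T)**2`` over
its tap period, so the angle starts and ends at zero (clean zero-posture
boundaries).  The angular velocity is its exact derivative with the clinical
sign convention (closing positive): ``omega(t) = -A*(pi/T)*sin(2*pi*t/T)``.
The velocity is placed on the Y axis of both sensors, split
``thumb_share : -(1 - thumb_share)`` between thumb and index finger, with a
small cross-axis leakage on the thumb X axis so that dominant-component
selection is exercised.  Slow sinusoidal drift (0.05 Hz) and white noise are
added per channel.

Events
------
* A *freeze* inserts a pause with fingers closed (zero velocity) of the given
  duration.
* A *hesitation* slows the ongoing taps without changing their aperture: the
  tap period is stretched so that the local CSAT level lands at the requested
  ``residual`` fraction of the running plateau (CSAT of a tap scales like
  ``amplitude * sqrt(rate)``, i.e. like ``s**1.5`` for a pure slow-down by a
  factor ``s``; hence ``s = residual**(2/3)``).  Attenuating the aperture
  instead would spuriously trigger the amplitude-decrement rule, which is why
  slowing is used.

Amplitude decrement is a per-tap profile: from ``decrement_onset_tap`` on,
apertures are multiplied by ``decrement_ratio`` once ("step" mode) or
compounded per tap with an optional floor ("geometric" mode).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .recording import GyroRecording

#: Frequency of the slow baseline drift, Hz.
DRIFT_FREQ = 0.05

#: Reference-cohort cell centers used by :func:`reference_cohort`:
#: per style, (alpha_av degrees, f_av Hz) for severities 0..3.
REFERENCE_CELLS = {
    "C1": {"alpha": (85.0, 55.0, 32.0, 15.0), "freq": (2.2, 1.9, 1.6, 1.3)},
    "C2": {"alpha": (50.0, 35.0, 22.0, 10.0), "freq": (3.2, 2.6, 2.0, 1.4)},
}
REFERENCE_SIGMA = {"alpha": 3.0, "freq": 0.12}


@dataclass
class SimulationSpec:
    """Parameters of one synthetic finger-tapping recording."""

    fs: float = 200.0
    duration: float = 15.0
    tap_frequency: float = 2.5       # Hz
    aperture: float = 60.0           # degrees
    decrement_ratio: float = 1.0     # 1.0 = no decrement
    decrement_onset_tap: int | None = None   # 1-based
    decrement_mode: str = "step"     # "step" | "geometric"
    decrement_floor: float = 0.0     # fraction of the nominal aperture
    hesitations: tuple[tuple[float, float, float], ...] = ()  # (onset s, duration s, residual)
    freezes: tuple[tuple[float, float], ...] = ()             # (onset s, duration s)
    drift_amplitude: float = 2.0     # deg/s
    noise_sd: float = 0.5            # deg/s
    thumb_share: float = 0.7
    cross_axis_leakage: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tap_frequency < self.fs / 4:
            raise ValueError("tap_frequency must lie in (0, fs/4)")
        if self.duration <= 0 or self.fs <= 0 or self.aperture <= 0:
            raise ValueError("fs, duration and aperture must be positive")
        if not 0 < self.decrement_ratio <= 1.0:
            raise ValueError("decrement_ratio must lie in (0, 1]")
        if self.decrement_mode not in ("step", "geometric"):
            raise ValueError(f"unknown decrement mode {self.decrement_mode!r}")
        if self.decrement_onset_tap is not None and self.decrement_onset_tap < 2:
            raise ValueError("decrement_onset_tap must be >= 2 (first tap is the reference)")
        for onset, dur, residual in self.hesitations:
            if not 0 <= onset < self.duration or dur <= 0:
                raise ValueError("hesitation events must lie within [0, duration]")
            if not 0 < residual < 1:
                raise ValueError("hesitation residual must lie in (0, 1)")
        for onset, dur in self.freezes:
            if not 0 <= onset < self.duration or dur <= 0:
                raise ValueError("freeze events must lie within [0, duration]")


@dataclass
class GroundTruth:
    """Construction-time truth for a generated recording."""

    true_apertures: np.ndarray           # degrees, per realized tap
    true_f: float                        # nominal tapping rate, Hz
    true_i_dec: int                      # per the 75 % running-max rule; sentinel n+1
    true_h_num: int
    true_f_num: int
    event_windows: list[tuple[int, int, str]]  # inclusive sample ranges
    clean_omega: np.ndarray              # noiseless dominant velocity, deg/s
    clean_angle: np.ndarray              # noiseless aperture angle, degrees


def _aperture_profile(spec: SimulationSpec, k: int) -> float:
    """Aperture of 1-based tap ``k`` under the decrement profile."""
    a = spec.aperture
    onset = spec.decrement_onset_tap
    if onset is None or k < onset or spec.decrement_ratio == 1.0:
        return a
    if spec.decrement_mode == "step":
        return a * spec.decrement_ratio
    factor = spec.decrement_ratio ** (k - onset + 1)
    return a * max(factor, spec.decrement_floor)


def _true_i_dec(apertures: np.ndarray, th: float = 0.75) -> int:
    running = apertures[0]
    for i in range(2, apertures.size + 1):
        if apertures[i - 1] < th * running:
            return i
        running = max(running, apertures[i - 1])
    return apertures.size + 1


def generate(spec: SimulationSpec) -> tuple[GyroRecording, GroundTruth]:
    """Synthesize a recording and its ground truth from ``spec``.

    All randomness (drift phases, noise) derives from ``spec.seed``; the same
    spec yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    fs, duration = spec.fs, spec.duration
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    period = 1.0 / spec.tap_frequency

    # Build the element timeline: ('tap', t0, period, aperture) and
    # ('gap', t0, duration).  Events are applied when the cursor reaches
    # their onset; hesitations stretch whole taps, freezes insert a pause.
    events = sorted(
        [(onset, "hesitation", dur, residual) for onset, dur, residual in spec.hesitations]
        + [(onset, "freeze", dur, None) for onset, dur in spec.freezes]
    )
    # Only complete taps are emitted; the trial ends at rest (fingers closed)
    # once no further full tap fits, which keeps the endpoint drift anchors
    # valid (angle = 0 at the first and last sample).
    eps = 1e-9
    elements: list[tuple] = []
    windows: list[tuple[float, float, str]] = []
    cursor, k, ev = 0.0, 1, 0
    while cursor < duration - eps:
        if ev < len(events) and events[ev][0] <= cursor:
            onset, kind, dur, residual = events[ev]
            ev += 1
            start = cursor
            if kind == "freeze":
                elements.append(("gap", cursor, min(dur, duration - cursor)))
                cursor += dur
            else:
                slow = residual ** (2.0 / 3.0)
                slow_period = period / slow
                n_slow = max(1, int(round(dur / slow_period)))
                added = 0
                for _ in range(n_slow):
                    if cursor + slow_period > duration + eps:
                        break
                    elements.append(("tap", cursor, slow_period, _aperture_profile(spec, k)))
                    cursor += slow_period
                    k += 1
                    added += 1
                if added == 0:
                    continue  # event did not fit: not realized
            windows.append((start, min(cursor, duration), kind))
        elif cursor + period <= duration + eps:
            elements.append(("tap", cursor, period, _aperture_profile(spec, k)))
            cursor += period
            k += 1
        else:
            break

    clean_omega = np.zeros(n)
    clean_angle = np.zeros(n)
    apertures = []
    for el in elements:
        if el[0] == "gap":
            continue
        _, t0, p, amp = el
        i0 = int(np.ceil(t0 * fs))
        i1 = min(n, int(np.ceil((t0 + p) * fs)))
        if i1 <= i0:
            continue
        phase = (t[i0:i1] - t0) / p
        clean_angle[i0:i1] = amp * np.sin(np.pi * phase) ** 2
        clean_omega[i0:i1] = -amp * (np.pi / p) * np.sin(2.0 * np.pi * phase)
        apertures.append(amp)
    apertures = np.asarray(apertures)

    omega1 = np.zeros((n, 3))
    omega2 = np.zeros((n, 3))
    omega1[:, 1] = spec.thumb_share * clean_omega
    omega1[:, 0] = spec.cross_axis_leakage * clean_omega
    omega2[:, 1] = -(1.0 - spec.thumb_share) * clean_omega
    for arr in (omega1, omega2):
        for axis in range(3):
            amp = spec.drift_amplitude * rng.uniform(0.5, 1.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            arr[:, axis] += amp * np.sin(2.0 * np.pi * DRIFT_FREQ * t + phase)
        arr += rng.normal(0.0, spec.noise_sd, size=arr.shape)

    rec = GyroRecording(
        fs=fs, omega1=omega1, omega2=omega2, t=t,
        subject_id=f"sim-{spec.seed}", meta={"spec": spec},
    )
    truth = GroundTruth(
        true_apertures=apertures,
        true_f=spec.tap_frequency,
        true_i_dec=_true_i_dec(apertures) if apertures.size else 0,
        true_h_num=sum(1 for w in windows if w[2] == "hesitation"),
        true_f_num=sum(1 for w in windows if w[2] == "freeze"),
        event_windows=[
            (int(a * fs), min(n - 1, int(b * fs)), kind) for a, b, kind in windows
        ],
        clean_omega=clean_omega,
        clean_angle=clean_angle,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _place_events(rng, durations, duration, min_gap=1.0):
    """Sequential onsets with at least ``min_gap`` seconds between events."""
    onsets = []
    cursor = rng.uniform(1.0, 1.8)
    for dur in durations:
        onsets.append(cursor)
        cursor += dur + min_gap + rng.uniform(0.0, 0.35)
    return onsets


def _style_params(rng, style):
    if style == "C1":
        return rng.uniform(78.0, 92.0), rng.uniform(2.15, 2.45)
    return rng.uniform(47.0, 56.0), rng.uniform(3.25, 3.55)


def sample_spec(archetype: int, seed: int) -> SimulationSpec:
    """Draw one simulation spec from the archetype's parameter distribution.

    Archetypes parameterize the severity anchors of the scale: 0 fast/wide
    with no events; 1 one-to-two hesitations or a late decrement; 2 three-to-
    five hesitations or a midway decrement; 3 six hesitations, a freeze, or a
    decrement from the second tap; 4 at least three severe criteria at once.
    """
    if archetype not in range(5):
        raise ValueError(f"archetype must be 0..4, got {archetype}")
    rng = np.random.default_rng(seed)
    style = "C1" if rng.random() < 0.5 else "C2"
    aperture, f = _style_params(rng, style)
    spec = SimulationSpec(tap_frequency=f, aperture=aperture, seed=int(rng.integers(2**31)))

    def hes_events(count):
        durations = rng.uniform(0.55, 0.9, size=count)
        onsets = _place_events(rng, durations, spec.duration)
        return tuple(
            (float(o), float(d), float(rng.uniform(0.26, 0.30)))
            for o, d in zip(onsets, durations)
        )

    if archetype == 0:
        return spec
    if archetype == 1:
        if rng.random() < 0.5:
            return replace(spec, hesitations=hes_events(int(rng.integers(1, 3))))
        return replace(spec, decrement_onset_tap=int(rng.integers(8, 11)), decrement_ratio=0.65)
    if archetype == 2:
        if rng.random() < 0.5:
            return replace(spec, hesitations=hes_events(int(rng.integers(3, 6))))
        return replace(spec, decrement_onset_tap=int(rng.integers(3, 8)), decrement_ratio=0.65)
    if archetype == 3:
        variant = rng.integers(3)
        if variant == 0:
            return replace(spec, hesitations=hes_events(6))
        if variant == 1:
            dur = float(rng.uniform(1.3, 2.0))
            onset = float(rng.uniform(3.0, spec.duration - dur - 2.0))
            return replace(spec, freezes=((onset, dur),))
        return replace(spec, decrement_onset_tap=2, decrement_ratio=0.55)
    # archetype 4: severe slowing + early geometric decrement + freeze(s) —
    # at least three criteria simultaneously in the severe band for either
    # style's boundaries ("barely performs the task").
    n_freezes = int(rng.integers(1, 3))
    durations = rng.uniform(1.3, 1.9, size=n_freezes)
    onsets = _place_events(rng, durations, spec.duration, min_gap=1.6)
    freezes = tuple((float(o + 3.0), float(d)) for o, d in zip(onsets, durations))
    return replace(
        spec,
        tap_frequency=float(rng.uniform(1.15, 1.35)),
        decrement_onset_tap=2,
        decrement_ratio=0.40,
        decrement_mode="geometric",
        decrement_floor=0.15,
        freezes=freezes,
    )


def sample_event_spec(seed: int) -> SimulationSpec:
    """Draw a recording spec with a random, well-separated event load.

    Freeze count 0–2 and hesitation count 0–6, jointly restricted to what
    fits in the trial with at least one second between events (with two
    freezes at most three hesitations fit; the individual ranges are fully
    covered across seeds).
    """
    rng = np.random.default_rng(seed)
    f = rng.uniform(2.0, 3.0)
    aperture = rng.uniform(50.0, 90.0)
    n_freezes = int(rng.integers(0, 3))
    h_max = {0: 6, 1: 5, 2: 3}[n_freezes]
    n_hes = int(rng.integers(0, h_max + 1))
    kinds = ["freeze"] * n_freezes + ["hesitation"] * n_hes
    rng.shuffle(kinds)
    durations = [
        float(rng.uniform(1.2, 2.0)) if k == "freeze" else float(rng.uniform(0.55, 0.9))
        for k in kinds
    ]
    onsets = _place_events(rng, durations, 15.0)
    hes, frz = [], []
    for kind, onset, dur in zip(kinds, onsets, durations):
        if kind == "freeze":
            frz.append((onset, dur))
        else:
            hes.append((onset, dur, float(rng.uniform(0.26, 0.30))))
    return SimulationSpec(
        tap_frequency=f, aperture=aperture, seed=int(rng.integers(2**31)),
        hesitations=tuple(hes), freezes=tuple(frz),
    )


def generate_cohort(archetype: int, n: int, seed: int) -> list[tuple[GyroRecording, GroundTruth]]:
    """Generate ``n`` seeded recordings drawn from one archetype."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        spec = sample_spec(archetype, int(rng.integers(2**31)))
        out.append(generate(spec))
    return out


def reference_cohort(seed: int, n_per_cell: int = 40):
    """Feature-space reference table: 2 styles x 4 severity cells.

    Returns ``(features, styles, severities)`` where ``features`` is an
    (8*n, 2) array of (alpha_av, f_av) draws around :data:`REFERENCE_CELLS`
    with Gaussian spread :data:`REFERENCE_SIGMA`.
    """
    rng = np.random.default_rng(seed)
    rows, styles, sevs = [], [], []
    for style, cells in REFERENCE_CELLS.items():
        for sev in range(4):
            alpha = rng.normal(cells["alpha"][sev], REFERENCE_SIGMA["alpha"], n_per_cell)
            freq = rng.normal(cells["freq"][sev], REFERENCE_SIGMA["freq"], n_per_cell)
            rows.append(np.column_stack([alpha, freq]))
            styles.extend([style] * n_per_cell)
            sevs.extend([sev] * n_per_cell)
    return np.vstack(rows), np.asarray(styles), np.asarray(sevs)


def reference_calibration(seed: int, n_per_cell: int = 40):
    """Fit a calibration model from a seeded synthetic reference cohort."""
    from .calibration import build_calibration

    features, styles, sevs = reference_cohort(seed, n_per_cell)
    normal = features[sevs == 0]
    return build_calibration(
        normal_features=normal,
        cohort_c1=features[styles == "C1"],
        cohort_c2=features[styles == "C2"],
        seed=seed,
    )
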