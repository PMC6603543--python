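"""Rule-based mapping of the five features to UPDRS finger-tapping scores.

Four criterion subscores (0–3) are derived from the feature set:

* ``s_alpha`` — average aperture against the calibrated angle boundaries;
* ``s_freq`` — average rate against the calibrated frequency boundaries;
* ``s_dec`` — decrement onset against the 10-tap anchors of the scale
  (after the first tap -> 3, midway (taps 3–7) -> 2, near the end
  (taps 8–10) -> 1, later or never -> 0);
* ``s_hf`` — hesitation/freeze counts (1–2 interruptions -> 1, 3–5 -> 2,
  more than 5 or any freeze -> 3).

The final score is 4 ("severe") when at least three subscores equal 3, and
the maximum subscore otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinematics, preprocess, segmentation, timefreq
from .calibration import CalibrationModel, assign_cluster
from .errors import StageError
from .recording import GyroRecording

#: i_dec bin edges realizing the 10-tap wording of the scale.
DEC_SEVERE_TAP = 2          # decrement starting after the first tap
DEC_MIDWAY = (3, 7)         # decrement midway in the 10-tap sequence
DEC_LATE = (8, 10)          # decrement near the end of the 10 taps


@dataclass
class FeatureSet:
    """The five decision inputs (plus the tap count they were measured on)."""

    alpha_av: float   # degrees
    f_av: float       # Hz
    i_dec: int        # 1-based tap index; sentinel n_taps + 1 when no decrement
    h_num: int
    f_num: int
    n_taps: int


@dataclass
class ScoreResult:
    s_alpha: int
    s_freq: int
    s_dec: int
    s_hf: int
    s_ft: int
    cluster: str


@dataclass
class AnalysisResult:
    """Full per-recording analysis bundle."""

    features: FeatureSet
    score: ScoreResult
    irregularities: timefreq.IrregularitySet
    angle: kinematics.AngleTrace
    markers: segmentation.TapMarkers | None = None
    relative: preprocess.RelativeVelocity | None = None
    csat: timefreq.CsatSeries | None = None
    frequency: timefreq.FrequencyCharacteristic | None = None


def subscore_from_boundaries(value: float, boundaries: np.ndarray) -> int:
    """Bin ``value`` against a strictly decreasing boundary triple.

    A value exactly on a boundary receives the better (lower) score.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.shape != (3,) or np.any(np.diff(b) >= 0):
        raise ValueError(f"boundaries must be a strictly decreasing triple, got {b}")
    if value >= b[0]:
        return 0
    if value >= b[1]:
        return 1
    if value >= b[2]:
        return 2
    return 3


def subscore_decrement(i_dec: int, n_taps: int | None = None) -> int:
    """Map the decrement onset tap to the 10-tap anchors of the scale."""
    if i_dec < 2:
        raise ValueError(f"i_dec must be >= 2 (first tap is the reference), got {i_dec}")
    if n_taps is not None and i_dec > n_taps:
        return 0  # sentinel: no decrement within the sequence
    if i_dec > DEC_LATE[1]:
        return 0
    if i_dec >= DEC_LATE[0]:
        return 1
    if i_dec >= DEC_MIDWAY[0]:
        return 2
    return 3  # i_dec == 2


def subscore_hesitations(h_num: int, f_num: int) -> int:
    """Interruption counts to subscore: >5 hesitations or any freeze -> 3."""
    if h_num < 0 or f_num < 0:
        raise ValueError("event counts must be non-negative")
    if f_num >= 1 or h_num > 5:
        return 3
    if h_num >= 3:
        return 2
    if h_num >= 1:
        return 1
    return 0


def final_score(s_alpha: int, s_freq: int, s_dec: int, s_hf: int) -> int:
    """Aggregate the four subscores: >= 3 threes -> 4, else the maximum."""
    subs = (s_alpha, s_freq, s_dec, s_hf)
    if any(s not in (0, 1, 2, 3) for s in subs):
        raise ValueError(f"subscores must be integers in 0..3, got {subs}")
    if sum(1 for s in subs if s == 3) >= 3:
        return 4
    return max(subs)


def score_features(
    features: FeatureSet,
    model: CalibrationModel,
    standardize: bool = False,
) -> ScoreResult:
    """Cluster assignment + the four rules + final aggregation."""
    cluster, (b_alpha, b_freq) = assign_cluster(
        features.alpha_av, features.f_av, model, standardize=standardize
    )
    s_alpha = subscore_from_boundaries(features.alpha_av, b_alpha)
    s_freq = subscore_from_boundaries(features.f_av, b_freq)
    s_dec = subscore_decrement(features.i_dec, features.n_taps)
    s_hf = subscore_hesitations(features.h_num, features.f_num)
    return ScoreResult(
        s_alpha=s_alpha,
        s_freq=s_freq,
        s_dec=s_dec,
        s_hf=s_hf,
        s_ft=final_score(s_alpha, s_freq, s_dec, s_hf),
        cluster=cluster,
    )


def score_recording(
    rec: GyroRecording,
    model: CalibrationModel,
    th_alpha: float = kinematics.TH_ALPHA,
    standardize: bool = False,
    rotation: np.ndarray | None = None,
) -> AnalysisResult:
    """Run the full pipeline on a recording and score it.

    Stages: relative velocity -> dominant component -> tap segmentation ->
    angle/apertures/decrement -> CWT/CSAT/events/rate -> cluster assignment ->
    subscores -> final score.  Stage failures are re-raised as
    :class:`StageError` naming the stage.
    """
    fs = rec.fs

    def run(stage, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - deliberately tagging the stage
            raise StageError(stage, exc) from exc

    omega_r = run("preprocess", preprocess.relative_angular_velocity, rec, rotation)
    rel = run("preprocess", preprocess.select_dominant_component, omega_r, fs)
    markers = run("segmentation", segmentation.segment_taps, rel.omega_rd, fs)
    raw_angle = run("kinematics", kinematics.integrate_angle, rel.omega_rd, fs)
    alpha_t, degree = run("kinematics", kinematics.remove_drift, raw_angle, markers.zero_posture)
    apertures, alpha_av = run("kinematics", kinematics.per_tap_apertures, alpha_t, markers)
    dec = run("kinematics", kinematics.decrement_index, apertures, th_alpha)
    cwt = run("timefreq", timefreq.cwt_morlet, rel.omega_rd, fs)
    freq = run("timefreq", timefreq.frequency_characteristic, cwt)
    cs = run("timefreq", timefreq.csat, cwt)
    irregs = run("timefreq", timefreq.detect_irregularities, cs, fs, 1.0 / freq.f_av)

    features = FeatureSet(
        alpha_av=alpha_av,
        f_av=freq.f_av,
        i_dec=dec.i_dec,
        h_num=irregs.h_num,
        f_num=irregs.f_num,
        n_taps=int(apertures.size),
    )
    score = run("scoring", score_features, features, model, standardize)
    angle = kinematics.AngleTrace(
        alpha_t=alpha_t, apertures=apertures, alpha_av=alpha_av, drift_poly_degree=degree
    )
    return AnalysisResult(
        features=features,
        score=score,
        irregularities=irregs,
        angle=angle,
        markers=markers,
        relative=rel,
        csat=cs,
        frequency=freq,
    )
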