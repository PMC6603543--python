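"""File formats: signal CSV/TSV, calibration YAML, analysis reports.

Signals are plain CSV/TSV with a time column and six angular-velocity
columns, default order ``t, g1x, g1y, g1z, g2x, g2y, g2z`` (deg/s).  The
column mapping is configurable.  Calibration models and reports use a small
YAML schema; floats are written at full repr precision so read(write(x))
is the identity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationModel
from .errors import ParseError
from .recording import GyroRecording
from .scoring import FeatureSet, ScoreResult
from .timefreq import IrregularitySet

#: Default column names, in order.
DEFAULT_COLUMNS = ("t", "g1x", "g1y", "g1z", "g2x", "g2y", "g2z")
_CHANNELS = DEFAULT_COLUMNS[1:]


def read_recording(
    path,
    fs: float | None = None,
    columns: dict[str, str] | None = None,
    subject_id: str = "",
    hand: str = "unknown",
) -> GyroRecording:
    """Read a recording from CSV/TSV.

    ``columns`` maps the canonical names (``t``, ``g1x``, ...) to the file's
    column names; by default canonical names are expected.  A missing time
    column is synthesized from ``fs``; with a time column present, ``fs`` is
    inferred from the median time step unless given.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path.name}: malformed table ({exc})") from exc
    mapping = {name: name for name in DEFAULT_COLUMNS}
    if columns:
        mapping.update(columns)

    missing = [name for name in _CHANNELS if mapping[name] not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing channel column(s) {missing}")

    data = {}
    for name in _CHANNELS:
        col = pd.to_numeric(df[mapping[name]], errors="coerce")
        bad = col.index[col.isna() & df[mapping[name]].notna()]
        if len(bad):
            raise ParseError(
                f"{path.name}: non-numeric value in column {mapping[name]!r}, row {int(bad[0])}"
            )
        if col.isna().any():
            raise ParseError(
                f"{path.name}: empty cell in column {mapping[name]!r}, "
                f"row {int(col.index[col.isna()][0])}"
            )
        data[name] = col.to_numpy(dtype=float)

    t = None
    if mapping["t"] in df.columns:
        t = pd.to_numeric(df[mapping["t"]], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(t)):
            raise ParseError(f"{path.name}: non-numeric value in time column")
        if fs is None:
            dt = np.median(np.diff(t))
            if dt <= 0:
                raise ParseError(f"{path.name}: time column is not increasing")
            fs = 1.0 / dt
    elif fs is None:
        raise ParseError(f"{path.name}: no time column and no sampling rate given")

    omega1 = np.column_stack([data["g1x"], data["g1y"], data["g1z"]])
    omega2 = np.column_stack([data["g2x"], data["g2y"], data["g2z"]])
    return GyroRecording(fs=fs, omega1=omega1, omega2=omega2, t=t,
                         subject_id=subject_id, hand=hand)


def write_recording(rec: GyroRecording, path) -> None:
    """Write a recording as CSV at full float precision (round-trip exact)."""
    path = Path(path)
    df = pd.DataFrame({
        "t": rec.time(),
        "g1x": rec.omega1[:, 0], "g1y": rec.omega1[:, 1], "g1z": rec.omega1[:, 2],
        "g2x": rec.omega2[:, 0], "g2y": rec.omega2[:, 1], "g2z": rec.omega2[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Calibration models
# ---------------------------------------------------------------------------

def write_calibration(model: CalibrationModel, path) -> None:
    payload = {
        "centers": {"C1": [float(v) for v in model.center_c1],
                    "C2": [float(v) for v in model.center_c2]},
        "boundaries_angle_C1": [float(v) for v in model.b_alpha_c1],
        "boundaries_angle_C2": [float(v) for v in model.b_alpha_c2],
        "boundaries_freq_C1": [float(v) for v in model.b_freq_c1],
        "boundaries_freq_C2": [float(v) for v in model.b_freq_c2],
        "feature_scale": [float(v) for v in model.feature_scale],
        "seed": int(model.seed),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_calibration(path) -> CalibrationModel:
    try:
        payload = yaml.safe_load(Path(path).read_text())
        return CalibrationModel(
            center_c1=payload["centers"]["C1"],
            center_c2=payload["centers"]["C2"],
            b_alpha_c1=payload["boundaries_angle_C1"],
            b_alpha_c2=payload["boundaries_angle_C2"],
            b_freq_c1=payload["boundaries_freq_C1"],
            b_freq_c2=payload["boundaries_freq_C2"],
            seed=payload.get("seed", 0),
            feature_scale=payload.get("feature_scale", [1.0, 1.0]),
        )
    except (KeyError, TypeError, yaml.YAMLError) as exc:
        raise ParseError(f"{path}: not a valid calibration file ({exc})") from exc


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(
    result: ScoreResult,
    features: FeatureSet,
    path,
    irregularities: IrregularitySet | None = None,
    fs: float | None = None,
    subject_id: str = "",
) -> None:
    """Structured text report: features, subscores, final score, events.

    Tap indices (``i_dec``) are 1-based; event segments are inclusive sample
    ranges, with times in seconds when ``fs`` is given.
    """
    segments = [] if irregularities is None else irregularities.segments
    events = []
    for start, stop, kind in segments:
        entry = {"kind": kind, "start_sample": int(start), "end_sample": int(stop)}
        if fs:
            entry["start_s"] = float(start / fs)
            entry["end_s"] = float(stop / fs)
        events.append(entry)
    payload = {
        "subject_id": subject_id,
        "features": {
            "alpha_av_deg": float(features.alpha_av),
            "f_av_hz": float(features.f_av),
            "i_dec": int(features.i_dec),
            "h_num": int(features.h_num),
            "f_num": int(features.f_num),
            "n_taps": int(features.n_taps),
        },
        "subscores": {
            "S_alpha": int(result.s_alpha),
            "S_f": int(result.s_freq),
            "S_dec": int(result.s_dec),
            "S_HF": int(result.s_hf),
        },
        "final_score": int(result.s_ft),
        "cluster": result.cluster,
        "events": events,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_report(path) -> dict:
    """Parse a report back into a plain dict (round-trip of write_report)."""
    try:
        payload = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: not a valid report ({exc})") from exc
    if not isinstance(payload, dict) or "features" not in payload:
        raise ParseError(f"{path}: not a valid report")
    return payload
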