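"""Complex-Morlet CWT, CSAT, event detection and the rate characteristic."""

import numpy as np
import pytest

import fingertap as ft
from fingertap import timefreq as tf
from fingertap.errors import DegenerateSignalError


def _direct_cwt_row(x, f, fs):
    """Brute-force time-domain convolution oracle for one frequency row."""
    k = tf.morlet_kernel(f, fs)
    full = np.convolve(x, k, mode="full")
    start = (k.size - 1) // 2
    return full[start:start + x.size] / fs


def test_fft_cwt_equals_direct_convolution(fs):
    x = np.random.default_rng(3).normal(size=400)
    cwt = tf.cwt_morlet(x, fs)
    scale = np.abs(cwt.coefficients).max()
    for row in range(0, cwt.freqs.size, 13):
        direct = _direct_cwt_row(x, cwt.freqs[row], fs)
        assert np.max(np.abs(direct - cwt.coefficients[row])) / scale < 1e-6


def test_zero_signal_gives_zero_matrix(fs):
    cwt = tf.cwt_morlet(np.zeros(300), fs)
    np.testing.assert_array_equal(cwt.coefficients, 0.0)


def test_tone_selectivity(fs):
    t = np.arange(3000) / fs
    cwt = tf.cwt_morlet(np.sin(2 * np.pi * 2.5 * t), fs)
    fc = tf.frequency_characteristic(cwt)
    interior = fc.f_i[400:-400]
    assert np.all(np.abs(interior - 2.5) <= 0.1)
    assert fc.f_av == pytest.approx(2.5, abs=0.1)


def test_invalid_grid_rejected(fs):
    with pytest.raises(ValueError):
        tf.cwt_morlet(np.ones(100), fs, freqs=np.array([]))
    with pytest.raises(ValueError):
        tf.cwt_morlet(np.ones(100), fs, freqs=np.array([1.0, 150.0]))


def test_csat_stationary_tone_flat_interior(fs):
    t = np.arange(3000) / fs
    cs = tf.csat(tf.cwt_morlet(np.sin(2 * np.pi * 2.5 * t), fs))
    interior = cs.csat[400:-400]
    assert cs.csat.max() == pytest.approx(100.0)
    assert interior.std() / interior.mean() < 0.02
    assert cs.th25 < cs.th50 < cs.mean_csat


def test_csat_tracks_amplitude_halving(fs):
    t = np.arange(6000) / fs
    x = np.sin(2 * np.pi * 2.5 * t)
    x[3000:] *= 0.5
    cs = tf.csat(tf.cwt_morlet(x, fs))
    first = cs.csat[500:2500].mean()
    second = cs.csat[3500:5500].mean()
    assert second / first == pytest.approx(0.5, abs=0.03)


def test_csat_zero_matrix_errors(fs):
    with pytest.raises(DegenerateSignalError):
        tf.csat(tf.cwt_morlet(np.zeros(300), fs))


def test_chirp_frequency_nondecreasing(fs):
    t = np.arange(3000) / fs
    x = np.cos(2 * np.pi * (2.0 * t + (2.0 / 15.0) * t**2 / 2))  # 2 -> 4 Hz
    fc = tf.frequency_characteristic(tf.cwt_morlet(x, fs))
    interior = fc.f_i[400:-400]
    coarse = interior[::100]
    assert np.all(np.diff(coarse) >= -0.051)  # one grid step of slack


def test_piecewise_tone_mean_frequency(fs):
    t = np.arange(3000) / fs
    x = np.where(t < 7.5, np.sin(2 * np.pi * 2.0 * t), np.sin(2 * np.pi * 4.0 * t))
    fc = tf.frequency_characteristic(tf.cwt_morlet(x, fs))
    assert fc.f_av == pytest.approx(3.0, abs=0.15)


def _detect(x, fs):
    cwt = tf.cwt_morlet(x, fs)
    fc = tf.frequency_characteristic(cwt)
    cs = tf.csat(cwt)
    return tf.detect_irregularities(cs, fs, 1.0 / fc.f_av), cs


def test_no_events_in_steady_tapping(clean_recording, fs):
    rec, _ = clean_recording
    rel = ft.select_dominant_component(ft.relative_angular_velocity(rec), fs)
    irr, _ = _detect(rel.omega_rd, fs)
    assert (irr.h_num, irr.f_num) == (0, 0)


def test_inserted_gap_detected_as_freeze(fs):
    spec = ft.SimulationSpec(tap_frequency=2.5, aperture=60.0, seed=8,
                             noise_sd=0.0, drift_amplitude=0.0,
                             freezes=((7.0, 2.0),))
    rec, gt = ft.generate(spec)
    rel = ft.select_dominant_component(ft.relative_angular_velocity(rec), fs)
    irr, _ = _detect(rel.omega_rd, fs)
    assert gt.true_f_num == 1
    assert (irr.h_num, irr.f_num) == (0, 1)
    # the detected freeze overlaps the inserted window (2 s > 3 periods)
    (a, b, kind), = [s for s in irr.segments if s[2] == "freeze"]
    wa, wb, _ = gt.event_windows[0]
    assert kind == "freeze" and a <= wb and b >= wa


def test_short_dip_detected_as_hesitation(fs):
    spec = ft.SimulationSpec(tap_frequency=2.5, aperture=60.0, seed=8,
                             noise_sd=0.0, drift_amplitude=0.0,
                             hesitations=((7.0, 0.8, 0.30),))
    rec, gt = ft.generate(spec)
    rel = ft.select_dominant_component(ft.relative_angular_velocity(rec), fs)
    irr, cs = _detect(rel.omega_rd, fs)
    assert gt.true_h_num == 1
    assert (irr.h_num, irr.f_num) == (1, 0)
    # the dip sits between the two thresholds
    wa, wb, _ = gt.event_windows[0]
    assert cs.th25 < cs.csat[wa:wb].min() < cs.th50


def test_event_counts_invariant_to_amplitude_scaling(fs):
    spec = ft.SimulationSpec(tap_frequency=2.5, aperture=60.0, seed=8,
                             noise_sd=0.0, drift_amplitude=0.0,
                             hesitations=((4.0, 0.8, 0.30),), freezes=((9.0, 1.8),))
    rec, _ = ft.generate(spec)
    rel = ft.select_dominant_component(ft.relative_angular_velocity(rec), fs)
    irr1, _ = _detect(rel.omega_rd, fs)
    irr2, _ = _detect(rel.omega_rd * 12.5, fs)
    assert (irr1.h_num, irr1.f_num) == (irr2.h_num, irr2.f_num) == (1, 1)


def test_long_shallow_dip_reclassified_as_freeze(fs):
    # hesitation-band samples lasting > 3 mean periods count as a freeze
    cs = tf.CsatSeries(csat=np.r_[np.full(400, 100.0), np.full(400, 40.0),
                                  np.full(400, 100.0)],
                       mean_csat=80.0, th50=40.5, th25=20.0, fs=fs)
    irr = tf.detect_irregularities(cs, fs, mean_period=0.4)
    assert (irr.h_num, irr.f_num) == (0, 1)


def test_very_short_runs_discarded(fs):
    cs = tf.CsatSeries(csat=np.r_[np.full(400, 100.0), np.full(30, 40.0),
                                  np.full(400, 100.0)],
                       mean_csat=80.0, th50=40.5, th25=20.0, fs=fs)
    irr = tf.detect_irregularities(cs, fs, mean_period=0.4)
    assert (irr.h_num, irr.f_num) == (0, 0)
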