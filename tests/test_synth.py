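"""Generator internal consistency and archetype construction guarantees."""

import numpy as np
import pytest

import fingertap as ft


def test_same_seed_bit_identical():
    spec = ft.SimulationSpec(tap_frequency=2.4, aperture=55.0, seed=9,
                             hesitations=((5.0, 0.8, 0.3),))
    rec1, _ = ft.generate(spec)
    rec2, _ = ft.generate(spec)
    np.testing.assert_array_equal(rec1.omega1, rec2.omega1)
    np.testing.assert_array_equal(rec1.omega2, rec2.omega2)


def test_clean_angle_derivative_matches_clean_omega():
    # the generated velocity is (minus) the derivative of the generated angle
    spec = ft.SimulationSpec(tap_frequency=2.5, aperture=60.0, noise_sd=0.0,
                             drift_amplitude=0.0, seed=1)
    _, gt = ft.generate(spec)
    deriv = np.gradient(gt.clean_angle, 1.0 / spec.fs)
    interior = slice(2, -2)
    err = np.max(np.abs(deriv[interior] + gt.clean_omega[interior]))
    assert err < 0.05 * np.max(np.abs(gt.clean_omega))


def test_decrement_ground_truth():
    spec = ft.SimulationSpec(tap_frequency=2.5, aperture=60.0, seed=2,
                             decrement_onset_tap=2, decrement_ratio=0.6)
    _, gt = ft.generate(spec)
    assert gt.true_i_dec == 2
    assert gt.true_apertures[0] == 60.0
    assert gt.true_apertures[1] == pytest.approx(36.0)


def test_relative_velocity_reconstruction():
    # thumb minus index recovers the full dominant-axis velocity
    spec = ft.SimulationSpec(tap_frequency=2.5, aperture=60.0, noise_sd=0.0,
                             drift_amplitude=0.0, seed=3, thumb_share=0.7)
    rec, gt = ft.generate(spec)
    np.testing.assert_allclose(rec.omega1[:, 1] - rec.omega2[:, 1], gt.clean_omega,
                               atol=1e-9)


def test_event_windows_overlap_detection():
    # every true event overlaps exactly one detected segment of its kind;
    # freezes (hard zero crossings of the activity) localize to Jaccard >=
    # 0.5, while hesitation runs are narrower than the generating window by
    # construction (only the sub-threshold core of the dip is marked)
    spec = ft.SimulationSpec(tap_frequency=2.5, aperture=60.0, seed=5,
                             hesitations=((4.0, 0.8, 0.30),), freezes=((9.0, 2.0),))
    rec, gt = ft.generate(spec)
    rel = ft.select_dominant_component(ft.relative_angular_velocity(rec), rec.fs)
    cwt = ft.cwt_morlet(rel.omega_rd, rec.fs)
    fc = ft.frequency_characteristic(cwt)
    irr = ft.detect_irregularities(ft.csat(cwt), rec.fs, 1.0 / fc.f_av)
    assert len(irr.segments) == len(gt.event_windows)
    for (ta, tb, kind) in gt.event_windows:
        matches = [s for s in irr.segments if s[2] == kind and s[0] <= tb and s[1] >= ta]
        assert len(matches) == 1, f"expected one detected {kind} overlapping [{ta}, {tb}]"
        a, b, _ = matches[0]
        inter = min(b, tb) - max(a, ta)
        union = max(b, tb) - min(a, ta)
        assert inter / union >= (0.5 if kind == "freeze" else 0.25)


@pytest.mark.parametrize("archetype,check", [
    (0, lambda gt: gt.true_h_num == 0 and gt.true_f_num == 0
        and gt.true_i_dec == len(gt.true_apertures) + 1),
    (3, lambda gt: gt.true_h_num > 5 or gt.true_f_num >= 1 or gt.true_i_dec == 2),
])
def test_archetype_construction(archetype, check):
    for _, gt in ft.generate_cohort(archetype, 10, seed=31):
        assert check(gt)


def test_archetype4_has_three_severe_criteria():
    for _, gt in ft.generate_cohort(4, 10, seed=32):
        severe = 0
        severe += gt.true_f_num >= 1                       # freeze
        severe += gt.true_i_dec == 2                       # immediate decrement
        severe += gt.true_f < 1.45                         # severe slowing
        severe += np.mean(gt.true_apertures) < 22.0        # collapsed amplitude
        assert severe >= 3


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        ft.SimulationSpec(tap_frequency=60.0)  # >= fs/4
    with pytest.raises(ValueError):
        ft.SimulationSpec(hesitations=((20.0, 1.0, 0.3),))  # onset beyond trial
    with pytest.raises(ValueError):
        ft.SimulationSpec(decrement_onset_tap=1)


def test_event_spec_sampler_is_well_separated():
    for seed in range(40):
        spec = ft.sample_event_spec(seed)
        events = sorted(
            [(o, o + d) for o, d, _ in spec.hesitations]
            + [(o, o + d) for o, d in spec.freezes]
        )
        assert len(spec.freezes) <= 2 and len(spec.hesitations) <= 6
        for (a0, b0), (a1, b1) in zip(events, events[1:]):
            assert a1 - b0 >= 1.0
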