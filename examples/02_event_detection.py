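"""Detect hesitations and freezes from the CWT cross-sectional area (CSAT).

A recording with one brief hesitation (a momentary slow-down) and one 2 s
freeze is generated; the CSAT characteristic — the per-sample sum of
complex-Morlet coefficient magnitudes, as a percentage of its maximum — is
thresholded at 50 % and 25 % of its mean to localize the two kinds of
rhythm interruptions.
"""

import fingertap as ft

spec = ft.SimulationSpec(
    tap_frequency=2.5, aperture=60.0, seed=5,
    hesitations=((4.0, 0.8, 0.30),),   # onset s, duration s, CSAT residual
    freezes=((9.0, 2.0),),             # onset s, duration s
)
recording, truth = ft.generate(spec)

relative = ft.select_dominant_component(
    ft.relative_angular_velocity(recording), recording.fs
)
cwt = ft.cwt_morlet(relative.omega_rd, recording.fs)
rate = ft.frequency_characteristic(cwt)
csat = ft.csat(cwt)
events = ft.detect_irregularities(csat, recording.fs, 1.0 / rate.f_av)

print(f"mean CSAT {csat.mean_csat:.1f} %  ->  thresholds "
      f"TH50 = {csat.th50:.1f} %, TH25 = {csat.th25:.1f} %")
print(f"detected: {events.h_num} hesitation(s), {events.f_num} freeze(s)")
for start, stop, kind in events.segments:
    print(f"  {kind:<10s} {start / recording.fs:5.2f} - {stop / recording.fs:5.2f} s")
print("generated:")
for start, stop, kind in truth.event_windows:
    print(f"  {kind:<10s} {start / recording.fs:5.2f} - {stop / recording.fs:5.2f} s")

# Samples between the two thresholds are hesitations; samples below 25 %
# (or hesitation runs lasting more than three tapping periods) are freezes.
# The detected runs mark the sub-threshold core of each disturbance.
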