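"""Fit the two tapping-style clusters and the per-style score boundaries.

Normal performers split into two styles — C1 "wider and slower" and C2
"narrower and faster" — found with 2-means on (average aperture, average
rate) pairs.  Within each style, 4-means on a severity-spanning reference
sample yields four cluster centers per feature; the decision boundaries are
the midpoints of neighbouring centers, b_i = (c_i + c_{i+1}) / 2.
"""

import numpy as np

import fingertap as ft
from fingertap.synth import REFERENCE_CELLS

features, styles, severities = ft.reference_cohort(seed=11, n_per_cell=40)
model = ft.build_calibration(
    normal_features=features[severities == 0],
    cohort_c1=features[styles == "C1"],
    cohort_c2=features[styles == "C2"],
    seed=11,
)

print(f"C1 center (alpha, f): ({model.center_c1[0]:5.1f} deg, {model.center_c1[1]:.2f} Hz)")
print(f"C2 center (alpha, f): ({model.center_c2[0]:5.1f} deg, {model.center_c2[1]:.2f} Hz)")
for style, ba, bf in (("C1", model.b_alpha_c1, model.b_freq_c1),
                      ("C2", model.b_alpha_c2, model.b_freq_c2)):
    cells = REFERENCE_CELLS[style]
    true_ba = (np.array(cells["alpha"][:-1]) + np.array(cells["alpha"][1:])) / 2
    print(f"{style} angle boundaries: {np.round(ba, 1)} deg  "
          f"(generating midpoints: {true_ba})")
    print(f"{style} rate  boundaries: {np.round(bf, 2)} Hz")

# A new recording is assigned to the nearer style center and graded against
# that style's boundary triples: values above b1 score 0, below b3 score 3.
label, (b_alpha, b_freq) = ft.assign_cluster(80.0, 2.1, model)
print(f"\nexample: (80 deg, 2.1 Hz) -> cluster {label}, "
      f"S_alpha = {ft.subscore_from_boundaries(80.0, b_alpha)}, "
      f"S_f = {ft.subscore_from_boundaries(2.1, b_freq)}")
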