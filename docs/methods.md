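# Methods

This note documents the signal-processing and decision model implemented in
`fingertap`, the choices made where the procedure was genuinely open, the
synthetic data the package is validated on, and the limits of what those
validations show.

## Signal model and assumptions

A finger-tapping trial is a sequence of open–close cycles of the thumb and
index finger, recorded by one 3-axis gyroscope per finger (deg/s, default
200 Hz, 15 s).  The analysis assumes:

* the tapping motion is dominantly a single-axis rotation, so the relative
  angular velocity ω_r = ω₁ − ω₂ can be reduced to a scalar ω_rd;
* the fingers are closed (tap angle = 0) at the start and end of the trial
  and between consecutive taps, so those instants can anchor drift removal;
* gyro bias and mounting drift vary slowly compared with the tapping rate.

Closing velocity is taken positive.  Since ω_rd = −dα/dt under that
convention (α is the non-negative aperture), the integrated angle trace may
be sign-flipped; all aperture computations therefore use |α(t)|, which makes
the result orientation-independent.

## Dominant component

Per-axis mean-squared value decides dominance.  If the strongest raw axis
holds ≥ 60 % of the total rotational power it is used directly (avoids
rotating nearly clean recordings); otherwise the series is projected onto
the principal rotation axis — the largest eigenvector of the 3×3 channel
second-moment matrix.  A clearly one-sided signal (mean of the top-decile
magnitude samples below −1 % of the peak) is flipped; symmetric signals are
left untouched so the decision is deterministic under noise.

## Tap segmentation and the orientation of zero-posture markers

The smoothed (moving average of span round((fs/f0)/2) samples, f0 the
spectral peak in 0.5–8 Hz), unit-normalized ω_rd is scanned for regions
above +0.1 and below −0.1 (regions shorter than 3 samples are discarded as
noise spurs; ties within a region resolve to the earliest sample).  Zero
crossings scanning forward from each *closing* peak are the closed-posture
markers; crossings after *opening* valleys would instead mark maximal
aperture.  Because a perfectly symmetric velocity waveform does not reveal
which family is which, the marker stage disambiguates them through the drift
model itself: closed postures all lie on the slow drift baseline of the
integrated signal, while maximum-aperture instants sit one (variable)
aperture above it, so the family whose anchor values (with the resting
endpoints) fit a cubic with the smaller RMS residual is taken as closed.
This selection is what makes marker placement robust when sensor mounting
inverts the sign or when noise makes the symmetric-signal flip ambiguous.

Markers are integer sample indices (no sub-sample interpolation): they feed
a polynomial fit over sample indices.  A tap is an interval between
consecutive markers containing at least one velocity extremum; trailing
partial intervals without an extremum are not counted.

## Angle, drift, apertures, decrement

The angle is the cumulative trapezoidal integral of ω_rd.  A cubic
(least-squares; degree reduced with a warning below 4 markers) through the
zero-posture samples removes drift.  Aperture α(i) = max |α(t)| within tap
i; segments whose peak is below 1 % of the global maximum are skipped as
flat.  The decrement index flags tap i ≥ 2 when α(i) < TH_α · max(α(1..i−1))
with TH_α = 0.75; "previously achieved maximum" is read as the running
maximum, so a recovery above an earlier peak raises the reference.  With no
flagged tap the sentinel n_taps + 1 is returned, which the scoring stage
treats as "no decrement within the 10-tap window".

## Time–frequency analysis

The CWT uses the complex Morlet wavelet
ψ(t) = (σ√(2π))^(−1/2) exp(−t²/2σ²) exp(i2πf₀t) with f₀ = 1 Hz and σ =
0.7 s, scaled by a = f₀/f with L2 normalization, on a 0.25–8.0 Hz grid in
0.05 Hz steps (covers the clinically observed tapping-rate range with
margin).  Each row is an FFT-based linear convolution with the sampled
wavelet (support ±8 scaled σ, zero-padded to the next power of two), so it
matches direct convolution to machine precision; "coefficient value" always
means complex magnitude.  Cone-of-influence samples are not excluded; edge
effects are mitigated by the relative thresholds below, and synthetic tests
assert on interior samples where a stationary reference level is defined.

CSAT is the per-sample sum of magnitudes over the grid, normalized to 100 %.
With mean m, samples in (0.25 m, 0.5 m) are hesitation samples and samples
≤ 0.25 m freeze samples.  Runs shorter than half the mean tapping period
are discarded; hesitation runs longer than three mean periods become
freezes.  "Three times / one half the average tapping frequency" is read as
periods — durations cannot be compared with a frequency.  The mean period
is 1/f_av where f_av is the mean of the per-sample dominant frequency
(argmax over rows; ties resolve to the lowest frequency).  Because all
thresholds are relative, event detection is invariant to uniform amplitude
scaling.  The L2 scale normalization biases the per-sample argmax a few
percent below the true rate (the √a factor favours lower-frequency rows);
at tapping rates up to ~3.5 Hz this stays within half a grid step to two
grid steps and is accepted as part of the stated wavelet convention.

## Calibration and scoring

Style centers come from 2-means (10 restarts, tol 1e−6, fixed seed) on
(α_av, f_av) pairs of reference performances rated normal; C1 is the center
with the larger aperture ("wider and slower").  Per style and feature,
4-means centers sorted descending give boundaries bᵢ = (cᵢ+cᵢ₊₁)/2, so the
subscore grows as the feature shrinks.  A recording is assigned to the
nearer style center — by raw-unit Euclidean distance by default, following
the original description.  Raw units let the aperture coordinate (tens of
degrees) dominate the rate coordinate (a few Hz); `standardize=True`
switches to a z-scored distance (scales stored with the model), which the
package's own cohort workflows use because severity-spanning cohorts are
otherwise assigned almost purely by aperture.  Ties go to C1.  A value
exactly on a boundary receives the better score.

The decrement subscore parameterizes the verbal anchors of the scale on the
10-tap window: i_dec = 2 → 3; 3–7 → 2; 8–10 → 1; later or never → 0 (a
fixed 10-tap window, not rescaled to the actual tap count).  The
interruption subscore: any freeze or more than five hesitations → 3; 3–5
hesitations → 2; 1–2 → 1.  Final score: 4 if at least three subscores are
3, otherwise the maximum.  Note that monotonicity of the final score under
an aperture or rate sweep is a within-style property: a sweep that crosses
the style-assignment boundary switches boundary sets and can lower a
subscore — an inherent feature of the two-cluster design.

## Synthetic data: what it emulates and what it does not

Each tap is a raised-sine angle pulse α(t) = A sin²(πt/T); its exact
derivative (closing positive) is placed on the Y axis, split 0.7/−0.3
between thumb and index sensors with 10 % cross-axis leakage on the thumb,
plus per-channel 0.05 Hz sinusoidal drift (default amplitude 2 deg/s, the
slow-bias scale of consumer gyros) and white noise (default SD 0.5 deg/s).
Trials start at a closed posture and end at rest once no complete tap fits,
matching the assumption behind the endpoint drift anchors.  Defaults follow
the study conditions: 200 Hz, 15 s, tapping rates ~1.8–3.5 Hz and apertures
~30–95°, the ranges observed across patient groups and controls.

Freezes are pauses with fingers closed.  Hesitations are local slow-downs
with the aperture preserved: attenuating the aperture (an alternative
realization) would trip the 75 % decrement rule and conflate two clinically
distinct criteria.  The CSAT of a tap scales like amplitude × √rate under
the L2 wavelet normalization, i.e. s^1.5 for a pure slow-down by factor s,
so the generator sets s = residual^(2/3) to land the dip at the requested
CSAT fraction; residuals around 0.26–0.30 of the plateau keep the dip inside
the hesitation band across realistic event loads (co-occurring freezes lower
the mean CSAT and with it both thresholds).

The severity archetypes (0–4) realize the anchor descriptions of the scale:
no events; 1–2 hesitations or a late decrement; 3–5 hesitations or a midway
decrement; six hesitations, a freeze, or an immediate decrement; and, for
grade 4, severe slowing (~1.25 Hz) plus an immediate geometric decrement
plus freezes — at least three criteria in the severe band simultaneously.
Event onsets are placed sequentially with ≥ 1 s separation; within a 15 s
trial this caps the joint event load (six hesitations with no freeze, five
with one, three with two), which is why the generator never emits the
geometrically infeasible combination of six hesitations and two freezes.
The reference feature cohort used for calibration is sampled directly in
(α_av, f_av) space from 2 styles × 4 severity cells (Gaussian spread 3° /
0.12 Hz) whose centers mirror the observed group ranges.

The generator does not emulate tremor superposition, asymmetric open/close
velocity profiles, biomechanical coupling between fingers, or sensor
misalignment beyond a static leakage term.  Passing the synthetic suites
therefore demonstrates correctness of the pipeline's mechanics and rules
under the stated signal model, not clinical performance on patient data.

## Numerical choices and degenerate inputs

* Base-frequency estimation: zero-padded FFT (4× length, next power of
  two); the in-band peak must exceed 4× the in-band median magnitude, else
  a no-tapping error.  At least 2 s of signal are required.
* Moving average via `uniform_filter1d(mode="nearest")`: constants stay
  constant and the window is centered (half-sample shift for even spans).
* k-means via scikit-learn (restarts 10, max 300 iterations, tol 1e−6);
  calibration is bit-reproducible under a fixed seed.  Fitting boundaries
  needs ≥ 4 distinct values (k = 4 feasibility).
* Fewer than 4 drift anchors: the fit degree falls back with a warning
  rather than failing; fewer than 2 is an error.
* Cohen's kappa with both raters constant and identical (pe = 1) is defined
  as 1.
* Problem sizes in the test suite (20 clean recordings, 30 event
  recordings, 25 recordings per archetype, 40 reference samples per
  calibration cell) were chosen so the full suite exercises every guarantee
  at cohort scale in well under half an hour on a single core.

## Known limitations

* The scoring depends on the calibration cohort; the bundled reference
  cohort is synthetic, and clinical use requires recalibration on real
  control/patient features (`build_calibration` accepts any table; the
  train/test composition is the caller's responsibility).
* Raw-unit cluster assignment is kept as the default for fidelity to the
  original description despite its scale imbalance; z-scoring is the
  recommended switch for wide-severity cohorts.
* Very low tapping rates (< ~1 Hz) push the trailing-rest and event-duration
  rules close to their discard thresholds; the detector is validated for
  ~1.15–3.5 Hz.
* f_av carries the small low-frequency bias of the L2 wavelet normalization
  described above.
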