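# Methods

This note documents the models, parameter choices and numerical decisions
behind `cisim`, in the spirit of a methods appendix.  It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Stimulus and recording model

Tone bursts are 5 ms cosine-ramped sinusoids (2.5 ms rise/fall, so the
plateau has zero length), presented at 2–32 kHz in 4 steps/octave
(17 frequencies) and 0–90 dB SPL in 10 dB steps, in both polarities.
Recordings are synthesised directly as the 20-presentation average at a
100 kHz sampling rate — high enough to represent the 32 kHz cochlear
microphonic before offline filtering — over an epoch of 5 ms pre-stimulus
baseline plus 20 ms post-onset, covering the 0–10 ms analysis window with
margin.

Each averaged trace is the sum of three components:

* **CAP** — a fixed template (difference of two sharp gamma-like bumps,
  ~0.5 ms wide) normalised to unit peak-to-peak amplitude, with the N1
  trough at 1.8 ms and the P1 peak at 3.0 ms at the highest level.  The
  complex translates 0.5 ms later per 20 dB toward threshold without
  changing shape, so its attenuation through the offline band-pass is a
  single constant (~0.86) at every level.  Peak-to-peak amplitude grows as
  `cap_gain × max(0, level − threshold)`; no physiological saturation is
  modelled.  The bump sharpness matters: the 200 Hz high-pass removes slow
  template energy, and a broader complex would silently lower the
  effective gain of the whole pipeline.
* **CM** — a copy of the tone burst whose sign follows stimulus polarity
  and whose amplitude scales linearly with sound pressure (`cm_gain` µV at
  60 dB SPL).  Polarity averaging cancels it exactly in the noise-free
  case, which the tests verify to < 1e−9 relative.
* **Noise** — white Gaussian, `noise_sd` µV per sample, representing the
  residual noise of the average.

| parameter | unit | default | rationale |
|---|---|---|---|
| `sample_rate` | Hz | 100 000 | CM representable up to 32 kHz pre-filter |
| `cap_gain` | µV/dB | 4.0 | round-window CAPs reach a few hundred µV at high sensation levels |
| `noise_sd` | µV | 0.3 | residual noise of a 20-sweep average |
| `cm_gain` | µV @ 60 dB | 1.0 | CM visible but an order below the CAP |
| `cochleostomy_jitter_sd` | dB | 2.0 | the drilling step produced minimal, non-significant shifts |

Baseline audiograms are smooth: a per-ear offset drawn uniformly from
18–30 dB SPL, a mild rise toward the 2 kHz edge (+6 dB at 2 kHz, flat at
and above 4 kHz), and a small (±0.75 dB) slow undulation.  Keeping the
basal half of the audiogram flat is deliberate: threshold estimates live
on a 10 dB lattice, and a smooth baseline keeps the lattice phase coherent
across the high-frequency plateau of the trauma profile, so the per-ear
*maximum* of the discretised shifts is an essentially unbiased estimate of
the injected maximum rather than being inflated by frequency-to-frequency
rounding diversity.

## Trauma model and cohort calibration

Insertion trauma is injected in the threshold domain as a rising logistic
in log-frequency, `TS(f) = ts_max · σ(log2(f/f_edge)/slope_w)`: the apex
(low frequencies) is spared, the shift is half-maximal at `f_edge` and
saturates basally.  Defaults: `f_edge` 6.7 kHz (deep/6Ch) and 9.5 kHz
(shallow/5Ch), `slope_w` 0.35 octaves — placing the transition so that
2–4 kHz stays essentially unshifted while the 4.7–9.5 kHz band carries the
group difference.  Trauma acts on thresholds only; suprathreshold
amplitude reductions emerge through the level-minus-threshold growth rule,
which is also what the amplitude-change tables measure.

The default cohort has 24 ears, split 12 shallow / 12 deep.  The split is
a calibration choice: the reported grand-mean maximal shift (16.5 dB)
equals the arithmetic mean of the two group values (23.0 and 10.0 dB),
which is only consistent with equal group weights.  Per ear, the target
maximal shift is drawn from a normal with the group mean and
SD = SEM·√n (SEM 3.5 dB deep, 4.5 dB shallow), clipped at zero.  Because
clipping a N(10, 15.6²) draw at zero would inflate its mean to ~12 dB, the
pre-clip mean is solved numerically (Brent on the truncated-normal
expectation) so the *post-clip* mean equals the target; the generator then
scales `ts_max` so the injected maximum over the frequency lattice equals
the drawn value exactly.  Per-ear electrode depths are drawn from the
reported group means ± SD of the apical-contact depth (4447.75 ± 290.23 µm
shallow, 5339.56 ± 306.45 µm deep).

Seeding: ear *i* of a cohort uses `SeedSequence(master_seed, spawn_key=(i,))`;
recording noise additionally keys on the condition index.  Cohorts are
byte-reproducible, piecewise per ear.

## Threshold estimation

The criterion "response two times larger than the baseline amplitude" is
implemented inclusively (≥ 2×) against the pre-stimulus peak-to-peak of
the same filtered, polarity-averaged trace (a pooled per-ear baseline is
available behind `baseline_mode="pooled"`).  `2·baseline` is floored at
0.1 µV so a noise-free zero baseline cannot declare threshold on numerical
dust.  Frequencies with no criterion crossing are censored and recorded as
`l_max + l_step` (100 dB on the default grid) with a flag; censored cells
are excluded from group statistics and per-ear maxima by default.
Filtering is zero-phase (forward–backward), so latencies are not
group-delay shifted; the quoted band-edge order (6) applies per pass and
per edge.

Noise-free recovery is exact: the estimated threshold equals the injected
threshold rounded up to the level lattice.  With noise, recovery within
one 10 dB step holds in ≥ 95% of cells down to a signal-to-noise ratio of
`cap_gain·10/noise_sd = 5`, which the suite checks at both the default and
the boundary setting.

## Spiral geometry

The basilar membrane is a conical logarithmic spiral
`(r0·e^{−bθ}cosθ, r0·e^{−bθ}sinθ, cθ)` with `r0 = 1.4 mm`, 4.25 turns, a
2.5 mm apical rise, and the taper `b` solved (Brent) so the arc length
equals 18.5 mm — the length implied by 2.59 mm/octave being ~14% of the
cochlear duct.  Arc length is tabulated on a 32 769-point grid
(trapezoidal, rescaled to the exact total) and inverted by monotone
interpolation; round trips are exact to < 1e−6 rad.  The summit-point
reference direction is taken where the reconstruction leaves the hook
region, at 1 mm arc depth by default; insertion angle is
`θ(s_Ch1) − θ_ref` in degrees, accumulating beyond 360°, clipped at zero
(with a warning) for contacts still inside the hook.  Depths re-measured
from placed contacts agree with the placed depths to well under the 17 µm
micro-CT voxel size used as the round-trip tolerance.

The depth endpoint for percent coverage is configurable
(`apical_contact` default, `basal_contact`, `carrier_tip`), since
"insertion depth" is quoted against the apical contact in some places and
the last contact in others.  Percent coverage uses the model's 18.5 mm
length; real specimens vary in membrane length, so no cross-consistency
between percent coverage and absolute depth is asserted for read-in
coordinate sets.  For CSV tracks the mid-modiolar axis must be supplied as
two points (`align_to_modiolar_axis`); template registration is out of
scope.

## Place-frequency map

The octave form uses the species constant 2.59 mm/octave with an anchor
`f_base = 33.6 kHz` at the basal origin — a calibration chosen so a
5.34 mm depth maps near 8.04 kHz, not a measured species constant.  The
Greenwood form uses standard guinea-pig values `A = 0.35 kHz, a = 2.1,
k = 0.85` over 18.5 mm; its local slope at mid-basal positions agrees with
2.59 mm/octave within 10%, which the suite verifies analytically.

## Statistics

Wilcoxon signed-rank: zeros dropped (Pratt available), ties mid-ranked,
exact sign-flip distribution for n ≤ 15 (computed by a generating-function
convolution equivalent to full enumeration, verified against a brute-force
oracle), normal approximation with tie and continuity corrections above.
Mann–Whitney: exact enumeration of all labelings for n+m ≤ 12, normal
approximation otherwise.  Per-frequency tests use α = 0.05 with no
multiple-testing correction, matching the study design (Holm is available
behind a flag).  "Hearing loss at 5.6 kHz" is evaluated at the lattice
frequency 5657 Hz.  The per-ear "maximal hearing loss" used in the
depth regression is the maximum over frequencies (switchable in
principle to a fixed frequency; the maximum is the default reading).

## What the generator does and does not emulate

The synthetic data reproduce the *measurement chain* and the
threshold-domain consequences of insertion trauma.  They do not model
summating potentials, auditory-nerve neurophonic, middle-ear transfer,
speaker calibration, CAP amplitude saturation, latency-based diagnostics,
or any non-monotone high-frequency recovery of thresholds: the logistic
trauma profile is non-decreasing in frequency by construction, so in
synthetic cohorts significant shifts extend from ~4.7 kHz all the way to
32 kHz, whereas animal data concentrate significance in a mid-frequency
band.  Passing tests therefore demonstrate correctness of the estimators
and pipeline on data with known ground truth, not fidelity of the
generator to every feature of real recordings.

## Problem sizes

The default cohort (24 ears × 3 conditions × 17 frequencies × 10 levels ×
2 polarities, 2 500 samples per trace) simulates and analyses in a few
seconds; the test suite uses the full default cohort for the acceptance
checks, 6–8-ear cohorts for recovery properties, and 200 replicate null
cohorts for the type-I-error calibration of the Wilcoxon test.
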