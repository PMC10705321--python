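# Methods

## Camera forward model

A pixel's response to incident brightness `B` (per channel) is modeled as

```
raw   = gain · B + zlo + ε,   ε ~ N(0, noise_sd²)
raw   = max(raw, 0)
pixel = clip( round( tone(raw / m) · m ), 0, m ),   m = 2^bit_depth − 1
```

* **Threshold mechanism.** Only the fitted negative intercept of the
  supra-threshold response is observable on real phones; the physical
  mechanism is not. The floor-then-linear form `max(0, gain·B + zlo)`
  is the simplest model that reproduces that signature exactly: readings
  are 0 below the threshold and track a line of intercept `zlo` above it.
* **Pipeline order.** Sensor (linear + offset + noise + floor) →
  normalize → tone map → rescale → round → clip. ISPs tone-map after
  sensor readout; the order matters only in that the offset must precede
  the tone curve for the automatic setting to distort it.
* **Quantization** is round-half-to-even at 8 bits (default).
* **Noise** is additive Gaussian read noise, truncated implicitly by the
  0/255 clip and seeded for reproducibility. Shot noise is omitted: the
  method under study is about systematic distortions, and nothing in the
  validation depends on the noise family.

### Tone curves

* `LINEAR` — identity; the CONTRAST_CURVE setting with control points
  (0,0), (1,1).
* `SRGB` — the standard transfer `12.92·L` below the breakpoint, else
  `1.055·L^(1/2.4) − 0.055`. The breakpoint is placed at the exact
  intersection of the two branches (0.0031306684425…) rather than the
  commonly quoted rounded 0.0031308, which leaves a ~3·10⁻⁸ jump; the
  exact breakpoint makes the curve continuous to machine precision and
  its closed-form inverse an exact round trip.
* `AUTOMATIC_SHIFTED_SRGB` — surrogate for the adaptive default mode
  ("FAST"), which is a black box: `srgb(clip((x − shift)/(1 − shift)))`
  with a scene/device parameter `shift ∈ [0, 0.5]`. This is a modeling
  conjecture, not a validated reconstruction of any vendor algorithm;
  conclusions about the automatic setting are conclusions about this
  surrogate.

## Bench emulation

Brightness is PWM duty fraction × full scale. Full scale is 250
brightness units so a unit-gain camera reads ≈250 at 100% duty — the
pixel pre-selection level that maximizes dynamic range without
saturation. PWM itself (MHz-scale in hardware) is abstracted to its
duty-cycle mean; rolling shutter, demosaicing, auto-exposure/white
balance and video compression are out of scope (the recommended capture
settings disable or avoid them).

* **Calibration sweep** — 101 equally spaced levels from 0 to full
  scale, 3 frames per level (1 in the noiseless acceptance run).
* **Pulse protocol** — 100 DC/AC combinations; target RoR drawn
  uniformly on [0.5, 2.0] (the operating range of pulse oximeters); DC
  per channel uniform on [0.2, 0.7]·FS; green AC uniform on
  [0.05, 0.25]·FS; the red AC is solved in closed form so the commanded
  RoR equals the target exactly (with `q = target·AC₂/(AC₂+DC₂)`,
  `AC₁ = q·DC₁/(1−q)`); infeasible draws (negative AC or peak above
  full scale) are rejected and redrawn. Each combination renders as 5
  square pulses (300 ms peak plateau) separated by 100 ms gaps at trough
  level, at one frame per 30 ms. Square pulses suffice because the
  analysis uses only max/min per segment. All combinations have equal
  frame counts so segment boundaries align with combination boundaries.

## Calibration

Ordinary least squares of pixel on brightness, after dropping floored
(pixel ≤ 0) and near-saturated (pixel ≥ 250) readings — floored points
would drag the intercept toward zero under the threshold model, and the
fit should see only the linear window. No robust estimator: the data are
bench recordings with no outlier mechanism. Repeated sweeps (or the red
and green channels of one sweep) are aggregated as the mean of per-fit
intercepts. The study uses one scalar ZLO per phone model, applied to
both wavelengths, matching how the correction is used in practice (a
shared per-model lookup table ships with the package).

Noiseless recovery is exact to within quantization (±0.5 pixel over a
101-step sweep); at noise_sd = 1 the intercept's sampling error stays
within ±1.5 pixel.

## RoR pipeline

Traces are cut into `n_segments` equal contiguous segments (tail
remainder dropped). Within a segment, pulse plateaus are frames above
the segment midrange (mean of max and min) — segment boundaries align
with the protocol, so no physiological pulse detection is needed. The
first and last plateau (and everything outside them) are discarded;
peak = max and trough = min of the remaining frames; AC = peak − trough,
DC = trough, per channel. Segments with DC = 0 in either channel are
discarded. A seeded uniform sample without replacement selects the
segments used for statistics (50 of 100 by default); the same selection
is used for all capture settings of a device so comparisons stay paired.

Degenerate inputs: a flat channel yields AC = 0 with DC at its constant
level; fewer than 3 detectable plateaus is an error (nothing remains
after the first/last discard); ties for max/min are irrelevant because
only the extreme values are used.

## Evaluation

MAE, R² (squared Pearson correlation of calculated vs. true RoR — a
y = x residual definition would go negative for a setting with a strong
multiplicative distortion despite high correlation, which is not what a
correlation analysis reports), and Bland-Altman bias with 1.96·SD limits
of agreement (sample SD, n−1). Paired comparisons are two-sided paired
t-tests on per-segment absolute errors, with percent error reduction
relative to the baseline setting; p-values are reported raw. All
statistics are cross-checked in the tests against brute-force
re-implementations (1e−12) and, for the t-test at n = 8, against an
exhaustive 256-relabeling sign-flip permutation.

## Study driver and conditions

Per device: capture the sweep under the linear curve and fit the ZLO;
render the pulse protocol once and capture it twice (automatic and
linear curves — replaying identical commanded signals); analyze; select;
compare three settings (Default automatic via Eq. 1, Uncalibrated linear
via Eq. 1, Calibrated linear via Eq. 2 with the fitted ZLO) against
ground truth. Everything is seeded: each device draws noise from streams
derived from its seed, and the protocol and selection have their own.
Reports carry a config hash.

The default study simulates the four characterized phone models with
their tabulated offsets (−22.5, −14, −19.6, −14.9), read noise
SD = 1 pixel, and automatic-curve shifts {0.05, 0.10, 0.15, 0.12}
spread over a plausible adaptation range without flooring typical DC
levels. These are the declared study conditions; they are not tuned.

## What the simulation does and does not show

The generator reproduces the *structure* of the bench validation:
controlled DC/AC levels with exactly known RoR, quantization, a sensor
threshold, and tone-map distortion. It does not reproduce physical
sensors: real photon/read noise spectra, the true adaptive tone-map
algorithm, LED spectral bleed, or finger physiology. Passing tests
therefore establish that the calibration math is correct and that the
qualitative ordering (calibrated linear < uncalibrated linear <
automatic, in error) holds under these conditions — not that any
particular published error magnitude transfers to hardware.

Known limitations: the automatic-mode surrogate is a conjecture; the
square-pulse protocol cannot probe waveform-shape effects; one global
ZLO per model ignores possible per-channel differences; max/min feature
extraction inflates AC slightly under noise (extreme-value bias), which
affects all settings identically and so cancels from the comparisons.
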