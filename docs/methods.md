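# Methods

## Signal model

A well photographed in a lightbox is summarized by channel means over a
central circular ROI. The analytical signal *y* for channel *k* is assumed
affine in analyte concentration *c* (% w/w) inside a linear dynamic range:

    y_k(c) = a_k + b_k · c,    c ∈ [c_lo, c_hi]

Below `c_lo` the response flattens: the hypochlorite oxidant is no longer
limiting, so the residual methyl-red color stops tracking urea. This
clipping is the single mechanistic feature the package models explicitly;
reaction kinetics (chloramine formation, fading over time) are out of
scope and appear only as capture metadata.

HSB channels follow the ImageJ convention (all planes scaled 0–255) and
are averaged **per pixel**, not computed from the mean RGB color. The
distinction is load-bearing for saturation: a strongly colored but
heterogeneous ROI keeps its per-pixel saturation, whereas the saturation of
the averaged color collapses toward gray. Hue uses an arithmetic (not
circular) mean; hue is excluded from channel selection a priori because it
shows no linear concentration dependence for this chemistry, so wrap-around
is a documented, inconsequential limitation.

## Plate reading

Well centers start from a configured grid (rows, cols, pitch, first
center) and are refined to the intensity-weighted centroid of
(255 − brightness) in a window of half-width pitch/2; the colored well is
darker than the white strip, so the centroid tracks the well. The window is
a full half-pitch because a quarter-pitch window can sit entirely inside a
well and then carries no correction signal; the shift is bounded to
±0.25·pitch so refinement can never jump to a neighbor. ROIs are discs of
radius 25 px by default (~1963 px², within the 1500–2200 px² band that
keeps the ROI clear of reflective well edges at the assumed capture
geometry); the area band is enforced.

Glare/bubble masking is per pixel: brightness ≥ 250, or any channel more
than 3.5·1.4826·MAD from the ROI channel median (a robust z-score ≈ 3.5;
uniform channels with zero MAD contribute no criterion). Wells with more
than 30 % of the ROI masked are rejected outright — beyond that the
"central area" is no longer representative. Masking is idempotent on the
fixtures it is designed for (uniform field + saturated artifact), though
not guaranteed to be in general, since remasking recomputes the median/MAD
over survivors.

## Calibration and linear dynamic range

Fits are ordinary least squares (via `scipy.stats.linregress`), R²
computed as 1 − SSE/SST. Replicate standards enter as individual points.
Blanks (0 % w/w) never join calibration fits — they sit below any valid
range — but remain available as diagnostics.

The linear range is determined by an explicit, configurable rule rather
than by eye: starting from all standards, fit, back-calculate every
standard, and while R² < 0.98 or any |back-calc bias| > 15 %, drop the
standards at the lowest retained concentration if that endpoint violates
the bias limit, otherwise the highest; stop when both criteria pass or
fewer than three standards remain. Low-first trimming reflects where this
chemistry actually fails (low-end clipping). The 15 % default is the
conventional acceptance at the quantification limit, separating biases the
assay tolerates (~10 %) from clip-induced ones (~30 %+).

Back-calculation flags results outside the linear range with an asymmetric
tolerance: 10 % of the range width above the top (mild extrapolation of a
still-linear response) but only 10 % of the lower limit below the floor,
because the response is *known* to be nonlinear there.

Channel selection keeps candidates with R² ≥ 0.98, restricts to those
whose linear range span ties the widest, and returns the steepest |slope|
(the most sensitive channel). On the reference-cream response this picks
saturation ahead of blue, matching practice.

## Quantification

Direct: replicate signals are averaged, then inverted through the
same-photo curve. Standard addition: the addition line y = a + b·x is fit
by OLS over all aliquots (an unspiked x = 0 aliquot is included when
measured — harmless under the model and it stabilizes the intercept), and

    c0 = c_ref + (a − y_ref)/b

extrapolates to a nonzero in-matrix reference standard measured in the
same photo (the design type deliberately carries no cross-photo option).
Replicate reference wells are averaged. With c_ref = 0 and y_ref equal to
the zero-analyte signal this reduces to the classical intercept
extrapolation; the nonzero reference keeps the extrapolation inside the
validated range. Estimates keep full precision; rounding happens only in
report formatting.

## Validation statistics

CV% uses the sample (n−1) standard deviation — standard for small-n method
validation. Per-level bias is computed from the mean of replicate
estimates (identical to averaging per-replicate biases, but pinned for
reproducibility). The report records per-run calibration R² and range, and
overall maxima/minima.

## The simulator

The simulator renders what the pipeline consumes, parameterized directly
by the per-channel response lines (blue 128.19 − 3.009·c clipped below
2.52 % w/w and above 30.03; red 187.04 − 0.255·c and green 171.90 −
0.452·c clipped below 8.1 % w/w) rather than by reaction kinetics, for
which no rate constants are available. Saturation/brightness responses are
emergent from the rendered RGB, not separately parameterized; emergent
saturation is linear with R² ≥ 0.98 over the unclipped range but its slope
is not forced to any particular value. Matrix presets vary only the linear
range and background tint (an opaque color-free cream narrows the top of
the range; a light-brown shampoo tints the background), a qualitative
stand-in for matrix effects.

Noise enters at three levels chosen to reproduce the two behaviors that
matter analytically:

- per-pixel Gaussian noise, sd 6 intensity units — large ROIs (~2000 px)
  average it to ≈ 0.13 units, so pixel noise is nearly irrelevant;
- per-well multiplicative gain, sd 1 % — local illumination/fill
  variation; this dominates the single-well error budget;
- per-run multiplicative gain, sd 5 %, shared by all wells of a photo —
  photo-to-photo illumination; in-photo calibration cancels it, which is
  why standards and samples must share the photo.

Gain draws are clamped to [0.6, 1.3], standing in for the camera's
automatic exposure: however much ambient light varies, a usable photo is
never grossly over- or under-exposed. Quantization to 8 bits is dithered
(floor(v + U[0,1)) per pixel), making the quantizer unbiased the way real
sensor noise does; without dither, uniform noiseless wells would carry a
systematic rounding offset of up to 0.5 LSB. Glare discs and bubble rings
are simple parametric shapes, sufficient to exercise masking;
photorealism is a non-goal. All draws flow from one seeded generator in a
fixed order (unconditional draws, scaled), so identical inputs give
byte-identical images and different noise settings remain pairwise
comparable at the same seed.

What the simulator does **not** emulate — illumination gradients across
the strip, emulsion texture, specular physics, time-dependent fading,
rgb-average fit idiosyncrasies (the rendered rgb_mean slope is exactly the
mean of the three channel slopes, which need not match a separately fitted
empirical rgb line) — bounds what passing tests show: they validate the
computational pipeline against its stated model of the data, not the wet
assay itself.

## Problem sizes and numerical choices

Simulated studies use one-row strips (pitch 70 px, well radius 30 px, ROI
radius 25 px), seven calibration standards at {2.52, 6.03, 10.07, 18.13,
23.32, 27.21, 30.03} % w/w per photo, six QC levels at {6.03, 10.07,
18.13, 23.32, 27.21, 30.03} % w/w, and 7–8 runs per study — the scale of a
realistic validation campaign for this assay, small enough that every
example and test runs in seconds. Degenerate inputs fail loudly: SST = 0
fits, zero-slope inversions, ROIs with fewer than 100 usable pixels, plate
map/layout mismatches and unknown config keys all raise typed errors
rather than propagating NaNs.

## Known limitations

- Arithmetic hue averaging (see above); hue is never the analytical
  channel.
- No weighted/robust regression, no LOD/LOQ estimation beyond the linear
  range's lower bound, no uncertainty propagation onto c0.
- No flat-field or perspective correction; mild shared gradients are
  absorbed by in-photo calibration, strong ones are out of scope.
- The linear-range trimming rule is an explicit procedure with documented
  defaults, not a claim about how any particular laboratory chose its
  printed range endpoints.
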