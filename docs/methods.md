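# Methods

This note records the numerical methods, conventions and default parameters
used by `camwall`, with the reasoning behind each choice.

## Synthetic vessel model

A vessel is a tube around a polyline centerline (parent plus, optionally, two
daughters forming a bifurcation; daughters continue the parent's arclength so
along-vessel quantities run continuously through the branch point). All
geometry is specified in micrometres.

**Radius waveform.** The local radius is `R(s) · m(t, s)` with

```
m(t, s) = 1 + Σₖ aₖ cos(2π k f · w(t) + φₖ(s))
```

where `f` is the fundamental (heart-rate) frequency, `aₖ` are fractional
harmonic amplitudes (their sum must stay below 1 so the lumen never
collapses), and `φₖ(s)` is either constant or varies linearly with normalized
arclength — the mechanism for imposing an along-vessel phase gradient of the
kind seen near bifurcations. A harmonic can optionally be gated on from a
chosen onset time, to model a component that strengthens partway through a
recording.

**Waveform asymmetry.** Arterial pulsation rises faster than it relaxes. The
time warp

```
w(t) = t − (β / 2πf) · (1 − cos 2πf t),   0 ≤ β < 1
```

preserves the period (`w(t + 1/f) = w(t) + 1/f`), keeps `w` monotone
(`w′ = 1 − β sin 2πf t > 0`), and concentrates the upstroke of the cosine into
a shorter time span than the downstroke. A warp of the form
`t − c·sin(2πf t)` would *not* work: the resulting waveform is still
time-symmetric about its peak, so mean ascending and descending slopes stay
equal and no asymmetry signature can be produced. The cos-based warp was
chosen for exactly this reason.

**Rigid translation.** Lateral wall motion is modeled as a whole-tube offset
`A cos(2πf w(t))` along a fixed direction (0° = +columns, 90° = −rows).

**Rendering.** Each pixel takes the value

```
I = I_vessel + (I_bg − I_vessel) · Φ(ρ / σ_psf)
```

where `ρ` is the signed distance from the pixel center to the moving vessel
surface (negative inside) and `Φ` is the standard normal CDF. This is the
*exact* profile of an ideal step edge convolved with a Gaussian PSF of width
`σ_psf` — a logistic profile looks similar but is not the PSF-convolved step
and misses the quantized background level near ±5σ. Additive Gaussian sensor
noise is seeded per frame from `(rng_seed, frame_index)` so any frame is
reproducible in isolation, then the image is quantized to 8 bits.

**Defaults** (chosen once, as representative acquisition/physiology, before
any analysis of results): 120 Hz frame rate, 3 s duration (360 frames),
2.4 µm/pixel, vessel gray 60 on background 180, `σ_psf` = 8 µm, noise σ = 1
gray level, baseline radius 50 µm, fundamental 3.2 Hz, harmonic amplitudes
0.06 / 0.03. These give wall displacements of a few µm — small but resolvable
at the default pixel pitch.

## Boundary detection

Frames are binarized with dark-vessel polarity (`pixel < threshold`); Otsu's
method supplies a threshold when none is given. Each 8-connected object's
outer contour is walked clockwise with Moore-Neighbor tracing: from the
current pixel, neighbors are scanned clockwise starting just past the
backtrack pixel; the first foreground neighbor becomes the next contour
pixel.

Two implementation details matter:

- **Termination** uses Jacob's criterion in its robust state-repetition form:
  the walk stops when the (pixel, backtrack-direction) state repeats. The
  textbook "re-enter the start pixel moving in the original direction" form
  can fail to fire on one-pixel-wide objects when the synthetic entry
  direction never reoccurs.
- **Inner corners.** A diagonal step of the clockwise walk can cut across a
  foreground pixel that touches the background only at that corner (e.g. the
  junction pixel of a T shape). Such pixels belong to the boundary-pixel set
  (object pixels not interior to the filled silhouette) but the classic walk
  skips them, so a diagonal step additionally records the foreground pixel on
  the corner it cuts. Consecutive trace points remain 8-adjacent, and the
  traced set equals the brute-force boundary definition (validated against
  random masks in the test suite).

**Cardiac phases.** A brightness time series from a high-motion pixel (or
line ROI) is detrended; the period comes from the dominant FFT peak (rejected
if below 3× the median spectral floor). After light smoothing (~period/10
moving average) local extrema at least 0.6 period apart are labeled systolic
or diastolic — for a dark vessel dilating at systole, brightness minima are
systolic. The peak-systolic and late-diastolic boundaries are superimposed on
the late-diastolic frame (diastolic solid, systolic dotted).

**Displacement convention.** The waveform swings the wall by ±a₁R about its
baseline, so the peak-systole ↔ late-diastole boundary separation is `2·a₁R`.
The *wall displacement amplitude* reported by `camwall.measure` is therefore
half the symmetric mean nearest-neighbor distance between the two traces
(frame-border pixels excluded — they are the cut where the vessel leaves the
field of view, not moving wall). Likewise the translation amplitude is half
the centroid shift between the congruent traces.

## Spectral maps

Each pixel's series is linearly detrended (removing mean and slow drift) and
transformed with an FFT zero-padded to 4× the record length. Padding refines
the frequency grid (1/12 Hz for 360 frames at 120 Hz) for peak *reporting*;
it adds no resolution. Coefficients are normalized by the source length `T`
so an on-bin unit cosine has one-sided magnitude 1.

The fundamental is chosen once per video: among the top-decile-RMS pixels,
each pixel with a substantial in-band peak (>10% of the strongest; a 1–8 Hz
band covers embryonic heart rates) votes for its peak bin, and the modal bin
wins — one heart rate per recording, robust to isolated noisy pixels. The
second harmonic is read at the bin nearest twice the fundamental.

Per-pixel maps: RMS amplitude (motion strength), fundamental and
second-harmonic one-sided magnitudes, their percentage ratio, and the phase
angle `atan2(Im, Re)` of the fundamental coefficient mapped into (−180°,
180°]. Ratio and phase are reported inside a mask of pixels whose RMS is
within 6 dB of the maximum (configurable), i.e. the moving wall. The phase
histogram (5° bins) separates motion types: dilation puts both walls in phase
(one mode); rigid translation brightens one wall while the other darkens (two
modes ~180° apart).

A video with no temporal variation at all (max RMS below 10⁻⁹ gray levels,
the detrending-roundoff floor for 8-bit data) yields an explicitly invalid
map set rather than noise-driven maps.

## Wavelet scalograms

The mother wavelet is the real Morlet `ψ(x) = exp(−x²/2) cos(5x)`. Its
dimensionless center frequency is taken from the spectral peak of ψ sampled
on its [−8, 8] support (1024 points): the bins of that 16-unit window fall at
multiples of 1/16, putting the peak at 13/16 = **0.8125**, the conventional
value slightly above the analytic carrier 5/2π ≈ 0.7958. Scales convert to
pseudo-frequencies via `f = Fc · fs / scale`; at 120 Hz, scale 30.5 ↔ 3.2 Hz
and scale 15.2 ↔ 6.4 Hz.

The CWT coefficient at scale `a` and shift `b` is the direct sum
`Σₜ x[t] ψ((t−b)/a) / √a` with zero extension beyond the record and the even
kernel truncated at |x| = 8, where the Gaussian envelope is ~10⁻¹⁴ (so the
truncation error is far below the 10⁻⁶ oracle tolerance). Each scale carries
a cone-of-influence margin of ⌈8a⌉ samples; `Scalogram.valid_mask()` marks
coefficients whose support lies fully inside the record, and time-localization
statements (e.g. "the second harmonic appears in the second half") are made
only over valid coefficients.

## Problem sizes and runtime

The test suite renders 128×128 × 360-frame videos (~1 s each) and computes
full map sets in ~2 s; the complete suite runs in well under a minute on one
CPU. The CLI defaults (256×256) scale linearly in pixel count.

## Limitations

The synthetic model emulates geometry, first-order optics and sensor noise —
not blood-cell texture, flow-dependent lumen contrast, focus drift,
illumination flicker, or out-of-plane motion. Analysis assumes one dominant
heart rate per recording and dark vessels on a bright background; phase-map
interpretation assumes the 6 dB mask isolates the wall. Boundary tracing
operates on a single global threshold per frame; vessels with strong
longitudinal contrast gradients may need per-region thresholds upstream.
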