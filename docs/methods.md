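# Methods

## Signal model

A dual-illumination acquisition is modelled per pixel and per frame as

    frame_i = w · m_w[i] + u · m_f[i] + c + ε_i

where `w` and `u` are the clean white-light reflectance and fluorescence
emission (both in [0, 1]), `m_w` and `m_f` are unipolar {0, 1} square
gates at the two modulation frequencies, `c` is a constant ambient offset,
and `ε_i ~ N(0, σ²)` is i.i.d. Gaussian sensor noise. All quantities are
on the [0, 1] float scale; the "noise level" quoted in tables is σ.

Assumptions baked into this model, and therefore into what the tests can
show: the scene is static over the integration window (frames are exact
copies), modulation is perfectly synchronous with the camera (both gates
start high at frame 0 unless a phase offset is configured), illumination
switches instantaneously (ideal square waves), and noise is additive,
white, signal-independent and unclipped. Real acquisitions violate all of
these to some degree — motion, source rise times, rolling shutters,
photon (Poisson) noise, saturation — and none of that is modelled. The
phantom generator is a correctness and calibration harness, not a camera
simulation.

## Demodulation

The demodulator correlates the stack against a bipolar ±1 reference `r` at
the channel frequency and scales by `2/n`:

    ĝ = (2/n) Σ_i frame_i · r_i

Implementation is the streaming add/subtract form (add the frame when
`r_i = +1`, subtract when `r_i = −1`, one pass, no per-pixel multiplies);
a test verifies bit-for-bit equality with the naive multiply-accumulate
oracle, which holds because multiplying by ±1.0 and negating are exact in
IEEE arithmetic and the accumulation order is identical.

Why `2/n`: over one period the unipolar gate and the bipolar reference
agree on half of the "on" samples, so `Σ m·r = n/2` and the scaling
returns the channel image in its native units, directly comparable to the
clean scene in the MSE/SNR metrics.

Enforced preconditions: the window must be a whole number of periods
(otherwise the zero-sum and orthogonality identities break and DC/
cross-channel signal leaks; a `trim` option drops trailing frames to the
largest whole common period instead), the reference must be bipolar with
unit amplitude, and dual-channel operation requires a frequency ratio of
exactly 2 — square waves at odd ratios share odd harmonics, so their
references are not orthogonal (ratio 5 is the canonical counterexample,
caught by `check_orthogonal`).

The low-pass filter is a boxcar integrator over the window. No IIR/FIR
filtering is attempted: the boxcar matches the integrator model, makes the
noiseless round trip exact, and gives the closed-form noise law below.

### Phase handling

Square-on-square correlation has a triangular phase response,
`u₀(φ) = WA(1−2φ/π)` on `[0, π]` and `WA(2φ/π−3)` on `[π, 2π)`; the open
interval endpoints are taken as branch limits (the function is continuous).
The standard pipeline assumes frame 0 is aligned with the reference high
phase. For unknown-phase stacks, `demodulate_iq` correlates against the
reference and its quarter-period-delayed copy; the quadrature shift is an
exact whole-sample cyclic delay, using the same sign convention as the
wave's own `phase_offset_samples` field (positive = delay). Amplitude is
estimated as `|I| + |Q|`, which is exact at every whole-sample offset for
the triangular response (the Euclidean `√(I²+Q²)` — appropriate for
sinusoidal references — is available as an option but under-reads between
the cardinal phases). Phase is recovered by piecewise-linear inversion of
the triangle: the sign quadrant of `(I, Q)` selects the phase quadrant and
`|·|/(|I|+|Q|)` interpolates within it; zero-amplitude pixels are assigned
phase 0 by convention.

## Noise law and the 7 dB figure

The demodulated error is `(2/n) Σ ε_i r_i`, with variance

    Var = (4/n²) · n σ² = 4σ²/n .

The single-frame baseline has error variance σ², so the SNR gain is
`10·log10(n/4)` dB — independent of σ and of the scene. The default
single-channel window of **20 frames** (5 periods at 4 samples/period) is
chosen precisely because `10·log10(5) = 6.99 dB`, the improvement the
study tables are built around; the dual-channel default of **24 frames**
(3 common periods of the 6 Hz channel at 48 fps, since 20 is not a whole
multiple of its 8-frame period) has a theoretical gain of 7.78 dB and is
labelled as such wherever it is offered.

## The study (table reproduction)

For each channel and each noise level σ ∈ {0.01, 0.05, 0.1, 0.15, 0.2,
0.25, 0.3}: render the clean single-channel stack once, then for each of
20 independent noise realizations add noise, demodulate, and score against
the clean channel image; the comparator is a single noisy full-
illumination frame (the time-sharing baseline). Reported values are means
over realizations. In this single-channel study each channel is modulated
at 4 samples per period (fs = 4f) — the per-channel protocol with the
other source off — because the 20-frame window cannot hold whole 8-frame
periods. Default problem size: 256×256 phantom, 2 channels × 7 levels ×
20 seeds (≈6 s on one CPU); sizes are configurable and the statistics are
scale-free.

Seeding: one master seed feeds a `numpy` `SeedSequence`; per-channel
spawn keys and one spawned child per (level, realization) keep all noise
streams independent and the whole study reproducible from a single
integer.

Expected structure, all verified by tests: the improvement column is
6.99 dB at every level for both channels; the baseline column falls
exactly 20 dB per decade of σ (for a fixed seed the noise field scales
linearly with σ, so the ratio is exact, not just in expectation); absolute
SNR columns depend on the phantom's `I_original` and are reported but not
treated as reference values, since they are scene-specific.

## Phantom generator

The `letters` style renders four block glyphs (5×7 bitmaps, scaled) on a
textured bright field with a mild illumination gradient, and marks the
first two letters as fluorescent — emulating a resolution-target scene
with dye applied to part of it. Values were fixed once so that the
bright-field mean squared intensity is ≈0.5 (giving a baseline SNR near
37 dB at σ = 0.01, the scale of a realistic reflectance scene); the
fluorescent letters sit at ≈0.8 emission on a zero background. A
`geometric` style (smooth field + fluorescent disc) exists for tests that
want simpler structure. Generation is deterministic in (shape, style,
seed) and dependency-free beyond `scipy.ndimage` smoothing.

Noisy pixels are **not** clipped to [0, 1] by default: clipping would
break the exact σ² baseline law and bend the improvement column at high σ,
which is inconsistent with the flat ~7 dB structure the study reproduces.
A `clip` option models a saturating sensor when wanted.

## Numerical choices and degenerate cases

- Whole-period windows are errors, not silent truncation; `trim` is
  explicit.
- `SNR` of a perfect reconstruction returns `+inf` (flagged in reports)
  rather than a large number; the all-zero 0/0 case raises.
- Orthogonality checks accumulate the ±1 sign products in integer
  arithmetic, so "exactly zero" is exact.
- Exactness tolerances: noiseless round trips are asserted at ≤1e−9 per
  pixel (they hold to ~1e−15; the slack covers accumulation order), and
  Monte-Carlo variance checks use 100 realizations with 5% relative
  tolerance (sampling error ≲1%).
- Stacks on disk are float32 TIFF (lossless for this data's precision
  needs) or 16-bit PNG with the linear scale recorded in the sidecar.

## Limitations

No optics (PSF, vignetting beyond the phantom's cosmetic gradient), no
Poisson noise, no motion or flicker, no hardware trigger model. The
package can demodulate user-supplied real stacks in either file dialect,
but agreement with any particular instrument's SNR figures depends on
that hardware and is outside what the synthetic tests establish.
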