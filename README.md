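# framelock

Fast digital lock-in demodulation of frequency-division-multiplexed image
frame stacks, with a synthetic phantom simulator and image-SNR evaluation.

## The problem

Fluorescence-guided endoscopy needs two images at once: a bright-field
(white light) view and a near-infrared fluorescence view of dye-labelled
tissue. Conventional systems *time-share* the two light sources, which
halves the usable frame rate and leaves each channel's single frame fully
exposed to sensor noise — a real problem for the weak fluorescence signal.

The alternative implemented here is **frequency-division multiplexing**:
both sources are driven by 50%-duty-cycle square waves at different
frequencies (white at `f_w`, near-infrared at `f_w / 2`; defaults 12 Hz and
6 Hz with a 48 fps camera), so a single camera stream carries both channels
simultaneously. A **fast digital lock-in** demodulator then recovers each
channel by correlating the pixel time series with a bipolar ±1 reference at
that channel's frequency. Because the reference only takes the values ±1,
the correlation needs no multiplications: frames where the reference is +1
are added, frames where it is −1 subtracted, and the accumulator is scaled
once by `2/n`. This requires the camera to sample at `4k` times each
modulation frequency (integer `k`), which also makes the 90° quadrature
reference an exact whole-sample shift.

## The model

For a stack of `n` frames (a whole number of modulation periods), the
demodulated image of a channel with clean image `f` and unipolar on/off
gating `m` is

    ĝ = (2/n) Σ_i frame_i · r_i ,   r_i ∈ {+1, −1}

which returns `f` exactly in the noiseless case, rejects any constant
ambient offset (the reference sums to zero), and rejects the other channel
exactly (references at frequency ratio 2 are orthogonal over whole common
periods). For additive i.i.d. Gaussian pixel noise of standard deviation σ
the demodulated error variance is `4σ²/n`, so relative to a single-frame
baseline the SNR gain is `10·log10(n/4)` dB — **6.99 dB for the default
20-frame window**, at every noise level.

Square-on-square correlation has a *triangular* phase response
`u₀(φ) = WA(1 − 2φ/π)` on `0 ≤ φ ≤ π` (and `WA(2φ/π − 3)` on the second
half-period), so for unknown-phase stacks the amplitude estimator is
`|I| + |Q|` (exact for the triangle, unlike `√(I²+Q²)`) with the phase
recovered by piecewise-linear inversion.

Image quality is scored as `SNR = 10·log10(I_original / MSE)` with
`I_original` the mean squared intensity of the clean reference image and
`MSE` the mean squared error of the reconstruction against it.

## Worked example

```python
from framelock import ExperimentConfig, reproduce_tables, tables_by_channel

df = reproduce_tables(ExperimentConfig(), seed=1)
for ch, t in tables_by_channel(df).items():
    print(ch); print(t.round(2).to_string()); print()
print('grand mean improvement: %.2f dB' % df.improvement_db.mean())
```

prints

```
fluor
noise level                    0.01   0.05  0.10  0.15  0.20  0.25  0.30
after lock-in image SNR/dB    29.78  15.80  9.77  6.25  3.75  1.82  0.23
without lock-in image SNR/dB  22.78   8.80  2.78 -0.74 -3.23 -5.18 -6.76
SNR improvement/dB             7.00   6.99  6.99  7.00  6.98  6.99  6.99

white
noise level                    0.01   0.05   0.10   0.15   0.20   0.25   0.30
after lock-in image SNR/dB    43.91  29.91  23.89  20.38  17.88  15.94  14.36
without lock-in image SNR/dB  36.91  22.92  16.91  13.39  10.89   8.95   7.37
SNR improvement/dB             7.00   6.99   6.98   7.00   6.99   6.99   6.99

grand mean improvement: 6.99 dB
```

Each column is one noise level σ (Gaussian, on [0,1]-scaled pixels); the
rows are the mean SNR of the 20-frame lock-in reconstruction, the mean SNR
of a single noisy frame, and their difference, averaged over 20 noise
realizations on a 256×256 phantom. The improvement sits at the theoretical
`10·log10(20/4) = 6.99` dB independent of the noise level, and the
baseline row falls 20 dB per tenfold increase in σ (MSE₀ = σ²).

The same machinery is available as modelling objects and a CLI:

```python
from framelock import LockInDemodulator, ModulationConfig, make_phantom, simulate_stack, add_noise

scene = make_phantom((256, 256), "letters", seed=0)
stack = add_noise(simulate_stack(scene, ModulationConfig()), 0.1, seed=1)
res = LockInDemodulator(stack).fit()
print(res.summary())          # channels, window, theoretical gain
res.save("demodulated/")      # float TIFFs + JSON sidecar
```

```sh
framelock simulate --out stack.tif --noise-sigma 0.1 --seed 0
framelock demodulate stack.tif --out demod/
framelock reproduce-tables --out tables.csv
framelock fuse --white demod/white.tif --fluor demod/fluor.tif --out overlay.png
```

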