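"""The fast lock-in demodulator: recovery, orthogonality, noise law, phase."""

import math

import numpy as np
import pytest

from framelock import (
    FrameStack,
    ModulationConfig,
    PhantomScene,
    SquareWaveSpec,
    add_noise,
    demodulate_in_phase,
    demodulate_iq,
    demultiplex_dual,
    noise_error_variance,
    phase_response,
    simulate_stack,
    square_wave,
)
from framelock.lockin import invert_phase_response


def naive_demodulate(stack, spec):
    """Independent oracle: per-frame multiply-accumulate with the +/-1
    reference, then scale by 2/n."""
    n = len(stack)
    ref = square_wave(
        SquareWaveSpec(spec.samples_per_period, n, spec.phase_offset_samples)
    )
    acc = np.zeros(stack.frame_shape)
    for i in range(n):
        acc += ref[i] * stack.frames[i]
    return acc * (2.0 / n)


def constant_stack(value, n_frames, period, shape=(4, 4), phase=0, ambient=0.0):
    """Unipolar-modulated constant scene, optionally phase-shifted."""
    gate = square_wave(
        SquareWaveSpec(period, n_frames, phase, polarity="unipolar")
    )
    frames = gate[:, None, None] * np.full(shape, value) + ambient
    cfg = ModulationConfig(
        frame_rate=4.0 * period,
        freq_white=4.0,
        freq_fluor=2.0,
        n_frames=n_frames,
        mode="single_channel",
    )
    return FrameStack(frames, cfg)


class TestInPhase:
    def test_constant_scene_recovered(self):
        stack = constant_stack(0.8, n_frames=20, period=4)
        out = demodulate_in_phase(stack, SquareWaveSpec(4, 20))
        np.testing.assert_allclose(out, 0.8, atol=1e-12)

    def test_other_channel_rejected(self):
        # signal modulated at period 8, demodulated with the period-4 reference
        stack = constant_stack(0.8, n_frames=24, period=8)
        out = demodulate_in_phase(stack, SquareWaveSpec(4, 24))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_ambient_only_gives_zero(self):
        frames = np.full((8, 4, 4), 0.3)
        stack = FrameStack(frames, ModulationConfig(n_frames=8))
        out = demodulate_in_phase(stack, SquareWaveSpec(4, 8))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_partial_period_window_rejected(self):
        stack = constant_stack(0.5, n_frames=20, period=4)
        with pytest.raises(ValueError, match="whole number of periods"):
            demodulate_in_phase(stack, SquareWaveSpec(8, 20))

    def test_non_unit_or_unipolar_reference_rejected(self):
        stack = constant_stack(0.5, n_frames=8, period=4)
        with pytest.raises(ValueError, match="bipolar"):
            demodulate_in_phase(stack, SquareWaveSpec(4, 8, polarity="unipolar"))
        with pytest.raises(ValueError, match="amplitude 1"):
            demodulate_in_phase(stack, SquareWaveSpec(4, 8, amplitude=2.0))

    def test_matches_naive_oracle_bit_for_bit(self, rng):
        """The add/subtract fast path equals the multiply-accumulate oracle
        exactly: multiplying by +/-1.0 and negating are both exact in IEEE
        arithmetic and the accumulation order is identical."""
        frames = rng.normal(0.4, 0.3, size=(24, 8, 8))
        stack = FrameStack(frames, ModulationConfig(n_frames=24))
        for period, phase in [(4, 0), (8, 0), (4, 3), (8, 5), (12, 2)]:
            spec = SquareWaveSpec(period, 24, phase)
            fast = demodulate_in_phase(stack, spec)
            np.testing.assert_array_equal(fast, naive_demodulate(stack, spec))

    def test_linearity(self, rng):
        f1 = rng.normal(size=(8, 6, 6))
        f2 = rng.normal(size=(8, 6, 6))
        cfg = ModulationConfig(n_frames=8)
        spec = SquareWaveSpec(4, 8)
        combo = demodulate_in_phase(FrameStack(2.0 * f1 + 3.0 * f2, cfg), spec)
        parts = 2.0 * demodulate_in_phase(FrameStack(f1, cfg), spec) + \
            3.0 * demodulate_in_phase(FrameStack(f2, cfg), spec)
        np.testing.assert_allclose(combo, parts, atol=1e-12)

    def test_offset_invariance(self, rng):
        frames = rng.normal(size=(16, 5, 5))
        cfg = ModulationConfig(n_frames=16)
        spec = SquareWaveSpec(4, 16)
        base = demodulate_in_phase(FrameStack(frames, cfg), spec)
        shifted = demodulate_in_phase(FrameStack(frames + 0.7, cfg), spec)
        np.testing.assert_allclose(shifted, base, atol=1e-12)


class TestPhaseResponse:
    @pytest.mark.parametrize(
        "phi, expected",
        [
            (0.0, 1.0),
            (math.pi / 2, 0.0),
            (math.pi, -1.0),
            (3 * math.pi / 2, 0.0),
            (math.pi / 4, 0.5),
            (2 * math.pi, 1.0),  # periodic wrap
        ],
    )
    def test_unit_triangle(self, phi, expected):
        assert phase_response(1.0, 1.0, phi) == pytest.approx(expected, abs=1e-12)

    def test_scales_with_amplitudes(self):
        assert phase_response(0.8, 2.0, 0.0) == pytest.approx(1.6)

    def test_even_and_periodic(self):
        phis = np.linspace(0.01, 2 * math.pi - 0.01, 57)
        np.testing.assert_allclose(
            phase_response(1.0, 1.0, -phis), phase_response(1.0, 1.0, phis), atol=1e-12
        )
        np.testing.assert_allclose(
            phase_response(1.0, 1.0, phis + 2 * math.pi),
            phase_response(1.0, 1.0, phis),
            atol=1e-12,
        )

    def test_empirical_sweep_matches_closed_form(self):
        """Demodulating a whole-sample phase-shifted noiseless stack lands
        exactly on the triangular response at every offset (period 32)."""
        period, n, W = 32, 32, 0.8
        spec = SquareWaveSpec(period, n)
        for d in range(period):
            stack = constant_stack(W, n, period, phase=d)
            out = demodulate_in_phase(stack, spec)
            expected = phase_response(W, 1.0, 2 * math.pi * d / period)
            np.testing.assert_allclose(out, expected, atol=1e-9)


class TestIQ:
    def test_in_phase_signal(self):
        stack = constant_stack(0.6, 20, 4)
        i_img, q_img, amp, phase = demodulate_iq(stack, SquareWaveSpec(4, 20))
        np.testing.assert_allclose(i_img, 0.6, atol=1e-12)
        np.testing.assert_allclose(q_img, 0.0, atol=1e-12)
        np.testing.assert_allclose(amp, 0.6, atol=1e-12)
        np.testing.assert_allclose(phase, 0.0, atol=1e-12)

    def test_quarter_period_shifted_signal(self):
        stack = constant_stack(0.6, 16, 8, phase=2)  # quarter of period 8
        i_img, q_img, amp, phase = demodulate_iq(stack, SquareWaveSpec(8, 16))
        np.testing.assert_allclose(i_img, 0.0, atol=1e-12)
        np.testing.assert_allclose(q_img, 0.6, atol=1e-12)
        np.testing.assert_allclose(phase, math.pi / 2, atol=1e-12)

    def test_amplitude_constant_over_all_offsets(self):
        """|I| + |Q| equals the true amplitude at every whole-sample phase
        offset, and the inverted phase matches the applied shift."""
        period, W = 32, 0.7
        spec = SquareWaveSpec(period, period)
        for d in range(period):
            stack = constant_stack(W, period, period, phase=d)
            _, _, amp, phase = demodulate_iq(stack, spec)
            np.testing.assert_allclose(amp, W, atol=1e-9)
            true_phi = 2 * math.pi * d / period
            err = np.abs(np.mod(phase - true_phi + math.pi, 2 * math.pi) - math.pi)
            assert err.max() < 1e-9

    def test_zero_amplitude_gets_zero_phase(self):
        i_img = np.zeros((3, 3))
        np.testing.assert_array_equal(invert_phase_response(i_img, i_img), 0.0)


class TestDemultiplexDual:
    def test_noiseless_roundtrip(self, letters_scene, dual_stack, dual_config):
        res = demultiplex_dual(dual_stack, dual_config)
        np.testing.assert_allclose(
            res.channel_images["white"], letters_scene.white_image, atol=1e-9
        )
        np.testing.assert_allclose(
            res.channel_images["fluor"], letters_scene.fluor_image, atol=1e-9
        )

    def test_ambient_rejected(self, letters_scene, dual_config):
        from dataclasses import replace

        lit = simulate_stack(letters_scene, replace(dual_config, ambient=0.1))
        res = demultiplex_dual(lit, dual_config)
        np.testing.assert_allclose(
            res.channel_images["white"], letters_scene.white_image, atol=1e-12
        )
        np.testing.assert_allclose(
            res.channel_images["fluor"], letters_scene.fluor_image, atol=1e-12
        )

    def test_wrong_ratio_rejected(self, dual_stack):
        # the frequency-ratio constraint fires at configuration time
        with pytest.raises(ValueError, match="cross-talk"):
            ModulationConfig(freq_white=12, freq_fluor=4, n_frames=24, mode="dual_channel")
        single = ModulationConfig(mode="single_channel", channel="white", n_frames=24)
        with pytest.raises(ValueError, match="dual_channel"):
            demultiplex_dual(dual_stack, single)

    def test_trim_drops_partial_period(self, letters_scene, dual_config):
        from dataclasses import replace

        long_cfg = replace(dual_config, n_frames=32)
        full = simulate_stack(letters_scene, long_cfg)
        ragged = FrameStack(full.frames[:27], long_cfg)
        with pytest.raises(ValueError, match="whole number of periods"):
            demultiplex_dual(ragged, long_cfg)
        res = demultiplex_dual(ragged, long_cfg, trim=True)
        assert res.window_used == 24
        np.testing.assert_allclose(
            res.channel_images["white"], letters_scene.white_image, atol=1e-9
        )


class TestNoiseSuppression:
    @pytest.mark.parametrize("n_frames", [8, 20, 40])
    @pytest.mark.parametrize("sigma", [0.01, 0.1, 0.3])
    def test_error_variance_law(self, n_frames, sigma):
        """Monte Carlo across >=100 noise realizations: demodulated error
        variance equals 4 sigma^2 / n_frames within 5%."""
        clean = constant_stack(0.5, n_frames, 4, shape=(16, 16))
        spec = SquareWaveSpec(4, n_frames)
        errors = []
        for seed in range(100):
            noisy = add_noise(clean, sigma, seed=seed)
            out = demodulate_in_phase(noisy, spec)
            errors.append(out - 0.5)
        var = np.var(np.stack(errors))
        assert var == pytest.approx(noise_error_variance(sigma, n_frames), rel=0.05)

    def test_dual_channel_noise_law(self, letters_scene, dual_config):
        """Each demultiplexed channel of a noisy 24-frame dual stack has
        error variance ~ 4 sigma^2 / 24."""
        sigma = 0.1
        clean = simulate_stack(letters_scene, dual_config)
        errors = {"white": [], "fluor": []}
        for seed in range(100):
            res = demultiplex_dual(add_noise(clean, sigma, seed=seed), dual_config)
            for ch in errors:
                errors[ch].append(
                    res.channel_images[ch] - letters_scene.channel_image(ch)
                )
        for ch, errs in errors.items():
            var = np.var(np.stack(errs))
            assert var == pytest.approx(4 * sigma**2 / 24, rel=0.05)
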