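"""Synthetic phantom scenes and frequency-multiplexed frame stacks.

The generator emulates the bench configuration of a dual-illumination
fluorescence endoscope: a bright-field (white light) scene containing a
few block letters, with a fluorescent dye applied to a subset of the
letters, imaged by a camera while both light sources are square-wave
modulated at a frequency ratio of 2 (defaults: white 12 Hz, near-infrared
6 Hz, camera 48 fps).  Sensor noise is additive zero-mean Gaussian on
[0, 1]-scaled pixels; the "noise level" quoted throughout is its standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .waveforms import SquareWaveSpec, square_wave

__all__ = [
    "PhantomScene",
    "ModulationConfig",
    "FrameStack",
    "make_phantom",
    "simulate_stack",
    "add_noise",
    "time_sharing_baseline",
]

Mode = Literal["single_channel", "dual_channel"]
Channel = Literal["white", "fluor"]

# 5x7 block glyphs for the phantom letters (1 = stroke).  A tiny built-in
# bitmap keeps the generator free of font dependencies and bit-exact
# across platforms.
_GLYPHS = {
    "T": ["11111", "00100", "00100", "00100", "00100", "00100", "00100"],
    "J": ["11111", "00010", "00010", "00010", "00010", "10010", "01100"],
    "P": ["11110", "10001", "10001", "11110", "10000", "10000", "10000"],
    "U": ["10001", "10001", "10001", "10001", "10001", "10001", "01110"],
}


@dataclass(frozen=True)
class PhantomScene:
    """A clean scene: bright-field image + fluorescence image + its support.

    ``white_image`` is the reflectance seen under full white illumination,
    ``fluor_image`` the emission seen under full excitation; both live in
    [0, 1] and share one shape.  ``fluor_image`` is zero outside
    ``fluor_mask``.
    """

    white_image: np.ndarray
    fluor_image: np.ndarray
    fluor_mask: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        w, f, m = self.white_image, self.fluor_image, self.fluor_mask
        if not (w.shape == f.shape == m.shape) or w.ndim != 2:
            raise ValueError("scene images must be 2-D and share one shape")
        for name, img in (("white_image", w), ("fluor_image", f)):
            if img.min() < 0 or img.max() > 1:
                raise ValueError(f"{name} pixel values must lie in [0, 1]")
        if np.any(f[~m] != 0):
            raise ValueError("fluor_image must be 0 outside fluor_mask")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.white_image.shape

    def channel_image(self, channel: Channel) -> np.ndarray:
        return self.white_image if channel == "white" else self.fluor_image


@dataclass(frozen=True)
class ModulationConfig:
    """Acquisition parameters for a modulated stack.

    Defaults mirror the reference acquisition: white source at 12 Hz,
    near-infrared at 6 Hz, camera at 48 fps, so the white channel spans 4
    samples per period and the fluorescence channel 8.  ``n_frames``
    defaults to 24 in dual-channel mode (3 common periods) and 20 in
    single-channel mode (5 periods of the 4-sample white period — the
    window whose n/4 noise-power suppression yields the ~7 dB gain).
    """

    frame_rate: float = 48.0
    freq_white: float = 12.0
    freq_fluor: float = 6.0
    n_frames: Optional[int] = None
    noise_sigma: float = 0.0
    mode: Mode = "dual_channel"
    channel: Channel = "white"  # active channel in single_channel mode
    ambient: float = 0.0
    phase_white: int = 0  # whole-sample offsets; both sources start high
    phase_fluor: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("single_channel", "dual_channel"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.channel not in ("white", "fluor"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for ch in self.active_channels:
            self.period(ch)  # validates the 4k constraint
        if self.mode == "dual_channel":
            if self.freq_white != 2 * self.freq_fluor:
                raise ValueError(
                    "dual-channel demultiplexing requires freq_white = 2 x "
                    f"freq_fluor; got {self.freq_white}/{self.freq_fluor} "
                    "(other ratios suffer odd-harmonic cross-talk)"
                )
        slow = max(self.period(ch) for ch in self.active_channels)
        if self.resolved_n_frames % slow != 0:
            raise ValueError(
                f"n_frames={self.resolved_n_frames} must be a whole multiple "
                f"of the slowest channel period ({slow} frames)"
            )

    @property
    def active_channels(self) -> Tuple[Channel, ...]:
        if self.mode == "dual_channel":
            return ("white", "fluor")
        return (self.channel,)

    def period(self, channel: Channel) -> int:
        """Samples per period for ``channel`` (must be a multiple of 4)."""
        freq = self.freq_white if channel == "white" else self.freq_fluor
        ratio = self.frame_rate / freq
        period = round(ratio)
        if abs(ratio - period) > 1e-9 or period % 4 != 0:
            raise ValueError(
                f"frame_rate/freq_{channel} = {ratio} must be an integer "
                "multiple of 4 (sampling rate = 4k x signal frequency)"
            )
        return period

    def phase(self, channel: Channel) -> int:
        return self.phase_white if channel == "white" else self.phase_fluor

    @property
    def resolved_n_frames(self) -> int:
        if self.n_frames is not None:
            return self.n_frames
        return 24 if self.mode == "dual_channel" else 5 * self.period(self.channel)

    def reference_spec(self, channel: Channel) -> SquareWaveSpec:
        """Bipolar unit-amplitude demodulation reference for ``channel``."""
        return SquareWaveSpec(
            samples_per_period=self.period(channel),
            n_samples=self.resolved_n_frames,
            phase_offset_samples=self.phase(channel),
            polarity="bipolar",
            amplitude=1.0,
        )

    def gating_spec(self, channel: Channel) -> SquareWaveSpec:
        """Unipolar on/off source-gating wave for ``channel``."""
        return replace(self.reference_spec(channel), polarity="unipolar")

    def to_dict(self) -> dict:
        return {
            "frame_rate": self.frame_rate,
            "freq_white": self.freq_white,
            "freq_fluor": self.freq_fluor,
            "n_frames": self.resolved_n_frames,
            "noise_sigma": self.noise_sigma,
            "mode": self.mode,
            "channel": self.channel,
            "ambient": self.ambient,
            "phase_white": self.phase_white,
            "phase_fluor": self.phase_fluor,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModulationConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class FrameStack:
    """An ordered stack of equally sized grayscale frames.

    ``frames`` has shape ``(n_frames, rows, cols)``; ``config`` records the
    acquisition parameters that produced it.
    """

    frames: np.ndarray
    config: ModulationConfig
    channel_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) array")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.frames.shape[1:]


def _letters_phantom(shape, rng):
    rows, cols = shape
    white = np.full(shape, 0.72)
    # gentle diagonal illumination falloff, as an endoscope's vignetting
    yy, xx = np.mgrid[0:rows, 0:cols]
    white += 0.06 * (xx / max(cols - 1, 1) - 0.5) - 0.06 * (yy / max(rows - 1, 1) - 0.5)
    # mild smoothed texture so the scene is not piecewise constant
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    white += 0.04 * texture / max(np.abs(texture).max(), 1e-12)

    text = "TJPU"
    n_letters = len(text)
    glyph_h, glyph_w = 7, 5
    scale = max(1, min(rows // (2 * glyph_h), cols // ((glyph_w + 2) * n_letters)))
    h, w = glyph_h * scale, glyph_w * scale
    gap = scale
    total_w = n_letters * w + (n_letters - 1) * gap
    top = (rows - h) // 2
    left = (cols - total_w) // 2

    letter_mask = np.zeros(shape, dtype=bool)
    fluor_mask = np.zeros(shape, dtype=bool)
    for k, ch in enumerate(text):
        bitmap = np.array([[c == "1" for c in row] for row in _GLYPHS[ch]])
        bitmap = np.kron(bitmap, np.ones((scale, scale), dtype=bool))
        r0, c0 = top, left + k * (w + gap)
        letter_mask[r0 : r0 + h, c0 : c0 + w] |= bitmap
        if k < 2:  # dye applied to the first two letters
            fluor_mask[r0 : r0 + h, c0 : c0 + w] |= bitmap

    white[letter_mask] = 0.30
    fluor = np.zeros(shape)
    fluor[fluor_mask] = 0.8 + 0.1 * (white[fluor_mask] - 0.3)
    return np.clip(white, 0.0, 1.0), np.clip(fluor, 0.0, 1.0), fluor_mask


def _geometric_phantom(shape, rng):
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    white = 0.55 + 0.15 * np.sin(2 * np.pi * xx / cols) * np.cos(2 * np.pi * yy / rows)
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    white += 0.05 * texture / max(np.abs(texture).max(), 1e-12)
    cy, cx = rows * 0.5, cols * 0.35
    r = min(rows, cols) * 0.18
    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    white = np.clip(white, 0.0, 1.0)
    fluor = np.zeros(shape)
    fluor[disc] = 0.85
    return white, np.clip(fluor, 0.0, 1.0), disc


def make_phantom(
    shape: Tuple[int, int] = (256, 256),
    style: Literal["letters", "geometric"] = "letters",
    seed: int = 0,
) -> PhantomScene:
    """Build a deterministic phantom scene.

    ``letters`` renders four block letters on a textured bright field and
    marks the first two as fluorescent; ``geometric`` uses a smooth field
    with a fluorescent disc.  Identical ``(shape, style, seed)`` give
    bit-identical scenes.
    """
    rows, cols = shape
    if rows < 16 or cols < 16:
        raise ValueError(f"phantom shape must be at least 16x16, got {shape}")
    rng = np.random.default_rng(seed)
    if style == "letters":
        white, fluor, mask = _letters_phantom(shape, rng)
    elif style == "geometric":
        white, fluor, mask = _geometric_phantom(shape, rng)
    else:
        raise ValueError(f"unknown phantom style {style!r}")
    return PhantomScene(white_image=white, fluor_image=fluor, fluor_mask=mask, seed=seed)


def simulate_stack(scene: PhantomScene, config: ModulationConfig) -> FrameStack:
    """Render the noiseless modulated frame stack for ``scene``.

    Frame ``i`` is ``white * m_w[i] + fluor * m_f[i] + ambient`` where the
    ``m`` are unipolar (on/off) gating waves; single-channel mode keeps
    only the configured channel's term.
    """
    n = config.resolved_n_frames
    frames = np.full((n, *scene.shape), float(config.ambient))
    for ch in config.active_channels:
        gate = square_wave(config.gating_spec(ch))
        frames += gate[:, None, None] * scene.channel_image(ch)[None, :, :]
    return FrameStack(frames=frames, config=config)


def add_noise(
    stack: FrameStack,
    noise_sigma: float,
    seed: int,
    clip: bool = False,
) -> FrameStack:
    """Add i.i.d. zero-mean Gaussian sensor noise to every pixel.

    Pixels are *not* clipped to [0, 1] by default, which keeps the
    closed-form SNR laws exact; pass ``clip=True`` to emulate a saturating
    sensor.  Deterministic given ``seed``.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        frames = stack.frames.copy()
    else:
        rng = np.random.default_rng(seed)
        frames = stack.frames + noise_sigma * rng.standard_normal(stack.frames.shape)
    if clip:
        frames = np.clip(frames, 0.0, 1.0)
    return FrameStack(
        frames=frames,
        config=replace(stack.config, noise_sigma=noise_sigma, seed=seed),
        channel_labels=stack.channel_labels,
    )


def time_sharing_baseline(
    scene: PhantomScene, noise_sigma: float, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """The conventional "without lock-in" comparator.

    Time-sharing acquisition dedicates frames to each channel; the
    baseline image per channel is the clean full-illumination image plus a
    single Gaussian noise realization (one frame, no averaging).  Noise
    scales linearly with ``noise_sigma`` for a fixed seed, so baseline SNR
    falls exactly 20 dB per tenfold increase in noise level.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    white = scene.white_image + noise_sigma * rng.standard_normal(scene.shape)
    fluor = scene.fluor_image + noise_sigma * rng.standard_normal(scene.shape)
    return white, fluor
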