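"""Fusion overlay: pseudo-colored fluorescence on the grayscale bright field.

The display convention used by fluorescence-guided endoscopy: the white
channel forms a grayscale base and the fluorescence channel is alpha
blended on top in a single saturated color, with opacity proportional to
the emission intensity above a threshold.  A fully saturated fluorescence
pixel is rendered as the pure overlay color.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

__all__ = ["fuse"]


def fuse(
    white: np.ndarray,
    fluor: np.ndarray,
    color: Tuple[float, float, float] = (0.0, 1.0, 0.2),
    threshold: float = 0.05,
) -> np.ndarray:
    """Blend ``fluor`` over ``white`` and return an (rows, cols, 3) RGB array.

    ``alpha = clip((fluor - threshold) / (1 - threshold), 0, 1)`` so pixels
    below the threshold stay pure grayscale and a unit-intensity pixel is
    the pure overlay color.  Inputs are clipped to [0, 1] for display.
    """
    white = np.asarray(white, dtype=np.float64)
    fluor = np.asarray(fluor, dtype=np.float64)
    if white.shape != fluor.shape:
        raise ValueError(f"shape mismatch: {white.shape} vs {fluor.shape}")
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    gray = np.clip(white, 0.0, 1.0)
    emission = np.clip(fluor, 0.0, 1.0)
    alpha = np.clip((emission - threshold) / (1.0 - threshold), 0.0, 1.0)
    rgb = np.empty((*white.shape, 3))
    for c in range(3):
        rgb[..., c] = (1.0 - alpha) * gray + alpha * color[c]
    return rgb
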