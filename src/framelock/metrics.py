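"""Image-quality arithmetic: signal power, MSE and SNR.

The image SNR used throughout is the ratio of the mean squared intensity
of the clean reference image to the mean squared error of a processed
image against it, in decibels::

    I_original = mean(f**2)
    MSE        = mean((f - g)**2)
    SNR        = 10 log10(I_original / MSE)

A perfect reconstruction (MSE = 0 with nonzero reference) yields an
explicit ``+inf`` sentinel; an all-zero reference compared with itself is
undefined and raises.  Images are compared on their native [0, 1] float
scale.  The SNR *improvement* between two reconstructions depends only on
their MSE ratio — the reference power cancels.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["SNRReport", "image_power", "mse", "snr_db", "compare"]


def _as_image(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.size == 0:
        raise ValueError(f"{name} must be a nonempty image")
    return arr


def image_power(f) -> float:
    """Mean squared pixel intensity of ``f`` (the signal power term)."""
    return float(np.mean(_as_image(f, "f") ** 2))


def mse(f, g) -> float:
    """Mean squared pixel difference between ``f`` and ``g``."""
    f = _as_image(f, "f")
    g = _as_image(g, "g")
    if f.shape != g.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {g.shape}")
    return float(np.mean((f - g) ** 2))


def snr_db(f, g) -> float:
    """Image SNR of ``g`` against reference ``f`` in dB.

    Returns ``math.inf`` when the error is exactly zero and the reference
    is nonzero; raises ``ValueError`` for the undefined 0/0 case.
    """
    power = image_power(f)
    err = mse(f, g)
    if err == 0.0:
        if power == 0.0:
            raise ValueError("SNR undefined: zero reference and zero error (0/0)")
        return math.inf
    return 10.0 * math.log10(power / err)


@dataclass(frozen=True)
class SNRReport:
    """With/without-lock-in comparison for one reference image."""

    i_original: float
    mse_with: float
    mse_without: float
    snr_with_db: float
    snr_without_db: float
    improvement_db: float
    n_rows: int
    n_cols: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        d = {
            k: ("inf" if isinstance(v, float) and math.isinf(v) else v)
            for k, v in self.to_dict().items()
        }
        return json.dumps(d, indent=2)

    @property
    def is_perfect(self) -> bool:
        """True when the lock-in reconstruction is error-free (SNR = +inf)."""
        return math.isinf(self.snr_with_db)


def compare(f, g_with, g_without) -> SNRReport:
    """Score a lock-in reconstruction against the single-frame baseline.

    ``f`` is the clean reference, ``g_with`` the lock-in demodulated
    image, ``g_without`` the unprocessed baseline.  The improvement is
    ``snr_with - snr_without`` and equals ``10 log10(mse_without /
    mse_with)`` whatever the reference power.
    """
    f = _as_image(f, "f")
    snr_with = snr_db(f, g_with)
    snr_without = snr_db(f, g_without)
    return SNRReport(
        i_original=image_power(f),
        mse_with=mse(f, g_with),
        mse_without=mse(f, g_without),
        snr_with_db=snr_with,
        snr_without_db=snr_without,
        improvement_db=snr_with - snr_without,
        n_rows=f.shape[0],
        n_cols=f.shape[1] if f.ndim > 1 else 1,
    )
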