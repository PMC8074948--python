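"""Discrete square-wave modulation and reference sequences.

Everything downstream (the simulator's source gating, the lock-in
demodulator's references) is built from 50%-duty-cycle square waves
sampled at an integer number of samples per period.  The fast lock-in
algorithm requires the sampling rate to be ``4k`` times the signal
frequency for integer ``k``, i.e. ``samples_per_period`` must be a
multiple of 4 — this makes the quarter-period (90 degree) shift used by
the quadrature reference an exact whole-sample shift, so amplitude and
phase can be recovered purely by adding and subtracting samples.

Conventions
-----------
* A period starts *high*: sample ``i`` is high when
  ``(i - phase_offset) mod P < P/2``.
* ``bipolar`` waves take values ``(+A, -A)`` and are used as demodulation
  references; ``unipolar`` waves take ``(A, 0)`` and model on/off gating
  of a light source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Tuple

import numpy as np

__all__ = [
    "SquareWaveSpec",
    "square_wave",
    "quadrature_reference",
    "check_orthogonal",
]

Polarity = Literal["unipolar", "bipolar"]


@dataclass(frozen=True)
class SquareWaveSpec:
    """Parameters of a discrete 50%-duty-cycle square wave.

    Parameters
    ----------
    samples_per_period : int
        Samples per modulation period.  Must be a positive multiple of 4
        (the ``fs = 4k f`` sampling constraint of the fast lock-in
        algorithm).
    n_samples : int
        Length of the generated sequence.
    phase_offset_samples : int
        Cyclic shift in whole samples; positive values delay the wave.
    polarity : {"bipolar", "unipolar"}
        ``bipolar`` -> values ``(+A, -A)``; ``unipolar`` -> ``(A, 0)``.
    amplitude : float
        Nonnegative amplitude ``A``.
    """

    samples_per_period: int
    n_samples: int
    phase_offset_samples: int = 0
    polarity: Polarity = "bipolar"
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.samples_per_period <= 0 or self.samples_per_period % 4 != 0:
            raise ValueError(
                "samples_per_period must be a positive multiple of 4 "
                f"(sampling rate = 4k x signal frequency); got "
                f"{self.samples_per_period}"
            )
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.polarity not in ("unipolar", "bipolar"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")

    @property
    def is_bipolar(self) -> bool:
        return self.polarity == "bipolar"

    def shifted(self, extra_samples: int) -> "SquareWaveSpec":
        """Return a copy cyclically delayed by ``extra_samples``."""
        return replace(
            self, phase_offset_samples=self.phase_offset_samples + extra_samples
        )

    @property
    def phase_radians(self) -> float:
        """Phase offset expressed in radians, in [0, 2*pi)."""
        frac = (self.phase_offset_samples % self.samples_per_period)
        return 2.0 * math.pi * frac / self.samples_per_period


def _high_mask(spec: SquareWaveSpec) -> np.ndarray:
    idx = (np.arange(spec.n_samples) - spec.phase_offset_samples) % spec.samples_per_period
    return idx < spec.samples_per_period // 2


def square_wave(spec: SquareWaveSpec) -> np.ndarray:
    """Generate the square wave described by ``spec``.

    Returns a float array of length ``spec.n_samples``: the first half of
    each period is high (``+A``), the second half low (``-A`` bipolar,
    ``0`` unipolar).
    """
    high = _high_mask(spec)
    if spec.polarity == "bipolar":
        wave = np.where(high, 1.0, -1.0)
    else:
        wave = np.where(high, 1.0, 0.0)
    return spec.amplitude * wave


def quadrature_reference(spec: SquareWaveSpec) -> np.ndarray:
    """Reference shifted by a quarter period (90 degrees).

    The shift is an exact whole-sample cyclic delay of
    ``samples_per_period / 4`` — no interpolation — which is why the
    sampling constraint demands a multiple of 4.  Only bipolar references
    have a quadrature counterpart.
    """
    if not spec.is_bipolar:
        raise ValueError("quadrature reference is defined for bipolar waves only")
    return square_wave(spec.shifted(spec.samples_per_period // 4))


def check_orthogonal(
    spec_a: SquareWaveSpec, spec_b: SquareWaveSpec, window: int
) -> Tuple[bool, float]:
    """Inner product of two bipolar references over ``window`` samples.

    Demultiplexing two channels relies on their references being exactly
    orthogonal over the integration window.  For a frequency ratio of 2
    and a window that is a whole multiple of the longer period the inner
    product is exactly zero; other odd ratios (e.g. 5) leak through shared
    odd harmonics and return a nonzero value.

    Returns
    -------
    (orthogonal, inner_product)
        ``orthogonal`` is True iff the inner product is exactly 0.  The
        sum is accumulated in integer arithmetic on the +/-1 sign
        sequences, then scaled by the two amplitudes, so "exactly 0" is
        meaningful.
    """
    if not (spec_a.is_bipolar and spec_b.is_bipolar):
        raise ValueError("orthogonality check requires bipolar references")
    lcm = math.lcm(spec_a.samples_per_period, spec_b.samples_per_period)
    if window < lcm:
        raise ValueError(
            f"window ({window}) must cover at least one common period ({lcm})"
        )
    sign_a = np.where(_high_mask(replace(spec_a, n_samples=window)), 1, -1)
    sign_b = np.where(_high_mask(replace(spec_b, n_samples=window)), 1, -1)
    inner_signs = int(np.dot(sign_a, sign_b))
    inner = inner_signs * spec_a.amplitude * spec_b.amplitude
    return inner_signs == 0, inner
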