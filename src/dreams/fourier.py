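"""Mass-tolerant Fourier features for m/z values.

An m/z value is expanded into sines and cosines over a fixed grid of
frequencies: a low block of reciprocals of the integers ``m_max .. 1``
(capturing the integer part of the mass, one frequency per nominal mass) and
a high block of reciprocals of multiples of the minimum decimal mass of
interest ``m_min`` (capturing the decimal part down to instrument accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class FourierGrid:
    """Frequency vector for mass-tolerant Fourier features.

    ``m_min``: minimum decimal mass of interest (absolute instrument
    accuracy, Da); ``m_max``: maximum integer mass of interest (Da);
    ``high_stride``: subsampling step of the high-frequency block (the
    default of 2 keeps every other multiple of ``m_min``, ending exactly at
    ``1/m_min``).
    """

    m_min: float = 1e-4
    m_max: int = 1000
    high_stride: int = 2
    frequencies: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (0 < self.m_min < 1 < self.m_max):
            raise ValueError("need 0 < m_min < 1 < m_max")
        if self.high_stride < 1:
            raise ValueError("high_stride must be >= 1")
        low = 1.0 / np.arange(self.m_max, 0, -1, dtype=np.float64)
        k_top = int(np.floor(1.0 / self.m_min + 1e-9))  # largest k with k*m_min <= 1
        ks = np.arange(1, k_top + 1, self.high_stride, dtype=np.float64)
        high = 1.0 / (ks[::-1] * self.m_min)
        object.__setattr__(self, "frequencies", np.concatenate([low, high]))

    @property
    def n_low(self) -> int:
        return int(self.m_max)

    @property
    def n_high(self) -> int:
        return len(self.frequencies) - self.n_low

    def __len__(self) -> int:
        return len(self.frequencies)


def build_fourier_grid(
    m_min: float = 1e-4, m_max: int = 1000, high_stride: int = 2
) -> FourierGrid:
    """Construct the frequency grid; see :class:`FourierGrid`."""
    return FourierGrid(m_min=m_min, m_max=m_max, high_stride=high_stride)


def fourier_features(m, grid: FourierGrid) -> np.ndarray:
    """Map masses to interleaved ``sin(2*pi*b_i*m), cos(2*pi*b_i*m)`` features.

    ``m`` may be a scalar or an array; the output appends a trailing axis of
    length ``2B`` with sine and cosine interleaved per frequency, every
    component in [-1, 1].
    """
    m = np.asarray(m, dtype=np.float64)
    phase = 2.0 * np.pi * m[..., None] * grid.frequencies
    out = np.empty(m.shape + (2 * len(grid),), dtype=np.float64)
    out[..., 0::2] = np.sin(phase)
    out[..., 1::2] = np.cos(phase)
    return out
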