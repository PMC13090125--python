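"""Core domain types for LC-MS/MS data.

A :class:`Spectrum` is a single peak list with precursor metadata; an
:class:`MSRun` is an ordered acquisition of spectra from one file. The model
input representation is a :class:`SpectrumMatrix`, a ``2 x (n+1)`` matrix whose
first column is the precursor token ``(m0, 1.1)`` and whose remaining columns
hold ``(m/z, relative intensity)`` pairs, zero-padded up to a fixed width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

#: Sentinel intensity of the precursor token. It is deliberately above the
#: maximum relative peak intensity of 1 so the model can tell it apart.
PRECURSOR_INTENSITY = 1.1


class IonizationMode(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


@dataclass(eq=False)
class Spectrum:
    """A single mass spectrum (MS1 or MSn peak list) with acquisition metadata.

    Invalid peak lists (negative intensity, duplicated identical m/z, empty,
    unsorted m/z) are representable: quality control must be able to see them,
    so construction never raises. Use :meth:`validity_issues` / :meth:`is_valid`.
    """

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    retention_time: Optional[float] = None
    ms_level: int = 2
    ionization_mode: IonizationMode = IonizationMode.UNKNOWN
    scan_index: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)

    def __len__(self) -> int:
        return int(self.mz.shape[0])

    def validity_issues(self) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        issues: list[str] = []
        if self.mz.shape != self.intensity.shape:
            issues.append("mz/intensity length mismatch")
            return issues
        if len(self) == 0:
            issues.append("empty spectrum")
            return issues
        if np.any(~np.isfinite(self.mz)) or np.any(~np.isfinite(self.intensity)):
            issues.append("non-finite values")
        if np.any(self.mz <= 0):
            issues.append("non-positive m/z")
        if np.any(self.intensity < 0):
            issues.append("negative intensity")
        if len(self) > 1 and np.any(np.diff(self.mz) == 0):
            issues.append("duplicate identical m/z")
        if len(self) > 1 and np.any(np.diff(self.mz) < 0):
            issues.append("unsorted m/z")
        return issues

    def is_valid(self) -> bool:
        return not self.validity_issues()

    @property
    def base_peak_index(self) -> int:
        return int(np.argmax(self.intensity))

    @property
    def base_peak_mz(self) -> float:
        return float(self.mz[self.base_peak_index])

    @property
    def amplitude(self) -> float:
        """Max intensity divided by min intensity (inf if a zero is present)."""
        lo = float(np.min(self.intensity))
        hi = float(np.max(self.intensity))
        return np.inf if lo == 0 else hi / lo


@dataclass
class MSRun:
    """An ordered LC-MS/MS acquisition; spectrum order is file order."""

    spectra: list[Spectrum] = field(default_factory=list)
    path: str = ""
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def ms1(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


@dataclass
class SpectrumMatrix:
    """Fixed-width model input: precursor token then peaks, zero-padded.

    ``values`` has shape ``(2, n+1)``; row 0 holds m/z, row 1 intensities.
    ``pad_mask`` has shape ``(n+1,)`` and is True for zero-padded columns.
    """

    values: np.ndarray
    pad_mask: np.ndarray

    @property
    def n_real_peaks(self) -> int:
        return int((~self.pad_mask).sum()) - 1  # minus the precursor token


def top_n_peaks(mz: np.ndarray, intensity: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Keep the ``n`` most intense peaks, ordered by ascending m/z.

    Invariant to the input peak order. Ties in intensity are broken in favour
    of the lower m/z so the selection is deterministic.
    """
    mz = np.asarray(mz, dtype=np.float64)
    intensity = np.asarray(intensity, dtype=np.float64)
    if len(mz) > n:
        # sort by (-intensity, mz): stable deterministic top-n
        order = np.lexsort((mz, -intensity))[:n]
        mz, intensity = mz[order], intensity[order]
    order = np.argsort(mz, kind="stable")
    return mz[order], intensity[order]


def to_spectrum_matrix(spectrum: Spectrum, n: int) -> SpectrumMatrix:
    """Build the ``2 x (n+1)`` model input for one spectrum.

    Column 0 is the precursor token ``(precursor_mz, 1.1)``. Peak intensities
    are normalised to the base peak; if the spectrum has more than ``n`` peaks
    the ``n`` most intense are kept, otherwise columns are zero-padded and
    flagged in ``pad_mask``. Retained peaks are ordered by ascending m/z.
    """
    if len(spectrum) == 0:
        raise ValueError("cannot build a spectrum matrix from an empty spectrum")
    if spectrum.precursor_mz is None:
        raise ValueError("spectrum has no precursor m/z")
    mz, intensity = top_n_peaks(spectrum.mz, spectrum.intensity, n)
    base = float(np.max(intensity))
    if base <= 0:
        raise ValueError("spectrum has no positive intensity")
    rel = intensity / base

    values = np.zeros((2, n + 1), dtype=np.float64)
    pad_mask = np.ones(n + 1, dtype=bool)
    values[0, 0] = float(spectrum.precursor_mz)
    values[1, 0] = PRECURSOR_INTENSITY
    pad_mask[0] = False
    k = len(mz)
    values[0, 1 : k + 1] = mz
    values[1, 1 : k + 1] = rel
    pad_mask[1 : k + 1] = False
    return SpectrumMatrix(values=values, pad_mask=pad_mask)


def spectra_to_matrices(spectra: Sequence[Spectrum], n: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack spectra into batched arrays ``(B, 2, n+1)`` and ``(B, n+1)``."""
    mats = [to_spectrum_matrix(s, n) for s in spectra]
    return (
        np.stack([m.values for m in mats]),
        np.stack([m.pad_mask for m in mats]),
    )
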