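"""File- and spectrum-level quality control for LC-MS/MS runs.

Implements the two estimation algorithms used for repository mining:

* instrument m/z accuracy, estimated as the median of m/z standard deviations
  within extracted ion chromatograms (XICs) built in two rounds (a coarse
  0.5 Da pass seeding a fine 0.01 Da pass);
* spectrum type (centroid / profile / thresholded), estimated from the shape
  of the half-maximum window around the base peak.

On top of these, tiered spectrum filters (presets A, B, C, strictest first)
select high-quality MS2 spectra for downstream model training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .spectrum import IonizationMode, MSRun, Spectrum


class SpectrumType(str, Enum):
    CENTROID = "centroid"
    PROFILE = "profile"
    THRESHOLDED = "thresholded"


@dataclass
class TierConfig:
    """Thresholds defining one quality tier.

    ``max_estimated_accuracy`` is compared against the file-level instrument
    accuracy estimate; ``None`` disables the check. An undefined accuracy
    estimate never fails the check by itself (it cannot be judged).
    """

    min_peaks: int = 5
    min_amplitude: float = 10.0
    max_precursor_mz: float = 1000.0
    require_positive_mode: bool = True
    require_single_charge: bool = True
    allow_unknown_charge: bool = False
    max_estimated_accuracy: Optional[float] = 1e-3
    require_centroided: bool = True

    name: str = ""


#: Shipped presets. A is strictest; outputs nest A ⊆ B ⊆ C. The numeric
#: thresholds behind "low number of peaks" / "low intensity amplitudes" are
#: package defaults (documented assumptions), all overridable.
TIER_PRESETS: dict[str, TierConfig] = {
    "A": TierConfig(name="A"),
    "B": TierConfig(
        name="B", max_estimated_accuracy=1e-2, allow_unknown_charge=True
    ),
    "C": TierConfig(
        name="C",
        min_peaks=3,
        min_amplitude=2.0,
        max_estimated_accuracy=None,
        require_single_charge=False,
        allow_unknown_charge=True,
    ),
}


@dataclass
class QCReport:
    file_pass: bool = True
    reasons: list[str] = field(default_factory=list)
    estimated_accuracy: Optional[float] = None
    spectrum_pass: list[bool] = field(default_factory=list)
    spectrum_reasons: list[list[str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "file_pass": self.file_pass,
            "reasons": self.reasons,
            "estimated_accuracy": self.estimated_accuracy,
            "spectrum_pass": self.spectrum_pass,
            "spectrum_reasons": self.spectrum_reasons,
        }


# ---------------------------------------------------------------------------
# instrument accuracy (XIC dispersion)


def _dedupe_seeds(seeds: np.ndarray, tol: float) -> np.ndarray:
    """Greedy deduplication: keep a seed only if > tol from the last kept."""
    if seeds.size == 0:
        return seeds
    seeds = np.sort(seeds)
    kept = [seeds[0]]
    for m in seeds[1:]:
        if m - kept[-1] > tol:
            kept.append(m)
    return np.asarray(kept)


def _xic(ms1: list[Spectrum], seed: float, tol: float) -> np.ndarray:
    """Collect, per MS1 scan in order, the closest peak m/z within ``tol``."""
    out = []
    for s in ms1:
        if len(s) == 0:
            continue
        j = int(np.argmin(np.abs(s.mz - seed)))
        if abs(s.mz[j] - seed) <= tol:
            out.append(s.mz[j])
    return np.asarray(out)


def estimate_instrument_accuracy(run: MSRun) -> Optional[float]:
    """Estimate absolute instrument m/z accuracy (Da) from MS1 XIC dispersion.

    First-round XICs use a 0.5 Da absolute tolerance seeded from MS1 base-peak
    m/z values; XICs with >= 5 points contribute their median m/z as a
    second-round seed. Second-round XICs use a 0.01 Da tolerance; the result
    is the median of per-XIC m/z standard deviations. Returns ``None``
    (undefined) when no second-round XIC reaches 5 points.
    """
    ms1 = [s for s in run.ms1() if len(s) > 0]
    if not ms1:
        raise ValueError("run contains no MS1 spectra")
    seeds1 = _dedupe_seeds(np.asarray([s.base_peak_mz for s in ms1]), 0.5)
    seeds2 = []
    for m in seeds1:
        x = _xic(ms1, float(m), 0.5)
        if len(x) >= 5:
            seeds2.append(float(np.median(x)))
    seeds2 = _dedupe_seeds(np.asarray(seeds2), 0.01)
    stds = []
    for m in seeds2:
        x = _xic(ms1, float(m), 0.01)
        if len(x) >= 5:
            stds.append(float(np.std(x)))
    if not stds:
        return None
    return float(np.median(stds))


# ---------------------------------------------------------------------------
# spectrum type (Algorithm 2)


def classify_spectrum_type(spectrum: Spectrum) -> SpectrumType:
    """Estimate whether a spectrum is centroided, profile, or thresholded.

    Fewer than 5 peaks is always centroid. Otherwise the half-maximum window
    S around the base peak (the maximal contiguous index run containing the
    base peak with intensity > half the base intensity) is inspected: a
    narrow window (index span < 3) or a wide one relative to the spectrum
    (m/z width > total span / 1000) indicates centroided data; otherwise the
    presence of zero intensities distinguishes profile from thresholded.
    """
    n = len(spectrum)
    if n == 0:
        raise ValueError("empty spectrum")
    if n < 5:
        return SpectrumType.CENTROID
    i = spectrum.intensity
    m = spectrum.mz
    b = int(np.argmax(i))
    half = i[b] / 2.0
    lo = b
    while lo - 1 >= 0 and i[lo - 1] > half:
        lo -= 1
    hi = b
    while hi + 1 < n and i[hi + 1] > half:
        hi += 1
    span = hi - lo
    width = m[hi] - m[lo]
    total = m[-1] - m[0]
    if span < 3 or width > total / 1000.0:
        return SpectrumType.CENTROID
    if np.any(i == 0):
        return SpectrumType.PROFILE
    return SpectrumType.THRESHOLDED


# ---------------------------------------------------------------------------
# file- and spectrum-level filters


def check_file_criteria(run: MSRun) -> QCReport:
    """File-level QC: retention-time order, MS-level sequence, MS1 presence,
    minimum spectrum count."""
    report = QCReport()
    rts = [s.retention_time for s in run.spectra if s.retention_time is not None]
    if any(b < a for a, b in zip(rts, rts[1:])):
        report.reasons.append("unordered retention times")
    levels = [s.ms_level for s in run.spectra]
    if any(b > a + 1 for a, b in zip(levels, levels[1:])):
        report.reasons.append("invalid MS-level sequence")
    if not any(lv == 1 for lv in levels):
        report.reasons.append("no MS1 spectra")
    if len(run) < 3:
        report.reasons.append("fewer than 3 spectra")
    report.file_pass = not report.reasons
    return report


def filter_spectra(run: MSRun, tier: TierConfig) -> tuple[list[Spectrum], QCReport]:
    """Apply spectrum-level tier criteria to the MS2 spectra of a run.

    Criteria are applied in order: validity, minimum peak count, intensity
    amplitude, charge rule, precursor m/z ceiling, ionization mode,
    centroidedness, and the file-level accuracy estimate.
    """
    report = QCReport()
    try:
        report.estimated_accuracy = estimate_instrument_accuracy(run)
    except ValueError:
        report.estimated_accuracy = None
    accuracy_bad = (
        tier.max_estimated_accuracy is not None
        and report.estimated_accuracy is not None
        and report.estimated_accuracy > tier.max_estimated_accuracy
    )
    kept = []
    for s in run.spectra:
        reasons = []
        if s.ms_level != 2:
            reasons.append("not MS2")
        else:
            issues = s.validity_issues()
            if issues:
                reasons.append("invalid: " + ", ".join(issues))
            else:
                if len(s) < tier.min_peaks:
                    reasons.append("too few peaks")
                if s.amplitude < tier.min_amplitude:
                    reasons.append("low intensity amplitude")
                if tier.require_single_charge:
                    if s.precursor_charge is None:
                        if not tier.allow_unknown_charge:
                            reasons.append("unknown precursor charge")
                    elif s.precursor_charge != 1:
                        reasons.append("non-single precursor charge")
                if s.precursor_mz is not None and s.precursor_mz > tier.max_precursor_mz:
                    reasons.append("precursor m/z too high")
                if (
                    tier.require_positive_mode
                    and s.ionization_mode != IonizationMode.POSITIVE
                ):
                    reasons.append("not positive ionization mode")
                if (
                    tier.require_centroided
                    and classify_spectrum_type(s) != SpectrumType.CENTROID
                ):
                    reasons.append("not centroided")
                if accuracy_bad:
                    reasons.append("instrument accuracy above tier threshold")
        report.spectrum_pass.append(not reasons)
        report.spectrum_reasons.append(reasons)
        if not reasons:
            kept.append(s)
    return kept, report
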