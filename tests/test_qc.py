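"""Quality control: XIC accuracy estimation, spectrum typing, tier filters."""

import numpy as np
import pytest

from dreams.qc import (
    SpectrumType,
    TIER_PRESETS,
    check_file_criteria,
    classify_spectrum_type,
    estimate_instrument_accuracy,
    filter_spectra,
)
from dreams.spectrum import IonizationMode, MSRun
from dreams.synthetic import SimConfig, generate_run

from conftest import make_spectrum


def brute_force_accuracy(run):
    """Independent literal re-implementation of the two-round XIC estimate."""
    ms1 = [s for s in run.spectra if s.ms_level == 1 and len(s)]

    def xic(seed, tol):
        points = []
        for s in ms1:
            deltas = np.abs(s.mz - seed)
            j = int(np.argmin(deltas))
            if deltas[j] <= tol:
                points.append(s.mz[j])
        return np.asarray(points)

    def dedupe(seeds, tol):
        kept = []
        for m in np.sort(np.asarray(seeds)):
            if not kept or m - kept[-1] > tol:
                kept.append(m)
        return kept

    seeds2 = []
    for m in dedupe([s.mz[np.argmax(s.intensity)] for s in ms1], 0.5):
        x = xic(m, 0.5)
        if len(x) >= 5:
            seeds2.append(np.median(x))
    stds = []
    for m in dedupe(seeds2, 0.01):
        x = xic(m, 0.01)
        if len(x) >= 5:
            stds.append(np.std(x))
    return float(np.median(stds)) if stds else None


class TestInstrumentAccuracy:
    def test_zero_dispersion(self):
        spectra = [
            make_spectrum([500.0], [10.0], ms_level=1, precursor_mz=None)
            for _ in range(6)
        ]
        assert estimate_instrument_accuracy(MSRun(spectra=spectra)) == 0.0

    def test_matches_brute_force_oracle_on_jittered_run(self):
        run, _ = generate_run(SimConfig(seed=3, jitter_sigma=1e-3, n_scans=250))
        ours = estimate_instrument_accuracy(run)
        oracle = brute_force_accuracy(run)
        assert ours == pytest.approx(oracle, abs=0)

    def test_undefined_below_five_scans(self):
        spectra = [
            make_spectrum([500.0], [10.0], ms_level=1, precursor_mz=None)
            for _ in range(3)
        ]
        assert estimate_instrument_accuracy(MSRun(spectra=spectra)) is None

    def test_error_without_ms1(self):
        with pytest.raises(ValueError):
            estimate_instrument_accuracy(
                MSRun(spectra=[make_spectrum([100.0], [1.0], ms_level=2)])
            )

    def test_monotone_in_jitter(self):
        estimates = []
        for sigma in (0.0, 1e-4, 1e-3, 1e-2):
            run, _ = generate_run(SimConfig(seed=9, jitter_sigma=sigma, n_scans=250))
            a = estimate_instrument_accuracy(run)
            estimates.append(-1.0 if a is None else a)
        assert estimates == sorted(estimates)


def _battery():
    """Constructed spectra with hand-executed type labels."""
    cases = []
    # fewer than 5 peaks: always centroid
    cases.append(([100.0, 200.0, 300.0, 400.0], [1, 2, 3, 4], SpectrumType.CENTROID))
    cases.append(([100.0], [1.0], SpectrumType.CENTROID))
    cases.append(([100.0, 200.0], [0.0, 1.0], SpectrumType.CENTROID))
    # hand-executed profile / thresholded pair around a 500 Da base peak
    mz = [100.0, 499.98, 499.99, 500.00, 500.01, 500.02, 1000.0]
    cases.append((mz, [0, 0.6, 0.9, 1.0, 0.8, 0.6, 0], SpectrumType.PROFILE))
    cases.append((mz, [0.1, 0.6, 0.9, 1.0, 0.8, 0.6, 0.1], SpectrumType.THRESHOLDED))
    # 5 sticks far apart: window is a single index, span 0 < 3
    cases.append(
        ([100.0, 200.0, 300.0, 400.0, 500.0], [1, 2, 9, 2, 1], SpectrumType.CENTROID)
    )
    # wide half-max window relative to the total span: centroid
    cases.append(
        ([100.0, 150.0, 200.0, 250.0, 300.0], [6, 7, 9, 8, 6], SpectrumType.CENTROID)
    )
    # narrow window, zeros elsewhere: profile
    cases.append(
        (
            [50.0, 299.999, 300.0, 300.001, 300.002, 600.0],
            [0.0, 0.8, 1.0, 0.9, 0.7, 0.1],
            SpectrumType.PROFILE,
        )
    )
    # same but all strictly positive: thresholded
    cases.append(
        (
            [50.0, 299.999, 300.0, 300.001, 300.002, 600.0],
            [0.05, 0.8, 1.0, 0.9, 0.7, 0.1],
            SpectrumType.THRESHOLDED,
        )
    )
    # window exactly 3 indices wide, small width, zero present
    cases.append(
        (
            [100.0, 400.0, 400.001, 400.002, 400.003, 400.004, 900.0],
            [0.0, 0.4, 0.6, 1.0, 0.9, 0.6, 0.0],
            SpectrumType.PROFILE,
        )
    )
    # base peak at the spectrum edge
    cases.append(
        (
            [400.0, 400.001, 400.002, 400.003, 500.0, 900.0],
            [1.0, 0.9, 0.8, 0.6, 0.1, 0.0],
            SpectrumType.PROFILE,
        )
    )
    cases.append(
        (
            [400.0, 400.001, 400.002, 400.003, 500.0, 900.0],
            [1.0, 0.9, 0.8, 0.6, 0.1, 0.01],
            SpectrumType.THRESHOLDED,
        )
    )
    # a flat spectrum: every index above half max, window spans everything
    cases.append(
        ([100.0, 200.0, 300.0, 400.0, 500.0], [1, 1, 1, 1, 1], SpectrumType.CENTROID)
    )
    # window broken by a sub-half valley right of the base
    cases.append(
        ([100.0, 200.0, 200.1, 200.2, 500.0], [0.1, 1.0, 0.4, 0.9, 0.1], SpectrumType.CENTROID)
    )
    return cases


def _generated_battery():
    cases = []
    for shape, label in (
        ("centroid", SpectrumType.CENTROID),
        ("profile", SpectrumType.PROFILE),
        ("thresholded", SpectrumType.THRESHOLDED),
    ):
        run, _ = generate_run(SimConfig(seed=21, peak_shape=shape, n_scans=12))
        for s in run.ms2()[:2]:
            cases.append((s.mz, s.intensity, label))
    return cases


class TestSpectrumType:
    @pytest.mark.parametrize("mz,intensity,expected", _battery() + _generated_battery())
    def test_battery_matches_hand_labels(self, mz, intensity, expected):
        s = make_spectrum(mz, intensity)
        assert classify_spectrum_type(s) == expected

    def test_battery_size_covers_twenty_fixtures(self):
        assert len(_battery()) + len(_generated_battery()) >= 20

    def test_empty_spectrum_errors(self):
        with pytest.raises(ValueError):
            classify_spectrum_type(make_spectrum([], []))


class TestFileCriteria:
    def _run(self, rts=None, levels=None):
        rts = rts or [10.0, 20.0, 30.0]
        levels = levels or [1, 2, 2]
        return MSRun(
            spectra=[
                make_spectrum([100.0, 200.0], [1.0, 2.0], retention_time=rt, ms_level=lv)
                for rt, lv in zip(rts, levels)
            ]
        )

    def test_unordered_retention_times(self):
        report = check_file_criteria(self._run(rts=[10.0, 5.0, 20.0]))
        assert not report.file_pass
        assert "unordered retention times" in report.reasons

    def test_invalid_ms_level_sequence(self):
        report = check_file_criteria(self._run(rts=[1.0, 2.0], levels=[1, 3]))
        assert "invalid MS-level sequence" in report.reasons

    def test_missing_ms1(self):
        report = check_file_criteria(self._run(levels=[2, 2, 2]))
        assert "no MS1 spectra" in report.reasons

    def test_valid_run_passes(self):
        report = check_file_criteria(self._run())
        assert report.file_pass and report.reasons == []


class TestTierFilters:
    def _spectrum(self, **kw):
        base = dict(
            mz=[100.0, 200.0, 300.0, 400.0, 500.0],
            intensity=[1.0, 2.0, 4.0, 8.0, 16.0],
        )
        mz = kw.pop("mz", base["mz"])
        inten = kw.pop("intensity", base["intensity"])
        return make_spectrum(mz, inten, **kw)

    def _run_with(self, spectrum):
        ms1 = make_spectrum([500.0], [10.0], ms_level=1, precursor_mz=None)
        return MSRun(spectra=[ms1, spectrum, self._spectrum()])

    @pytest.mark.parametrize(
        "kw,reason",
        [
            ({"precursor_mz": 1200.0}, "precursor m/z too high"),
            ({"precursor_charge": 2}, "non-single precursor charge"),
            ({"ionization_mode": IonizationMode.NEGATIVE}, "not positive ionization mode"),
            ({"intensity": [10.0, 11.0, 12.0, 13.0, 14.0]}, "low intensity amplitude"),
            ({"mz": [100.0, 200.0], "intensity": [1.0, 16.0]}, "too few peaks"),
        ],
    )
    def test_exclusion_reasons(self, kw, reason):
        bad = self._spectrum(**kw)
        kept, report = filter_spectra(self._run_with(bad), TIER_PRESETS["A"])
        assert bad not in kept
        assert reason in report.spectrum_reasons[1]

    def test_tier_outputs_nest(self, synthetic_run):
        run, _ = synthetic_run
        outputs = {}
        for tier in "ABC":
            kept, _ = filter_spectra(run, TIER_PRESETS[tier])
            outputs[tier] = {id(s) for s in kept}
        assert outputs["A"] <= outputs["B"] <= outputs["C"]

    def test_unknown_charge_tier_dependence(self):
        unk = self._spectrum(precursor_charge=None)
        run = self._run_with(unk)
        kept_a, _ = filter_spectra(run, TIER_PRESETS["A"])
        kept_b, _ = filter_spectra(run, TIER_PRESETS["B"])
        assert unk not in kept_a and unk in kept_b
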