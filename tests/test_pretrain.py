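"""Masking, bin labels, loss analytics, the training loop, linear probing."""

import numpy as np
import pytest

from dreams.nn.autodiff import Tensor
from dreams.nn.model import EncoderConfig, SpectrumTransformer
from dreams.pretrain import (
    MASK_SENTINEL,
    PretrainConfig,
    augment_shift,
    mask_spectrum,
    mass_bin_label,
    pretrain_losses,
    probe_fingerprints,
    run_pretraining,
    sample_training_pair,
)
from dreams.spectrum import to_spectrum_matrix
from dreams.synthetic import SimConfig, generate_run

from conftest import make_spectrum


class TestMassBinLabel:
    @pytest.mark.parametrize(
        "m,c,expected",
        [
            (0.0, 20000, 0),
            (999.99, 20000, 19999),
            (0.05, 20000, 1),  # boundary belongs to the right bin
            (500.0, 1000, 500),
        ],
    )
    def test_examples(self, m, c, expected):
        assert mass_bin_label(m, c) == expected

    @pytest.mark.parametrize("m", [-0.1, 1000.0, 1500.0])
    def test_out_of_range(self, m):
        with pytest.raises(ValueError):
            mass_bin_label(m, 20000)


class TestMasking:
    def _matrix(self):
        s = make_spectrum([100.25, 200.5, 300.75], [10.0, 30.0, 60.0])
        return to_spectrum_matrix(s, n=5)

    def test_zero_ratio_is_identity(self):
        cfg = PretrainConfig(mask_ratio=0.0)
        mat = self._matrix()
        masked, picks, labels = mask_spectrum(mat, cfg, np.random.default_rng(0))
        assert np.array_equal(masked.values, mat.values)
        assert len(picks) == 0 and len(labels) == 0

    def test_mask_count_and_sentinel(self):
        cfg = PretrainConfig(mask_ratio=0.34, c=1000)
        masked, picks, labels = mask_spectrum(
            self._matrix(), cfg, np.random.default_rng(1)
        )
        assert len(picks) == round(0.34 * 3)
        assert np.all(masked.values[0, picks] == MASK_SENTINEL)
        # intensities untouched
        assert np.array_equal(masked.values[1], self._matrix().values[1])

    def test_precursor_never_masked(self):
        cfg = PretrainConfig(mask_ratio=0.9, c=1000)
        mat = self._matrix()
        rng = np.random.default_rng(2)
        for _ in range(10_000):
            _, picks, _ = mask_spectrum(mat, cfg, rng)
            assert 0 not in picks

    def test_intensity_proportional_selection(self):
        # one masked peak out of three: P(pick j) = w_j / sum(w)
        cfg = PretrainConfig(mask_ratio=0.34, c=1000)
        mat = self._matrix()
        rng = np.random.default_rng(3)
        trials = 5000
        hits = sum(
            3 in mask_spectrum(mat, cfg, rng)[1] for _ in range(trials)
        )  # column 3 holds the most intense peak (intensity 60 of 100)
        p = 0.6
        se = np.sqrt(p * (1 - p) / trials)
        assert abs(hits / trials - p) < 3 * se


class TestLossAnalytics:
    def test_perfect_prediction_zero_loss(self):
        cfg = PretrainConfig(c=10)
        labels = np.array([3, 7])
        log_probs = np.full((2, 10), -1e9)
        log_probs[0, 3] = 0.0
        log_probs[1, 7] = 0.0
        l_mass, _, _ = pretrain_losses(
            Tensor(log_probs), labels, np.array([0, 0]),
            Tensor(np.array([[0.5]])), np.array([1]), cfg,
        )
        assert float(l_mass.data) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_equals_log_c(self):
        c = 20000
        cfg = PretrainConfig(c=c)
        log_probs = np.full((2, c), -np.log(c))  # one masked peak per spectrum
        l_mass, _, _ = pretrain_losses(
            Tensor(log_probs), np.array([5, 17]), np.array([0, 0]),
            Tensor(np.array([[0.5]])), np.array([1]), cfg,
        )
        assert float(l_mass.data) == pytest.approx(np.log(20000), rel=1e-9)
        assert float(l_mass.data) == pytest.approx(9.9035, abs=1e-4)

    def test_weighted_combination(self):
        # L_mass = 1 and L_order = 2 must combine to 0.8 + 0.4 = 1.2
        cfg = PretrainConfig(c=10)
        c = 10
        log_probs = np.full((2, c), 0.0)
        log_probs[:, 4] = -1.0  # true-bin log prob = -1 per peak -> L_mass = 1
        p_order = float(np.exp(-2.0))  # BCE(y=1) = -log(p) = 2
        _, l_order, total = pretrain_losses(
            Tensor(log_probs), np.array([4, 4]), np.array([0, 0]),
            Tensor(np.array([[p_order]])), np.array([1]), cfg,
        )
        assert float(l_order.data) == pytest.approx(2.0, rel=1e-9)
        assert float(total.data) == pytest.approx(1.2, rel=1e-9)


class TestAugmentAndPairs:
    def test_shift_prob_zero_is_identity(self):
        cfg = PretrainConfig(shift_prob=0.0)
        mat = to_spectrum_matrix(make_spectrum([100.0, 200.0], [1.0, 2.0]), 4)
        out = augment_shift(mat, cfg, np.random.default_rng(0))
        assert np.array_equal(out.values, mat.values)

    def test_shift_preserves_differences(self):
        cfg = PretrainConfig(shift_prob=1.0)
        mat = to_spectrum_matrix(make_spectrum([100.0, 200.0, 321.5], [1, 2, 3]), 4)
        out = augment_shift(mat, cfg, np.random.default_rng(1))
        real = ~mat.pad_mask
        assert not np.array_equal(out.values[0, real], mat.values[0, real])
        assert np.allclose(
            np.diff(out.values[0, real]), np.diff(mat.values[0, real])
        )
        assert np.array_equal(out.values[1], mat.values[1])

    def test_shift_seeded_reproducible(self):
        cfg = PretrainConfig(shift_prob=1.0)
        mat = to_spectrum_matrix(make_spectrum([100.0, 200.0], [1.0, 2.0]), 4)
        a = augment_shift(mat, cfg, np.random.default_rng(9))
        b = augment_shift(mat, cfg, np.random.default_rng(9))
        assert np.array_equal(a.values, b.values)

    def test_pair_order_label(self):
        s1 = make_spectrum([100.0], [1.0], retention_time=10.0, source_id="r")
        s2 = make_spectrum([110.0], [1.0], retention_time=20.0, source_id="r")
        found = set()
        for seed in range(20):
            a, b, y = sample_training_pair([s1, s2], np.random.default_rng(seed))
            assert y == int(b.retention_time > a.retention_time)
            found.add(y)
        assert found == {0, 1}

    def test_pair_needs_two_spectra(self):
        s = make_spectrum([100.0], [1.0], retention_time=1.0, source_id="r")
        with pytest.raises(ValueError):
            sample_training_pair([s], np.random.default_rng(0))

    def test_pair_requires_single_source(self):
        s1 = make_spectrum([100.0], [1.0], retention_time=1.0, source_id="a")
        s2 = make_spectrum([110.0], [1.0], retention_time=2.0, source_id="b")
        with pytest.raises(ValueError):
            sample_training_pair([s1, s2], np.random.default_rng(0))


def _tiny_setup(steps, seed=0, n_scans=120):
    run, _ = generate_run(SimConfig(seed=seed, n_scans=n_scans))
    pcfg = PretrainConfig(c=200, n_peaks=8, batch_size=4, seed=seed)
    mcfg = EncoderConfig(
        d=32, d_m=28, d_p=4, layers=1, heads=4, c=200, n_peaks=8,
        ffn_f_depth=2, ffn_f_hidden=32, m_min=0.05, m_max=100,
    )
    return run.ms2(), pcfg, mcfg


class TestTrainingLoop:
    def test_zero_steps_keeps_initialization(self):
        spectra, pcfg, mcfg = _tiny_setup(0)
        result = run_pretraining(spectra, pcfg, mcfg, steps=0, seed=0)
        reference = SpectrumTransformer(mcfg, seed=0)
        for k, v in reference.params.items():
            assert np.array_equal(v.data, result.model.params[k].data)

    def test_fixed_seed_reproduces_loss_trace(self):
        spectra, pcfg, mcfg = _tiny_setup(2)
        a = run_pretraining(spectra, pcfg, mcfg, steps=2, seed=3)
        b = run_pretraining(spectra, pcfg, mcfg, steps=2, seed=3)
        assert [t["loss"] for t in a.loss_trace] == [t["loss"] for t in b.loss_trace]

    def test_loss_decreases_over_short_run(self):
        spectra, pcfg, mcfg = _tiny_setup(30)
        result = run_pretraining(spectra, pcfg, mcfg, steps=30, seed=1)
        first = np.mean([t["loss"] for t in result.loss_trace[:5]])
        last = np.mean([t["loss"] for t in result.loss_trace[-5:]])
        assert last < first


class TestProbe:
    def test_separable_labels_reach_high_recall(self):
        rng = np.random.default_rng(0)
        emb = rng.standard_normal((300, 16))
        w = rng.standard_normal((16, 6))
        bits = (emb @ w > 0).astype(int)
        recall, precision = probe_fingerprints(emb, bits, epochs=300, lr=0.5)
        assert recall > 0.9
        assert precision > 0.8

    def test_independent_labels_stay_near_base_rate(self):
        rng = np.random.default_rng(1)
        emb = rng.standard_normal((300, 16))
        bits = rng.integers(0, 2, size=(300, 6))
        recall, _ = probe_fingerprints(emb, bits, epochs=100, lr=0.5)
        # a useless probe predicts positives at roughly the base rate
        assert recall < 0.75
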