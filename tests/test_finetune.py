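"""Task losses, triplet mining, fold guards, and evaluation metrics."""

import numpy as np
import pytest

from dreams.finetune import (
    FinetuneConfig,
    annotate_from_smiles,
    assert_murcko_disjoint,
    cosine_similarity,
    evaluate_binary_ranking,
    evaluate_retrieval,
    evaluate_similarity,
    fingerprint_loss,
    fit_property_scaler,
    finetune,
    focal_loss,
    mine_triplets,
    normalize_properties,
    property_loss,
    triplet_loss,
)
from dreams.nn.model import EncoderConfig, SpectrumTransformer
from dreams.synthetic import SimConfig, generate_annotated_library

from conftest import make_spectrum


def _unit(theta):
    return np.array([np.cos(theta), np.sin(theta)])


class TestTripletLoss:
    def test_satisfied_margin_is_zero(self):
        z = _unit(0.0)
        loss = triplet_loss(z, z, _unit(np.pi / 2))  # cos+ = 1, cos- = 0
        assert loss == pytest.approx(0.0)

    def test_equal_similarities_give_margin(self):
        z, other = _unit(0.0), _unit(0.4)
        assert triplet_loss(z, other, other) == pytest.approx(0.1)

    def test_margin_exceeded_clamps_to_zero(self):
        assert triplet_loss(_unit(0), _unit(0.05), _unit(2.5)) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        z, p, n = rng.standard_normal((3, 8))
        assert triplet_loss(z, p, n) == pytest.approx(
            triplet_loss(5 * z, 0.1 * p, 42 * n)
        )


class TestFingerprintLoss:
    def test_identical_vectors(self):
        y = np.array([1.0, 0.0, 1.0, 1.0])
        assert fingerprint_loss(y, y) == pytest.approx(0.0)

    def test_orthogonal_vectors(self):
        assert fingerprint_loss(
            np.array([1.0, 0.0]), np.array([0.0, 1.0])
        ) == pytest.approx(1.0)

    def test_hand_cosine_half(self):
        a = np.array([1.0, 0.0])
        b = np.array([0.5, np.sqrt(3) / 2])
        assert fingerprint_loss(a, b) == pytest.approx(0.5)

    def test_zero_target_errors(self):
        with pytest.raises(ValueError):
            fingerprint_loss(np.array([1.0, 0.0]), np.zeros(2))


class TestPropertyLoss:
    def test_perfect_prediction(self):
        y = np.arange(11.0)
        assert property_loss(y, y) == 0.0

    def test_all_ones_residual(self):
        y = np.zeros(11)
        assert property_loss(y + 1.0, y) == pytest.approx(1.0)

    def test_scaler_maps_train_extremes_to_unit_interval(self):
        rng = np.random.default_rng(0)
        props = rng.uniform(-5, 5, size=(20, 3))
        scaler = fit_property_scaler(props, names=("a", "b", "c"))
        scaled = normalize_properties(props, scaler)
        assert np.allclose(scaled.min(axis=0), 0.0)
        assert np.allclose(scaled.max(axis=0), 1.0)

    def test_constant_property_named_in_error(self):
        props = np.ones((5, 2))
        props[:, 0] = np.arange(5)
        with pytest.raises(ValueError, match="second"):
            fit_property_scaler(props, names=("first", "second"))


class TestFocalLoss:
    def test_confident_correct_is_zero(self):
        assert focal_loss(1.0 - 1e-16, 1) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        # y=1, p=0.5, alpha=0.8, gamma=0.5: 0.8 * sqrt(0.5) * ln 2
        expected = 0.8 * np.sqrt(0.5) * np.log(2.0)
        assert focal_loss(0.5, 1) == pytest.approx(expected, abs=1e-9)
        assert focal_loss(0.5, 1) == pytest.approx(0.3921, abs=1e-4)

    def test_negative_class_uses_complementary_weight(self):
        # y=0, p_F = 1 - y_hat, alpha_F = 0.2
        y_hat = 0.3
        expected = -0.2 * (1 - 0.7) ** 0.5 * np.log(0.7)
        assert focal_loss(y_hat, 0) == pytest.approx(expected, abs=1e-12)

    def test_reduces_to_half_bce(self):
        cfg = FinetuneConfig(focal_alpha=0.5, focal_gamma=0.0)
        for y_hat, y in ((0.3, 1), (0.9, 0), (0.42, 1)):
            p = y_hat if y == 1 else 1 - y_hat
            assert focal_loss(y_hat, y, cfg) == pytest.approx(0.5 * -np.log(p))


class TestTripletMining:
    def _record(self, smiles, mz):
        return annotate_from_smiles(
            make_spectrum([100.0, 150.0], [1.0, 2.0], precursor_mz=mz), smiles
        )

    def test_three_record_exhaustive(self):
        lib = [
            self._record("c1ccccc1CCC", 300.0),
            self._record("c1ccccc1CCC", 300.0),
            self._record("c1ccccc1C(C)C", 300.02),
        ]
        triples = mine_triplets(lib)
        assert sorted(triples) == [(0, 1, 2), (1, 0, 2)]

    def test_no_negative_in_window(self):
        lib = [
            self._record("c1ccccc1CCC", 300.0),
            self._record("c1ccccc1CCC", 300.0),
            self._record("c1ccccc1C(C)C", 301.0),
        ]
        assert mine_triplets(lib) == []

    def test_same_molecule_never_negative(self):
        lib = [
            self._record("c1ccccc1CCC", 300.0),
            self._record("c1ccccc1CCC", 300.0),
            self._record("c1ccccc1CCC", 300.01),
        ]
        for _, _, q in mine_triplets(lib):
            assert lib[q].inchikey14 != lib[0].inchikey14
        assert mine_triplets(lib) == []


class TestEvaluation:
    def test_monotone_scores(self):
        assert evaluate_similarity([0.1, 0.2, 0.3], [1.0, 2.0, 3.0]) == pytest.approx(1.0)
        assert evaluate_binary_ranking([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_constant_scores_error(self):
        with pytest.raises(ValueError):
            evaluate_similarity([0.5, 0.5], [0.1, 0.9])

    def test_auroc_hand_case(self):
        assert evaluate_binary_ranking(
            [0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]
        ) == pytest.approx(0.75)

    def test_retrieval_threshold_semantics(self):
        predicted = np.array([1.0, 0.0, 0.0])
        candidates = np.array(
            [
                [0.9, 0.1, 0.0],  # rank 1, negative
                [0.8, 0.3, 0.0],  # rank 2, negative
                [0.7, 0.5, 0.0],  # rank 3, the positive
                [0.0, 1.0, 0.0],
            ]
        )
        positive = np.array([False, False, True, False])
        acc = evaluate_retrieval([(predicted, candidates, positive)], ks=(1, 5))
        assert acc[1] == 0.0 and acc[5] == 1.0

    def test_pool_without_positive_errors(self):
        with pytest.raises(ValueError):
            evaluate_retrieval(
                [(np.ones(2), np.ones((2, 2)), np.array([False, False]))]
            )


class TestFinetuneLoop:
    def test_leaky_folds_abort(self):
        a = annotate_from_smiles(make_spectrum([100.0], [1.0]), "c1ccccc1CCC")
        b = annotate_from_smiles(make_spectrum([100.0], [1.0]), "c1ccccc1CCCC")
        with pytest.raises(ValueError, match="leakage"):
            assert_murcko_disjoint([a], [b])

    def test_zero_epochs_keeps_weights(self):
        lib = generate_annotated_library(
            SimConfig(seed=5), n_molecules=8, spectra_per_molecule=2
        )
        cfg = EncoderConfig(
            d=32, d_m=28, d_p=4, layers=1, heads=4, c=100, n_peaks=8,
            ffn_f_depth=2, ffn_f_hidden=32, m_min=0.05, m_max=100,
        )
        model = SpectrumTransformer(cfg, seed=0)
        before = model.state_dict()
        result = finetune(
            model, "fluorine", lib, lib[:2], FinetuneConfig(n_peaks=8),
            epochs=0, check_folds=False,
        )
        for k, v in before.items():
            assert np.array_equal(v, result.model.params[k].data)

    def test_contrastive_finetuning_improves_decoy_discrimination(self):
        """Triplet fine-tuning on same-mass hard negatives raises the AUROC
        for telling same-molecule pairs from decoy pairs above zero-shot."""
        import itertools

        from dreams.spectrum import spectra_to_matrices

        lib = generate_annotated_library(
            SimConfig(seed=20), n_molecules=20, spectra_per_molecule=3
        )
        cfg = EncoderConfig(
            d=32, d_m=28, d_p=4, layers=1, heads=4, c=100, n_peaks=12,
            ffn_f_depth=2, ffn_f_hidden=32, m_min=0.05, m_max=100,
        )

        def decoy_auroc(model):
            vals, pads = spectra_to_matrices([r.spectrum for r in lib], 12)
            z = model.heads_forward(model.forward_encoder(vals, pads), "embedding").data
            scores, labels = [], []
            for i, j in itertools.combinations(range(len(lib)), 2):
                same = lib[i].inchikey14 == lib[j].inchikey14
                close = (
                    abs(lib[i].spectrum.precursor_mz - lib[j].spectrum.precursor_mz)
                    <= 0.05
                )
                if same or close:
                    scores.append(cosine_similarity(z[i], z[j]))
                    labels.append(int(same))
            return evaluate_binary_ranking(scores, labels)

        model = SpectrumTransformer(cfg, seed=2)
        before = decoy_auroc(model)
        result = finetune(
            model, "similarity", lib, lib[:6],
            FinetuneConfig(n_peaks=12, lr=3e-3, patience=20),
            epochs=12, check_folds=False,
        )
        assert decoy_auroc(result.model) > before

    def test_fingerprint_finetuning_improves_validation(self):
        lib = generate_annotated_library(
            SimConfig(seed=6), n_molecules=12, spectra_per_molecule=2
        )
        split = len(lib) - 6
        train, val = lib[:split], lib[split:]
        cfg = EncoderConfig(
            d=32, d_m=28, d_p=4, layers=1, heads=4, c=100, n_peaks=12,
            ffn_f_depth=2, ffn_f_hidden=32, m_min=0.05, m_max=100,
        )
        ft_cfg = FinetuneConfig(n_peaks=12, lr=1e-3, patience=10)
        model = SpectrumTransformer(cfg, seed=1)
        result = finetune(
            model, "fingerprint", train, val, ft_cfg, epochs=6, check_folds=False
        )
        first = result.history[0]["val_loss"]
        best = min(h["val_loss"] for h in result.history)
        assert best < first
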