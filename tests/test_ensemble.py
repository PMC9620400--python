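"""One-versus-one ensemble: balancing, calibration, consensus, CV."""

import numpy as np
import pytest

from agndesign.curation import CLASS_ORDER, ColorClass
from agndesign.ensemble import (
    EnsembleModel,
    PairMember,
    PairModel,
    TrainingConfig,
    balanced_subsamples,
    class_pairs,
    cross_validate,
    pair_probability,
    predict_class,
    predict_classes,
    train_ensemble,
)
from agndesign.features import feature_names


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestBalancedSubsamples:
    def test_majority_subsampled_to_minority_size(self, rng):
        draws = balanced_subsamples(np.arange(30), np.arange(100, 600), 10, rng)
        assert len(draws) == 10
        for a, b in draws:
            assert a.size == b.size == 30
            assert np.array_equal(a, np.arange(30))  # minority identical throughout
        # majority draws differ between outputs
        assert any(not np.array_equal(draws[0][1], d[1]) for d in draws[1:])

    def test_equal_sizes_pass_through(self, rng):
        draws = balanced_subsamples(np.arange(20), np.arange(50, 70), 10, rng)
        for a, b in draws:
            assert np.array_equal(a, np.arange(20))
            assert np.array_equal(b, np.arange(50, 70))

    def test_deterministic_given_seed(self):
        d1 = balanced_subsamples(np.arange(10), np.arange(100), 5, np.random.default_rng(3))
        d2 = balanced_subsamples(np.arange(10), np.arange(100), 5, np.random.default_rng(3))
        for (a1, b1), (a2, b2) in zip(d1, d2):
            assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_insufficient_class_rejected(self, rng):
        with pytest.raises(ValueError, match="insufficient"):
            balanced_subsamples(np.array([1]), np.arange(50), 3, rng)

    def test_majority_coverage_consistent_with_uniform(self):
        """Over 100 draws of 30 from 120, per-row inclusion ~ Binomial(100, 1/4)."""
        rng = np.random.default_rng(99)
        counts = np.zeros(120)
        for a, b in balanced_subsamples(np.arange(30), np.arange(120), 100, rng):
            counts[b] += 1
        assert counts.min() > 0  # every majority row selected at least once
        # chi-square sanity check against uniform expectation 25
        chi2 = float(((counts - 25.0) ** 2 / 25.0).sum())
        # 119 dof: mean 119, sd ~15.4; allow generous 5-sigma band
        assert chi2 < 119 + 5 * np.sqrt(2 * 119)


def planted_pair_data(rng, n_per_class=60, informative=0):
    """Two classes separated by a single feature column, zero noise."""
    X = rng.integers(0, 3, size=(2 * n_per_class, 144)).astype(float)
    y = np.array([1] * n_per_class + [0] * n_per_class)
    X[:, informative] = np.where(y == 1, 5.0, 0.0)
    return X, y


class TestTrainEnsemble:
    def test_hundred_members_and_all_pairs(self, model):
        assert model.n_members == 100
        assert set(model.pair_models) == set(class_pairs())
        for pm in model.pair_models.values():
            assert len(pm.members) == 10

    def test_member_weights_sparse_under_l1(self, model):
        """Planted single-motif rules + L1 at c=0.1 zero out most weights."""
        weights = np.concatenate(
            [m.weights for pm in model.pair_models.values() for m in pm.members]
        )
        assert np.mean(weights == 0.0) >= 0.90

    def test_separable_pair_trains_to_perfection(self, rng):
        X, y = planted_pair_data(rng)
        labels = [ColorClass.GREEN if t else ColorClass.RED for t in y]
        # pad remaining classes with well-separated dummy rows
        pads, pad_labels = [], []
        for j, c in enumerate((ColorClass.DARK, ColorClass.FARRED, ColorClass.NIR)):
            P = rng.integers(0, 3, size=(10, 144)).astype(float)
            P[:, 100 + j] = 9.0
            pads.append(P)
            pad_labels += [c] * 10
        X_all = np.vstack([X, *pads])
        labels_all = labels + pad_labels
        m = train_ensemble(X_all, labels_all, TrainingConfig(seed=0))
        pm = m.pair_models[(ColorClass.GREEN, ColorClass.RED)]
        for member in pm.members:
            pred = (member.decision(X) > 0).astype(int)
            assert np.mean(pred == y) == 1.0

    def test_requires_two_members_per_class(self, rng):
        X = rng.integers(0, 3, size=(5, 144)).astype(float)
        labels = [ColorClass.DARK, ColorClass.GREEN, ColorClass.RED, ColorClass.FARRED, ColorClass.NIR]
        with pytest.raises(ValueError, match="need >= 2"):
            train_ensemble(X, labels)


def toy_model(members_margins):
    """Hand-built single-pair model whose members emit fixed margins for x=0."""
    pair = (ColorClass.GREEN, ColorClass.RED)
    members = [
        PairMember(weights=np.zeros(144), bias=float(b), subsample_index=i)
        for i, b in enumerate(members_margins)
    ]
    return EnsembleModel(
        pair_models={pair: PairModel(pair=pair, members=members)},
        feature_names=feature_names(),
        config=TrainingConfig(),
    )


class TestPairProbability:
    def test_zero_margin_is_half(self):
        m = toy_model([0.0])
        x = np.zeros(144)
        assert pair_probability(m, (ColorClass.GREEN, ColorClass.RED), x) == 0.5

    def test_sigmoid_symmetry_average(self):
        m = toy_model([1.0, -1.0])
        x = np.zeros(144)
        p = pair_probability(m, (ColorClass.GREEN, ColorClass.RED), x)
        assert p == pytest.approx((sigmoid(1) + sigmoid(-1)) / 2)
        assert p == pytest.approx(0.5)

    def test_saturation_with_large_margin(self):
        m = toy_model([50.0] * 10)
        x = np.zeros(144)
        assert pair_probability(m, (ColorClass.GREEN, ColorClass.RED), x) > 1 - 1e-12

    def test_complement_identity(self, model, split):
        (_, _), (X_te, _) = split
        for pair in class_pairs():
            p = pair_probability(model, pair, X_te[:50])
            q = pair_probability(model, (pair[1], pair[0]), X_te[:50])
            assert np.all(np.abs(p + q - 1.0) < 1e-12)

    def test_unknown_pair_rejected(self, model):
        with pytest.raises(KeyError):
            pair_probability(
                toy_model([0.0]), (ColorClass.DARK, ColorClass.NIR), np.zeros(144)
            )


class TestPredictClass:
    def test_consensus_accuracy_on_holdout(self, model, split):
        """Planted-rule data at zero label noise: >= 0.95 held-out accuracy."""
        _, (X_te, y_te) = split
        pred = predict_classes(model, X_te)
        acc = float(np.mean([p is t for p, t in zip(pred, y_te)]))
        assert acc >= 0.95

    def test_symmetric_model_ties_flag_and_break_low(self):
        m = toy_model([0.0])
        m.classes = (ColorClass.GREEN, ColorClass.RED)
        # single pair: both classes score 0.5 -> tie, canonical order wins
        cls, table, tie = predict_class(m, np.zeros(144))
        assert tie
        assert cls is ColorClass.GREEN  # Green < Red in canonical order

    def test_minority_recall_beats_unbalanced_single_classifier(self, split):
        """Balanced subsampling lifts NIR recall over one raw-imbalance SVM."""
        from agndesign.ensemble import _fit_member

        (X_tr, y_tr), (X_te, y_te) = split
        pair = (ColorClass.FARRED, ColorClass.NIR)
        tr_mask = np.array([l in pair for l in y_tr])
        te_mask = np.array([l in pair for l in y_te])
        Xp, yp = X_tr[tr_mask], np.array([l is ColorClass.NIR for l in y_tr])[tr_mask]
        Xq, yq = X_te[te_mask], np.array([l is ColorClass.NIR for l in y_te])[te_mask]
        raw = _fit_member(Xp, yp.astype(int), TrainingConfig(), 0, seed=0)
        raw_recall = float(np.mean((raw.decision(Xq[yq]) > 0)))
        m = train_ensemble(X_tr, y_tr, TrainingConfig(seed=1))
        p = pair_probability(m, (ColorClass.NIR, ColorClass.FARRED), Xq[yq])
        ens_recall = float(np.mean(p > 0.5))
        assert ens_recall >= raw_recall


class TestSerialization:
    def test_round_trip_bit_identical(self, model, split, tmp_path):
        _, (X_te, _) = split
        path = tmp_path / "model.json"
        model.save(path)
        loaded = EnsembleModel.load(path)
        for pair in class_pairs():
            a = pair_probability(model, pair, X_te[:100])
            b = pair_probability(loaded, pair, X_te[:100])
            assert np.array_equal(a, b)


class TestCrossValidate:
    def test_planted_pairs_learnable(self, split):
        (X_tr, y_tr), _ = split
        report = cross_validate(X_tr, y_tr, TrainingConfig(seed=3, n_cv_repeats=3))
        assert len(report.entries) == 10  # C(5,2)
        for (a, b), (mean, sd) in report.entries.items():
            assert 0.0 <= mean <= 1.0
            assert mean >= 0.95  # zero label noise, linear rule

    def test_shuffled_labels_give_chance_accuracy(self, split):
        """Permutation null: accuracy 0.5 +/- 0.05 over 100 repeats."""
        (X_tr, y_tr), _ = split
        rng = np.random.default_rng(11)
        mask = np.array([l in (ColorClass.GREEN, ColorClass.RED) for l in y_tr])
        X = X_tr[mask][:300]
        y = rng.permutation(
            np.array([ColorClass.GREEN, ColorClass.RED])[
                rng.integers(0, 2, size=X.shape[0])
            ]
        )
        report = cross_validate(X, list(y), TrainingConfig(seed=5, n_cv_repeats=100))
        (mean, sd) = report.entries[(ColorClass.GREEN, ColorClass.RED)]
        assert abs(mean - 0.5) <= 0.05

    def test_small_class_skipped_with_warning(self, rng):
        X = rng.integers(0, 3, size=(25, 144)).astype(float)
        labels = [ColorClass.GREEN] * 20 + [ColorClass.RED] * 5
        with pytest.warns(UserWarning, match="skipping pair"):
            report = cross_validate(X, labels, TrainingConfig(n_cv_repeats=1))
        assert report.entries == {}
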