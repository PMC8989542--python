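"""Training protocol: standardization, folds, detrend calibration, early
stopping, correlation evaluation, cross-validation bookkeeping."""

import numpy as np
import pytest

from dnabend.model import DegenerateLabelsError, IRLSTMRegressor, fit_detrend_values
from dnabend.synth import make_library
from dnabend.training import (
    SequenceLibrary,
    cross_validate,
    fit_detrend,
    kfold_split,
    pearson,
    standardize_labels,
    train_model,
)

from conftest import TINY, random_seqs


class TestStandardizeLabels:
    def test_mean_zero_sd_one(self):
        lib = SequenceLibrary("t", random_seqs(3, 50), [1.0, 2.0, 3.0])
        out, mean, std = standardize_labels(lib)
        assert abs(out.labels.mean()) < 1e-12
        assert abs(out.labels.std() - 1.0) < 1e-12
        assert np.allclose(out.labels * std + mean, lib.labels, atol=1e-12)

    def test_idempotent_on_standardized(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        y = (y - y.mean()) / y.std()
        lib = SequenceLibrary("t", random_seqs(4, 50), y)
        out, _, _ = standardize_labels(lib)
        assert np.allclose(out.labels, y, atol=1e-12)

    def test_constant_labels_error(self):
        lib = SequenceLibrary("t", random_seqs(3, 50), [2.0, 2.0, 2.0])
        with pytest.raises(DegenerateLabelsError):
            standardize_labels(lib)


class TestKFold:
    def test_balanced_sizes(self):
        a = kfold_split(100, 10, seed=1)
        assert sorted(np.bincount(a)[1:]) == [10] * 10

    def test_pigeonhole_12_into_10(self):
        sizes = sorted(np.bincount(kfold_split(12, 10, seed=0))[1:])
        assert sizes == [1] * 8 + [2] * 2

    def test_deterministic_under_seed(self):
        assert np.array_equal(kfold_split(57, 10, seed=4), kfold_split(57, 10, seed=4))

    def test_partition_matches_naive_bookkeeping(self):
        n, k = 83, 7
        a = kfold_split(n, k, seed=2)
        assert a.min() == 1 and a.max() == k
        assert len(a) == n
        sizes = np.bincount(a)[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_too_few_items(self):
        with pytest.raises(ValueError):
            kfold_split(5, 10)


class TestPearson:
    def test_perfect_and_anti(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # r for x=(1,2,3), y=(1,2,4) from the product-moment definition:
        # cov = 3/2; sd_x = sqrt(2/3)*...  computed directly below
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        expected = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_error(self):
        with pytest.raises(DegenerateLabelsError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDetrend:
    @pytest.mark.parametrize(
        "transform,expected",
        [
            (lambda y: y, (0.0, 1.0)),          # identity
            (lambda y: y - 5.0, (5.0, 1.0)),    # pure mean drift
            (lambda y: 0.5 * y, (0.0, 2.0)),    # pure variance shrinkage
        ],
    )
    def test_worked_examples(self, transform, expected):
        labels = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        a, b = fit_detrend_values(transform(labels), labels)
        assert a == pytest.approx(expected[0], abs=1e-10)
        assert b == pytest.approx(expected[1], abs=1e-10)

    def test_least_squares_identities(self):
        """After calibration the corrected outputs match the labels in mean,
        and the OLS slope of labels on corrected outputs is exactly 1."""
        rng = np.random.default_rng(0)
        labels = rng.normal(size=300)
        raw = 0.6 * labels - 0.8 + rng.normal(0, 0.3, size=300)
        a, b = fit_detrend_values(raw, labels)
        corrected = a + b * raw
        assert corrected.mean() == pytest.approx(labels.mean(), abs=1e-8)
        slope = np.polyfit(corrected, labels, 1)[0]
        assert slope == pytest.approx(1.0, abs=1e-8)

    def test_zero_variance_raw_error(self):
        with pytest.raises(DegenerateLabelsError):
            fit_detrend_values(np.zeros(5), np.arange(5.0))

    def test_fit_detrend_stores_on_model(self, tiny_trained_model):
        est, lib = tiny_trained_model
        calib = lib.subset(np.arange(100))
        a, b = fit_detrend(est, calib)
        assert (est.detrend_a_, est.detrend_b_) == (a, b)
        corrected = est.predict(calib.sequences)
        assert corrected.mean() == pytest.approx(calib.labels.mean(), abs=1e-8)


class TestTraining:
    def test_constant_target_fit(self):
        """With all-zero labels (standardization off) the model collapses
        to predicting approximately zero."""
        seqs = random_seqs(300, 50, seed=8)
        est = IRLSTMRegressor(random_state=0, max_epochs=8, standardize=False,
                              detrend=False, **TINY)
        est.fit(seqs, np.zeros(300))
        val_mse = min(est.history_["val_mse"])
        assert val_mse < 0.05
        assert np.abs(est.predict(seqs[:20])).max() < 0.5

    def test_checkpoint_never_worse_than_history(self, tiny_trained_model):
        est, _ = tiny_trained_model
        assert est.history_["val_mse"][est.best_epoch_ - 1] == min(
            est.history_["val_mse"]
        )

    def test_restored_weights_reproduce_best_val_mse(self):
        lib = make_library(400, seed=9)
        tr, va = lib.subset(np.arange(300)), lib.subset(np.arange(300, 400))
        est = IRLSTMRegressor(random_state=1, max_epochs=4, **TINY)
        est.fit(tr.sequences, tr.labels, X_val=va.sequences, y_val=va.labels)
        yv = (va.labels - est.label_mean_) / est.label_std_
        # recompute the checkpointed val MSE from the restored weights
        from dnabend.model import _as_onehot
        pred = est._forward_batched(_as_onehot(va.sequences))
        mse = float(np.mean((pred - yv) ** 2))
        assert mse == pytest.approx(min(est.history_["val_mse"]), abs=1e-12)

    def test_patience_zero_stops_one_epoch_after_first_non_improvement(self):
        lib = make_library(400, seed=10)
        est = IRLSTMRegressor(random_state=2, max_epochs=30, patience=0, **TINY)
        est.fit(lib.sequences, lib.labels)
        if est.n_epochs_ < 30:  # stopped early
            assert est.n_epochs_ == est.best_epoch_ + 1

    def test_empty_validation_rejected(self):
        seqs = random_seqs(5, 50, seed=0)
        est = IRLSTMRegressor(validation_fraction=0.0, **TINY)
        with pytest.raises(ValueError, match="validation"):
            est.fit(seqs, np.arange(5.0))

    def test_train_model_wrapper(self):
        lib = make_library(300, seed=12)
        est = train_model(lib, config=dict(max_epochs=2, **TINY), seed=5)
        assert est.n_epochs_ <= 2
        assert np.isfinite(est.predict(lib.sequences[:5])).all()


class TestCrossValidation:
    def test_folds_cover_every_sequence_once(self):
        lib = make_library(120, seed=13)
        cv = cross_validate(lib, config=dict(max_epochs=1, **TINY), k=3, seed=0)
        assert sorted(np.unique(cv.fold_assignments)) == [1, 2, 3]
        assert len(cv.fold_assignments) == 120
        assert len(cv.per_fold_models) == 3
        assert all(-1 <= r <= 1 for r in cv.per_fold_pearson)
        assert cv.best_fold_index == int(np.argmax(cv.per_fold_pearson))
        report = cv.report()
        assert report["n_test"].sum() == 120
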