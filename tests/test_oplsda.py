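import numpy as np
import pytest

import metaboclass as mc
from metaboclass.latent import ModelError, ScalingSpec
from metaboclass.oplsda import (
    ConfusionSummary,
    confusion_from_cv,
    cross_validate,
    cv_anova,
    fit_oplsda,
    predict,
)
from .conftest import group_rows, processed_cohort


def two_class_data(rng, n_per=12, k=10, sep=2.0):
    X = rng.normal(size=(2 * n_per, k))
    X[:n_per, 0] += sep
    labels = ["case"] * n_per + ["ctrl"] * n_per
    return X, labels


class TestFit:
    def test_zero_ortho_matches_pls1_oracle(self):
        """With no orthogonal components the predictive score equals the
        first component of textbook PLS1 on the same scaled data."""
        rng = np.random.default_rng(0)
        X, labels = two_class_data(rng)
        m = fit_oplsda(X, labels, n_ortho=0)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        y = np.array([1.0] * 12 + [-1.0] * 12)
        yc = y - y.mean()
        w = Xs.T @ yc
        w /= np.linalg.norm(w)
        t = Xs @ w
        cos = abs(t @ m.t_pred) / (np.linalg.norm(t) * np.linalg.norm(m.t_pred))
        assert cos > 1 - 1e-8

    def test_feature_identical_to_response_has_pcorr_one(self):
        """When one column is the class coding and the rest carry no class
        signal, the predictive score aligns with y and that column's
        p(corr) is exactly 1."""
        rng = np.random.default_rng(1)
        y = np.array([1.0] * 12 + [-1.0] * 12)
        X = rng.normal(size=(24, 10))
        X -= np.outer(y, y @ X) / (y @ y)  # other columns orthogonal to y
        X[:, 3] = y
        labels = ["case"] * 12 + ["ctrl"] * 12
        m = fit_oplsda(X, labels, n_ortho=0,
                       scaling=ScalingSpec(center=True, mode="none"))
        assert m.pcorr[3] == pytest.approx(1.0, abs=1e-8)

    def test_orthogonality_invariants(self):
        rng = np.random.default_rng(2)
        X, labels = two_class_data(rng)
        m = fit_oplsda(X, labels, n_ortho=2)
        y = np.array([1.0] * 12 + [-1.0] * 12)
        yc = y - y.mean()
        for a in range(2):
            assert abs(m.t_ortho[:, a] @ yc) < 1e-8
            assert abs(m.t_ortho[:, a] @ m.t_pred) < 1e-8
        assert np.all(np.abs(m.pcorr) <= 1.0)

    def test_variance_bookkeeping(self):
        """SS of scaled X = predictive + orthogonal + residual parts."""
        rng = np.random.default_rng(3)
        X, labels = two_class_data(rng)
        m = fit_oplsda(X, labels, n_ortho=2)
        Xs = (X - m.means) * m.scale_weights
        recon = np.outer(m.t_pred, m.p_pred)
        for a in range(m.n_ortho):
            recon += np.outer(m.t_ortho[:, a], m.p_ortho[:, a])
        ss_resid = np.sum((Xs - recon) ** 2)
        captured = m.r2x * m.ss_x_scaled
        assert captured + ss_resid == pytest.approx(m.ss_x_scaled, rel=1e-8)

    def test_one_class_and_excess_ortho_rejected(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 5))
        with pytest.raises(ModelError, match="two classes"):
            fit_oplsda(X, ["a"] * 10)
        with pytest.raises(ModelError):
            fit_oplsda(X, ["a"] * 5 + ["b"] * 5, n_ortho=50)

    def test_permuted_labels_shrink_pcorr(self):
        """Planted effects dominate |p(corr)| over label permutations."""
        eff = mc.default_effectspec()
        planted = [f for f, d in eff.offsets.items() if "SLE" in d]
        gaps = []
        for seed in range(5):
            table, metadata = processed_cohort(seed)
            mask, pooled = group_rows(table, metadata, ("SLE", "HV"))
            X, labels = table.values[mask], list(pooled[mask])
            m = fit_oplsda(X, labels, n_ortho=1, positive_class="SLE")
            idx = [table.feature_names.index(f) for f in planted]
            planted_med = np.median(np.abs(m.pcorr[idx]))
            rng = np.random.default_rng(seed)
            perm = list(rng.permutation(labels))
            mp = fit_oplsda(X, perm, n_ortho=1, positive_class="SLE")
            gaps.append(planted_med - np.quantile(np.abs(mp.pcorr), 0.95))
        assert np.median(gaps) > 0


class TestPredict:
    def test_class_means_map_to_opposite_signs(self):
        rng = np.random.default_rng(5)
        X, labels = two_class_data(rng, sep=3.0)
        m = fit_oplsda(X, labels, n_ortho=1, positive_class="case")
        y_hat, pred = predict(m, np.vstack([X[:12].mean(0), X[12:].mean(0)]))
        assert y_hat[0] > 0 > y_hat[1]
        assert pred == ["case", "ctrl"]

    def test_training_grand_mean_gets_positive_tie_rule(self):
        rng = np.random.default_rng(6)
        X, labels = two_class_data(rng)  # balanced -> y_mean = 0
        m = fit_oplsda(X, labels, n_ortho=1, positive_class="case")
        y_hat, pred = predict(m, X.mean(0))
        assert y_hat[0] == pytest.approx(0.0, abs=1e-10)
        assert pred == ["case"]

    def test_orthogonal_loading_direction_filtered_exactly(self):
        """Adding any multiple of p_o (in raw units) leaves ŷ unchanged."""
        rng = np.random.default_rng(7)
        X, labels = two_class_data(rng)
        m = fit_oplsda(X, labels, n_ortho=1)
        x = X[5].copy()
        y0, _ = predict(m, x)
        shift = m.p_ortho[:, 0] / m.scale_weights  # undo scaling
        y1, _ = predict(m, x + 13.7 * shift)
        assert y1[0] == pytest.approx(y0[0], abs=1e-8)

    def test_column_mismatch_raises(self):
        rng = np.random.default_rng(8)
        X, labels = two_class_data(rng)
        m = fit_oplsda(X, labels)
        with pytest.raises(ModelError):
            predict(m, np.ones((2, 3)))


class TestCrossValidate:
    def test_loo_supported_and_deterministic(self):
        rng = np.random.default_rng(9)
        X, labels = two_class_data(rng, n_per=6)
        cv1 = cross_validate(X, labels, 1, folds=len(labels))
        cv2 = cross_validate(X, labels, 1, folds=len(labels))
        np.testing.assert_array_equal(cv1.y_hat_cv, cv2.y_hat_cv)
        assert len(np.unique(cv1.fold_assignment)) == 6

    def test_every_sample_predicted_once(self):
        rng = np.random.default_rng(10)
        X, labels = two_class_data(rng)
        cv = cross_validate(X, labels, 1, folds=7)
        assert not np.any(np.isnan(cv.y_hat_cv))

    def test_folds_stratified_by_class(self):
        """Round-robin assignment spreads each class across the folds, so
        no training split can lose a class."""
        rng = np.random.default_rng(11)
        X, labels = two_class_data(rng, n_per=7)
        cv = cross_validate(X, labels, 0, folds=3)
        labels_arr = np.array(labels)
        for cls in ("case", "ctrl"):
            per_fold = np.bincount(cv.fold_assignment[labels_arr == cls],
                                   minlength=3)
            assert per_fold.max() - per_fold.min() <= 1


class TestCvAnova:
    def make_cv(self, y, y_hat, n_ortho=1):
        from metaboclass.oplsda import CvPrediction

        return CvPrediction(
            y=y, y_hat_cv=y_hat, fold_assignment=np.zeros(len(y), int),
            q2=1 - np.sum((y - y_hat) ** 2) / np.sum((y - y.mean()) ** 2),
            positive_class="a", negative_class="b", n_ortho=n_ortho,
        )

    def test_perfect_prediction_p_tends_to_zero(self):
        y = np.array([1.0] * 8 + [-1.0] * 8)
        res = cv_anova(self.make_cv(y, y.copy()))
        assert res.p == pytest.approx(0.0, abs=1e-300)

    def test_mean_prediction_gives_f_zero_p_one(self):
        y = np.array([1.0] * 8 + [-1.0] * 8)
        res = cv_anova(self.make_cv(y, np.full(16, y.mean())))
        assert res.F == 0.0 and res.p == 1.0

    def test_null_p_values_calibrated(self):
        """Fraction of null-data models with p < 0.05 stays near 0.05."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(24, 10))
            labels = ["a", "b"] * 12
            cv = cross_validate(X, labels, 1, folds=7)
            hits += cv_anova(cv).p < 0.05
        assert abs(hits / n_seeds - 0.05) < 0.04

    def test_df_error_guard(self):
        y = np.array([1.0, 1.0, -1.0])
        with pytest.raises(ModelError):
            cv_anova(self.make_cv(y, y, n_ortho=1))


class TestConfusion:
    def test_all_correct(self):
        y = np.array([1.0] * 5 + [-1.0] * 5)
        cv = TestCvAnova().make_cv(y, y * 0.8)
        c = confusion_from_cv(cv)
        assert c.sensitivity == 1.0 and c.specificity == 1.0

    def test_all_predicted_positive(self):
        y = np.array([1.0] * 5 + [-1.0] * 5)
        cv = TestCvAnova().make_cv(y, np.ones(10))
        c = confusion_from_cv(cv)
        assert c.sensitivity == 1.0 and c.specificity == 0.0

    def test_count_conservation(self):
        rng = np.random.default_rng(12)
        y = np.array([1.0] * 7 + [-1.0] * 9)
        cv = TestCvAnova().make_cv(y, rng.normal(size=16))
        c = confusion_from_cv(cv)
        assert c.tp + c.fn == 7 and c.tn + c.fp == 9

    def test_stated_formulas_on_hand_counts(self):
        c = ConfusionSummary(tp=59, fn=41, tn=86, fp=14)
        assert c.sensitivity == pytest.approx(0.59)
        assert c.specificity == pytest.approx(0.86)
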