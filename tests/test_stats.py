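import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import metaboclass as mc
from metaboclass.latent import fit_pca
from metaboclass.stats import (
    StatsError,
    pca_score_roc,
    roc_auc,
    significance_table,
    welch_ttest,
)
from .conftest import processed_cohort


def welch_formula(a, b):
    """Independent textbook evaluation of the Welch statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_samples_give_t0_p1(self):
        r = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0

    def test_matches_textbook_formula_example(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        t, df, p = welch_formula(a, b)
        r = welch_ttest(a, b)
        assert r.t == pytest.approx(t, abs=1e-12)
        assert r.df == pytest.approx(df, abs=1e-12)
        assert r.p == pytest.approx(p, abs=1e-12)
        # frozen sanity values for the hand example
        assert t == pytest.approx(-1.0954451150103321, abs=1e-12)
        assert df == pytest.approx(6.0, abs=1e-12)

    def test_matches_formula_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2),
                           size=rng.integers(3, 20))
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2),
                           size=rng.integers(3, 20))
            t, df, p = welch_formula(a, b)
            r = welch_ttest(a, b)
            assert abs(r.p - p) < 1e-10
            assert abs(r.t - t) < 1e-10

    def test_shift_monotonically_decreases_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        ps = [welch_ttest(a, b + shift).p for shift in np.linspace(2, 6, 8)]
        assert all(q < p or q < 1e-12 for p, q in zip(ps, ps[1:]))

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=10)
        r1, r2 = welch_ttest(a, b), welch_ttest(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)
        assert r1.df == pytest.approx(r2.df)

    def test_small_samples_rejected(self):
        with pytest.raises(StatsError):
            welch_ttest([1.0], [1.0, 2.0])

    def test_degenerate_zero_variance_rules(self):
        assert welch_ttest([2.0, 2.0], [2.0, 2.0]).p == 1.0
        assert welch_ttest([3.0, 3.0], [2.0, 2.0]).p == 0.0


class TestRoc:
    def test_perfect_separation(self):
        curve = roc_auc([3.0, 2.5, 2.0, 1.0, 0.5, 0.1],
                        [True, True, True, False, False, False])
        assert curve.auc == 1.0

    def test_all_tied_scores_give_half(self):
        curve = roc_auc([1.0] * 8, [True] * 4 + [False] * 4)
        assert curve.auc == 0.5

    def test_matches_mann_whitney_pair_count(self):
        """Trapezoidal AUC equals concordant pairs + half ties, exactly."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            scores = rng.integers(0, 6, size=30).astype(float)  # many ties
            labels = rng.random(30) < 0.4
            if labels.all() or not labels.any():
                continue
            pos, neg = scores[labels], scores[~labels]
            pairs = sum(
                1.0 if p > n else 0.5 if p == n else 0.0
                for p in pos for n in neg
            )
            expected = pairs / (len(pos) * len(neg))
            assert roc_auc(scores, labels).auc == pytest.approx(
                expected, abs=1e-12
            )

    def test_complement_identity(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=25)
        labels = rng.random(25) < 0.5
        labels[0], labels[1] = True, False
        a1 = roc_auc(scores, labels).auc
        a2 = roc_auc(-scores, labels).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_curve_ends_and_stored_auc_consistent(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        c = roc_auc(scores, labels)
        assert (c.fpr[0], c.tpr[0]) == (0.0, 0.0)
        assert (c.fpr[-1], c.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(c.fpr) >= 0) and np.all(np.diff(c.tpr) >= 0)
        assert c.auc == pytest.approx(np.trapezoid(c.tpr, c.fpr), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(6)
        scores = rng.normal(size=50) + rng.integers(0, 2, 50)
        labels = rng.random(50) < 0.5
        labels[0], labels[1] = True, False
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(StatsError):
            roc_auc([1.0, 2.0], [True, True])


class TestPcaScoreRoc:
    def test_labels_equal_to_score_sign_give_auc_one(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 6))
        m = fit_pca(X, 2)
        labels = m.scores[:, 0] > 0
        res = pca_score_roc(m, labels, components=(1,))
        assert res[1]["auc"] == 1.0

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 10))
        m = fit_pca(X, 2)
        labels = rng.permutation([True] * 40 + [False] * 40)
        res = pca_score_roc(m, labels, components=(1, 2))
        for comp in (1, 2):
            assert 0.5 <= res[comp]["auc"] <= 0.6  # oriented >= 0.5

    def test_component_beyond_model_rejected(self):
        rng = np.random.default_rng(9)
        m = fit_pca(rng.normal(size=(20, 5)), 2)
        with pytest.raises(StatsError):
            pca_score_roc(m, np.zeros(20, bool), components=(3,))


class TestSignificanceTable:
    def test_planted_directions_recovered(self):
        table, metadata = processed_cohort(1)
        frame = significance_table(table, metadata, ("SLE", "HV"))
        eff = mc.default_effectspec()
        planted = {f: d["SLE"] for f, d in eff.offsets.items() if "SLE" in d}
        hits = 0
        for f, delta in planted.items():
            row = frame[frame.feature == f].iloc[0]
            hits += row.significant and np.sign(row.mean_log_diff) == np.sign(delta)
        assert hits >= 18

    def test_null_false_positive_rate_calibrated(self):
        counts = []
        for seed in range(20):
            table, metadata = mc.generate_cohort(
                mc.GeneratorConfig(seed=seed), mc.EffectSpec()
            )
            table = mc.apply_normalizer(table, mc.fit_is_normalizer(table))
            metadata = mc.pool_sle_subgroups(metadata)
            frame = significance_table(
                mc.filter_features(table, True, False), metadata, ("SLE", "HV")
            )
            counts.append(int(frame.significant.sum()))
        assert abs(np.median(counts) - 0.05 * 243) <= 7

    def test_alpha_one_flags_everything(self):
        table, metadata = processed_cohort(2)
        frame = significance_table(table, metadata, ("SLE", "HV"), alpha=1.0)
        assert frame.significant.all()

    def test_bh_correction_is_more_conservative(self):
        table, metadata = processed_cohort(3)
        raw = significance_table(table, metadata, ("SLE", "HV"))
        bh = significance_table(table, metadata, ("SLE", "HV"),
                                bh_correct=True)
        assert bh.significant.sum() <= raw.significant.sum()
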