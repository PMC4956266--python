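import numpy as np
import pytest

import metaboclass as mc
from metaboclass.latent import ModelError, ScalingSpec, dmodx
from metaboclass.simca import classify, fit_simca, loo_validate
from metaboclass.tables import FeatureAnnotation, MetaboliteTable, SampleMetadata
from .conftest import processed_cohort


def toy_two_class(rng, n_per=15, k=8, sep=6.0):
    """Two well-separated Gaussian clouds as a table + metadata."""
    X = rng.normal(size=(2 * n_per, k))
    X[:n_per, :2] += sep
    X = np.exp(X * 0.1)  # keep values positive
    feats = [FeatureAnnotation(f"m{j}", identified=True, chem_class="other")
             for j in range(k)]
    ids = [f"S{i}" for i in range(2 * n_per)]
    table = MetaboliteTable(X, ids, feats)
    meta = [SampleMetadata(ids[i], "SLE_G1" if i < n_per else "HV")
            for i in range(2 * n_per)]
    meta = mc.pool_sle_subgroups(meta)
    return table, meta


class TestFit:
    def test_training_samples_inside_own_model(self):
        """On default synthetic cohorts, >= 90% of each class's training
        samples sit inside their own class model (20-seed median)."""
        fracs = []
        for seed in range(20):
            table, metadata = processed_cohort(seed)
            ids = [m.sample_id for m in metadata
                   if m.pooled_group in ("SLE", "HV")]
            sub = table.subset_samples(ids)
            model = fit_simca(sub, metadata, ["SLE", "HV"],
                              components={"SLE": 2, "HV": 2})
            by_id = {m.sample_id: m.pooled_group for m in metadata}
            inside = []
            for c in model.classes:
                rows = [i for i, s in enumerate(sub.sample_ids)
                        if by_id[s] == c.label]
                res = dmodx(c.model, sub.values[rows], is_training=True)
                inside.extend(res.dmodx_norm <= c.dcrit)
            fracs.append(np.mean(inside))
        assert np.median(fracs) >= 0.90

    def test_single_class_model_is_valid_outlier_detector(self):
        rng = np.random.default_rng(0)
        table, meta = toy_two_class(rng)
        model = fit_simca(table, meta, ["HV"], components={"HV": 2})
        assert model.labels == ["HV"]
        dists, coomans = classify(model, table, meta)
        assert coomans is None and "HV" in dists

    def test_absent_class_raises(self):
        rng = np.random.default_rng(1)
        table, meta = toy_two_class(rng)
        with pytest.raises(ModelError, match="pSS"):
            fit_simca(table, meta, ["pSS"], components={"pSS": 1})

    def test_too_few_samples_raises(self):
        rng = np.random.default_rng(2)
        table, meta = toy_two_class(rng, n_per=4)
        with pytest.raises(ModelError, match="SLE"):
            fit_simca(table, meta, ["SLE", "HV"],
                      components={"SLE": 3, "HV": 3})


class TestClassify:
    def test_class_mean_inside_its_model(self):
        rng = np.random.default_rng(3)
        table, meta = toy_two_class(rng)
        model = fit_simca(table, meta, ["SLE", "HV"],
                          components={"SLE": 2, "HV": 2})
        mean_row = table.values[:15].mean(0, keepdims=True)
        feats = table.features
        probe = MetaboliteTable(mean_row, ["probe"], feats)
        dists, _ = classify(model, probe)
        assert dists["SLE"]["inside"][0]

    def test_far_sample_outside_both(self):
        rng = np.random.default_rng(4)
        table, meta = toy_two_class(rng)
        model = fit_simca(model_table := table, metadata := meta,
                          ["SLE", "HV"], components={"SLE": 2, "HV": 2})
        far = MetaboliteTable(
            table.values[:1] * 50.0, ["far"], table.features
        )
        dists, _ = classify(model, far)
        assert not dists["SLE"]["inside"][0]
        assert not dists["HV"]["inside"][0]

    def test_coomans_quadrants_match_membership(self):
        rng = np.random.default_rng(5)
        table, meta = toy_two_class(rng)
        model = fit_simca(table, meta, ["SLE", "HV"],
                          components={"SLE": 2, "HV": 2})
        dists, coomans = classify(model, table, meta)
        mem = coomans.membership()
        for i in range(table.n_samples):
            assert mem[i][0] == dists["SLE"]["inside"][i]
            assert mem[i][1] == dists["HV"]["inside"][i]
        assert np.all(coomans.d1 >= 0) and np.all(coomans.d2 >= 0)

    def test_feature_mismatch_raises(self):
        rng = np.random.default_rng(6)
        table, meta = toy_two_class(rng)
        model = fit_simca(table, meta, ["SLE", "HV"],
                          components={"SLE": 2, "HV": 2})
        other = MetaboliteTable(
            table.values[:, :4], table.sample_ids, table.features[:4]
        )
        with pytest.raises(ModelError, match="feature"):
            classify(model, other)


class TestLooValidate:
    def test_duplicated_rows_give_full_sensitivity(self):
        """A class of copies of two base rows is perfectly self-consistent:
        every held-out copy lies in the remaining model's plane."""
        rng = np.random.default_rng(7)
        base = np.exp(rng.normal(size=(2, 6)) * 0.2)
        rows = np.vstack([base] * 4)  # 8 samples, rank 2
        other = np.exp(rng.normal(2.0, 0.2, size=(8, 6)))
        values = np.vstack([rows, other])
        feats = [FeatureAnnotation(f"m{j}", identified=True,
                                   chem_class="other") for j in range(6)]
        ids = [f"S{i}" for i in range(16)]
        meta = [SampleMetadata(ids[i], "SLE_G1" if i < 8 else "HV")
                for i in range(16)]
        meta = mc.pool_sle_subgroups(meta)
        table = MetaboliteTable(values, ids, feats)
        summaries, _ = loo_validate(
            table, meta, ["SLE", "HV"], components={"SLE": 1, "HV": 1},
            scaling=ScalingSpec(center=True, mode="none"),
        )
        assert summaries["SLE"].sensitivity == 1.0

    def test_loo_coomans_and_confusion_consistent(self):
        table, metadata = processed_cohort(4)
        ids = [m.sample_id for m in metadata if m.pooled_group in ("SLE", "HV")]
        sub = table.subset_samples(ids)
        summaries, coomans = loo_validate(
            sub, metadata, ["SLE", "HV"], components={"SLE": 2, "HV": 2}
        )
        assert set(summaries) == {"SLE", "HV"}
        for s in summaries.values():
            assert s.tp + s.fn + s.tn + s.fp == sub.n_samples
        assert len(coomans.d1) == sub.n_samples

    def test_null_rejection_rate_near_alpha(self):
        """One Gaussian population split into two arbitrary 'classes':
        LOO own-class rejection approximates the nominal alpha."""
        rejections, total = 0, 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            L = rng.normal(size=(20, 3))
            X = rng.normal(size=(500, 3)) @ L.T + rng.normal(
                scale=0.5, size=(500, 20)
            )
            X = np.exp(X * 0.05)
            feats = [FeatureAnnotation(f"m{j}", identified=True,
                                       chem_class="other") for j in range(20)]
            ids = [f"S{i}" for i in range(500)]
            meta = [SampleMetadata(ids[i], "SLE_G1" if i < 250 else "HV")
                    for i in range(500)]
            meta = mc.pool_sle_subgroups(meta)
            table = MetaboliteTable(X, ids, feats)
            summaries, _ = loo_validate(
                table, meta, ["SLE", "HV"],
                components={"SLE": 3, "HV": 3},
                scaling=ScalingSpec(center=True, mode="none"),
            )
            for s in summaries.values():
                rejections += s.fn
                total += s.tp + s.fn
        assert abs(rejections / total - 0.05) < 0.02

    def test_membership_invariant_to_row_order(self):
        table, metadata = processed_cohort(5)
        ids = [m.sample_id for m in metadata if m.pooled_group in ("SLE", "HV")]
        sub = table.subset_samples(ids)
        model = fit_simca(sub, metadata, ["SLE", "HV"],
                          components={"SLE": 2, "HV": 2})
        dists, _ = classify(model, sub)
        perm = list(np.random.default_rng(0).permutation(ids))
        sub_p = sub.subset_samples(perm)
        dists_p, _ = classify(model, sub_p)
        order = [perm.index(s) for s in ids]
        np.testing.assert_allclose(
            dists["SLE"]["dmodx"], dists_p["SLE"]["dmodx"][order], rtol=1e-12
        )
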