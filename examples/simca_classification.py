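"""SIMCA soft classification of SLE versus healthy volunteers.

One PCA model is fit per class; a sample belongs to a class when its
normalized distance to that model (DModX) is below the F-test critical
distance (DCrit at 5%).  Leave-one-out refitting gives honest sensitivity;
the fitted pair of models then softly classifies the pSS and SSc cohorts,
whose rejection rate is the models' specificity against related diseases.
"""

import metaboclass as mc

table, metadata = mc.generate_cohort(mc.GeneratorConfig(seed=1))
table = mc.filter_features(mc.apply_normalizer(table, mc.fit_is_normalizer(table)))
metadata = mc.pool_sle_subgroups(metadata)

ids = [m.sample_id for m in metadata if m.pooled_group in ("SLE", "HV")]
sub = table.subset_samples(ids)
components = {"SLE": 2, "HV": 2}

summaries, coomans = mc.loo_validate(sub, metadata, ["SLE", "HV"], components)
for label, c in summaries.items():
    print(f"{label} model: LOO sensitivity {c.sensitivity:.2f}, "
          f"specificity vs the other class {c.specificity:.2f} "
          f"(tp={c.tp} fn={c.fn} tn={c.tn} fp={c.fp})")

model = mc.fit_simca(sub, metadata, ["SLE", "HV"], components)
ext_ids = [m.sample_id for m in metadata if m.pooled_group in ("pSS", "SSc")]
dists, _ = mc.classify(model, table.subset_samples(ext_ids))
for label in ("SLE", "HV"):
    outside = 1.0 - dists[label]["inside"].mean()
    print(f"{label} model rejects {outside:.0%} of the pSS/SSc samples "
          "(specificity against related diseases)")
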