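"""Internal-standard normalization and PCA overview of the pooled cohort.

Fits the one-component non-centered PCA model on the 11 internal-standard
columns to estimate per-sample injection factors, normalizes, restricts to
the 73 identified analytes, and summarizes the cohort with a centered,
unit-variance PCA: R2X(cum) is the explained variance, Q2(cum) its
cross-validated counterpart, and per-score ROC AUCs quantify how well
single score vectors separate pairs of diagnoses.
"""

import numpy as np

import metaboclass as mc
from metaboclass.latent import fit_pca, q2_pca

table, metadata = mc.generate_cohort(mc.GeneratorConfig(seed=1))

norm = mc.fit_is_normalizer(table)
print("injection factors: min %.3f, median %.3f, max %.3f"
      % (norm.factors.min(), np.median(norm.factors), norm.factors.max()))

table = mc.filter_features(mc.apply_normalizer(table, norm))
metadata = mc.pool_sle_subgroups(metadata)
print(f"modeling set: {table.n_features} identified metabolites")

model = fit_pca(table.values, 4)
model.q2_cum = q2_pca(table.values, 4, folds=7)
print("overview PCA: R2X(cum) =", model.r2x_cum.round(3).tolist())
print("              Q2(cum)  =", model.q2_cum.round(3).tolist())

# does the first score vector separate SLE from HV?
pooled = np.array([m.pooled_group for m in metadata])
mask = np.isin(pooled, ("SLE", "HV"))
sub = fit_pca(table.values[mask], 2)
rocs = mc.pca_score_roc(sub, pooled[mask] == "SLE", components=(1, 2))
for comp, r in rocs.items():
    print(f"SLE vs HV AUC(t{comp}) = {r['auc']:.4f}")
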