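"""OPLS-DA discriminant profile: which metabolites separate SLE from HV?

A single predictive component plus one orthogonal component is fit to the
two-class data; each metabolite's p(corr) — the correlation between the
predictive score and its data column — summarizes its discriminatory
direction and strength.  Cross-validated Q2, CV-ANOVA and the ROC of the
cross-validated predictions quantify model reliability.
"""

import numpy as np

import metaboclass as mc

table, metadata = mc.generate_cohort(mc.GeneratorConfig(seed=1))
table = mc.filter_features(mc.apply_normalizer(table, mc.fit_is_normalizer(table)))
metadata = mc.pool_sle_subgroups(metadata)

pooled = np.array([m.pooled_group for m in metadata])
mask = np.isin(pooled, ("SLE", "HV"))
X, labels = table.values[mask], list(pooled[mask])

model = mc.fit_oplsda(X, labels, n_ortho=1, positive_class="SLE")
cv = mc.cross_validate(X, labels, n_ortho=1, folds=7, positive_class="SLE")
anova = mc.cv_anova(cv)
conf = mc.confusion_from_cv(cv)
roc = mc.roc_auc(cv.y_hat_cv, cv.y > 0)

print(f"R2Y = {model.r2y:.3f}, cross-validated Q2 = {cv.q2:.3f}")
print(f"CV-ANOVA: F = {anova.F:.1f}, p = {anova.p:.2e}")
print(f"CV confusion: sensitivity {conf.sensitivity:.2f}, "
      f"specificity {conf.specificity:.2f}; CV-ROC AUC = {roc.auc:.3f}")

order = np.argsort(model.pcorr)
names = table.feature_names
print("most decreased in SLE (negative p(corr)):")
for j in order[:5]:
    print(f"  {names[j]:<20s} p(corr) = {model.pcorr[j]:+.3f}")
print("most increased in SLE (positive p(corr)):")
for j in order[-5:][::-1]:
    print(f"  {names[j]:<20s} p(corr) = {model.pcorr[j]:+.3f}")
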