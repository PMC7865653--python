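"""LASSO selection, classifier comparison and external validation.

Splits a cohort into training and held-out validation patients, selects
predictors by cross-validated LASSO on the 0/1 label, compares LDA / SVM /
KNN / NNET / DT by stratified 10-fold CV, and scores the winning model once
on the validation cohort.
"""

from lesionrad import (
    PhantomConfig,
    external_validate,
    fit_classifiers,
    generate_cohort,
    lasso_select,
)
from lesionrad.features import ExtractionConfig, extract_cohort

records = generate_cohort(
    PhantomConfig(n_patients=60, mutant_fraction=0.5, lesions_per_patient=(1, 2),
                  diameter_mm=(18.0, 35.0), n_phases=2, texture_effect=1.0, seed=41)
)
X, y = extract_cohort(records, ExtractionConfig(), reader=1)
X = X.dropna(axis=1)
train, val = X.index[:44], X.index[44:]

sel = lasso_select(X.loc[train], y.loc[train], seed=0)
print(f"LASSO predictors (alpha={sel.alpha_opt:.4f}): {sel.selected}")

reports = fit_classifiers(X.loc[train, sel.selected], y.loc[train], seed=0)
print(f"\n{'model':6} {'median AUC':10} {'median ACC':10}")
for name, rep in reports.items():
    star = "*" if rep.winner else " "
    print(f"{name:6} {rep.cv_median['auc']:<10.3f} {rep.cv_median['acc']:<10.3f}{star}")

winner = next(r for r in reports.values() if r.winner)
ext = external_validate(
    winner.model, X.loc[train, sel.selected], y.loc[train],
    X.loc[val, sel.selected], y.loc[val], seed=0,
)
c = ext.confusion
print(f"\nexternal validation of {winner.model} on {len(val)} held-out patients:")
print(f"  confusion TP={c['tp']} TN={c['tn']} FP={c['fp']} FN={c['fn']}")
print(f"  ACC {100 * ext.external['acc']:.1f}%  SEN {100 * ext.external['sen']:.1f}%  "
      f"SPEC {100 * ext.external['spec']:.1f}%")
print("\n* marks the winning model (highest CV median AUC, ties by ACC); "
      "validation patients never touch training or standardization.")
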