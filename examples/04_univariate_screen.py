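"""Per-feature ROC screening with Youden cut-offs and BH-FDR.

On a cohort whose classes differ in co-occurrence structure, each feature
is tested with Wilcoxon-Mann-Whitney and characterized by its ROC curve:
AUC with a DeLong 95% CI, the Youden-optimal cut-off and the operating
metrics there.  Significance means the BH-adjusted p stays below 0.05.
"""

from lesionrad import PhantomConfig, generate_cohort, univariate_table
from lesionrad.features import ExtractionConfig, extract_cohort

records = generate_cohort(
    PhantomConfig(n_patients=40, mutant_fraction=0.5, lesions_per_patient=(1, 2),
                  diameter_mm=(18.0, 35.0), n_phases=2, texture_effect=1.0, seed=29)
)
X, y = extract_cohort(records, ExtractionConfig(), reader=1)
X = X.dropna(axis=1)

table = univariate_table(X, y)
cols = ["auc", "auc_ci_low", "auc_ci_high", "cutoff", "sen", "spec", "acc",
        "p_value", "p_adjusted"]
top = table.sort_values("auc", ascending=False).head(8)
print(top[cols].to_string(float_format="%.3f"))
n_sig = int(table["significant"].sum())
print(f"\n{n_sig} of {len(table)} features significant after FDR adjustment.")
print("co-occurrence features (contrast, dissimilarity, entropy) should "
      "dominate; morphology should not separate the classes, since the "
      "generator draws shapes identically for both.")
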