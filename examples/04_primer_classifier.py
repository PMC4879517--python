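"""Train the primer-efficiency decision-support models.

Labels synthetic 18-parameter primer vectors efficient/non-efficient by a
monotone rule on anchor-LD P and primer Tm, evaluates logistic regression,
RBF-SVM, decision tree and random forest by repeated stratified holdout,
and ranks the forest's feature importances.
"""

import numpy as np

from ampseq import LabeledTemplate, auc_band, cross_validate, rank_features
from ampseq.templates import FEATURE_NAMES

rng = np.random.default_rng(17)
i_p = FEATURE_NAMES.index("pvalue")
i_t = FEATURE_NAMES.index("ltemp")
X = rng.normal(size=(300, len(FEATURE_NAMES)))
data = [LabeledTemplate(x, int(x[i_p] < 0 and x[i_t] > -1)) for x in X]
print(f"{sum(d.label for d in data)} efficient / "
      f"{sum(1 - d.label for d in data)} non-efficient primers")

report = cross_validate(data, repeats=20, seed=17)
for model in report.auc:
    print(f"{model:20s} AUC {report.auc[model]:.3f} ({auc_band(report.auc[model])}), "
          f"accuracy {report.accuracy[model]:.3f}")
print(f"best model by AUC: {report.best_model}")

ranked = rank_features(report.fitted["random_forest"])
print("top forest features:", ", ".join(ranked[:4]))
print(
    "AUC is the probability that a random efficient primer outscores a "
    "random non-efficient one; >=0.90 is very good. The planted rule uses "
    "pvalue and ltemp, which should rank at the top."
)
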