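"""Train the cubic SVM on the default annotated fixture and report CV metrics.

Reproduces the classifier benchmark: 13 synthetic images, ~1710 annotated
crystals with class imbalance toward COM and COD, stratified fivefold
cross-validation of a degree-3 polynomial-kernel SVM on standardized
features.
"""

import crystalscreen as cs

table = cs.make_training_fixture(n_crystals=1710, seed=1)
model, report = cs.train(table, seed=1)

print(f"training crystals  : {len(table)}")
print(f"CV overall accuracy: {report.overall_accuracy * 100:.1f}%")
print("per-class F1       :", {cs.CLASS_NAMES[k]: round(v, 3)
                               for k, v in report.f1.items()})
print("confusion matrix (rows = true):")
print(report.confusion_matrix)
# Accuracy lands around 99% on the emulated task; the real assay reported
# 90.9% on its hand-annotated training data, which this benchmark treats
# as the floor.
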