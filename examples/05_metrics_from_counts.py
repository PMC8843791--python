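"""Evaluate the five confusion-matrix metrics from raw TP/FP/TN/FN counts.

With TP=195, FP=5, TN=190, FN=10 (400 test samples): precision 97.50,
recall 95.12, specificity 97.44, F1 96.30 — F1 is the harmonic mean
2PR/(P+R) of precision and recall.
"""

from fusionclass import ConfusionMatrix, classification_metrics, roc_curve

cm = ConfusionMatrix(tp=195, fp=5, tn=190, fn=10)
report = classification_metrics(cm)
for name, value in report.rounded().items():
    print(f"{name:12s} {value:6.2f} %")

# AUC of a tiny score ranking: 3 of the 4 positive-negative pairs are
# concordant -> AUC = 0.75
roc = roc_curve([0.9, 0.8, 0.4, 0.2],
                ["malignant", "benign", "malignant", "benign"], "malignant")
print(f"{'auc':12s} {roc.auc:6.2f}")
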