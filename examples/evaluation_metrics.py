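"""Confusion matrix, per-class F1, macro-F1 and the binary collapse.

Scores a hand-made prediction vector on a 24-image test set (the size of
the benchmark holdout) and shows how the four-class problem collapses to
control-vs-pathogenic.
"""

import numpy as np

from col6fl import binarize, evaluate_predictions

# 24 "true" labels (1=control, 2=glycine sub., 3=pseudoexon, 4=exon skip)
y_true = np.array([1] * 7 + [2] * 6 + [3] * 6 + [4] * 5)
# a classifier that confuses two pseudoexon images with control
y_pred = y_true.copy()
y_pred[[14, 15]] = 1

rep = evaluate_predictions(y_true, y_pred, k=4)
print("confusion (rows = true, cols = predicted):")
print(rep.confusion.counts)
for lbl, p, r, f in zip(rep.confusion.class_order, rep.precision, rep.recall, rep.f1):
    print(f"  {lbl:22s} precision {p:.3f} recall {r:.3f} F1 {f:.3f}")
print(f"macro-F1 {rep.macro_f1:.3f} (mean of per-class F1), "
      f"accuracy {rep.accuracy:.3f} ({np.trace(rep.confusion.counts)}/{rep.n})")

binary = evaluate_predictions(
    binarize(y_true) + 1, binarize(y_pred) + 1, k=2,
    class_order=["control", "pathogenic"],
)
print(f"binary collapse (control vs pathogenic): macro-F1 {binary.macro_f1:.3f}, "
      f"accuracy {binary.accuracy:.3f}")
print("Binary accuracy always dominates four-class accuracy: every"
      " correctly-classified image stays correct after the collapse.")
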