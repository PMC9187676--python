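"""Diagnostic-accuracy statistics on a published confusion table.

Reproduces the worked example of a node-level classifier evaluated on 1156
lymph-node images (295 positive, 861 negative) at its operating threshold,
then shows the ROC/DeLong machinery and count-consistency CV on small data.
"""

import numpy as np

import slidestream as ss

cm = ss.ConfusionMatrix(tp=263, fp=12, fn=32, tn=849)
metrics = ss.confusion_metrics(cm)
lo, hi = ss.clopper_pearson(cm.tp, cm.tp + cm.fn, 0.95)
print("confusion counts: TP=263 FP=12 FN=32 TN=849 (n=1156)")
print(f"sensitivity {metrics['sensitivity']:.4f}  (95% exact CI {lo:.4f}-{hi:.4f})")
print(f"specificity {metrics['specificity']:.4f}")
print(f"MCC         {metrics['mcc']:.4f}")

rng = np.random.default_rng(0)
labels = rng.integers(0, 2, 80)
good = np.clip(labels * 0.6 + rng.normal(0, 0.25, 80), 0, 1)
weak = np.clip(labels * 0.25 + rng.normal(0, 0.3, 80), 0, 1)
ta = ss.ScoreTable(np.arange(80), np.zeros(80), good, labels)
tb = ss.ScoreTable(np.arange(80), np.zeros(80), weak, labels)
out = ss.delong(ta, tb)
print(f"\npaired ROC comparison on 80 simulated nodes:")
print(f"AUC(a) {out['auc']:.3f} vs AUC(b) {out['auc_b']:.3f}, "
      f"delta {out['delta_auc']:.3f}, two-sided p = {out['p_value']:.2g}")

print(f"\nLN-count consistency: counts (11, 12, 14) across raters "
      f"-> CV = {ss.count_cv([11, 12, 14]):.4f}")
# Small CV means raters agree on how many nodes a slide contains; the paired
# DeLong p-value tests whether two correlated AUCs differ.
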