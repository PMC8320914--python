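"""Full density-classification pipeline on synthetic textures.

Generates a small labelled dataset (fatty / glandular / dense presets),
extracts multi-orientation elliptical LBP features, and cross-validates a
naive Bayes classifier with correlation-based feature selection inside
each training fold.  Prints per-run accuracy, the pooled confusion matrix
and the prevalence-weighted area under the ROC curve (Az).
"""

import numpy as np

from mammotex import DescriptorConfig, run_cv
from mammotex.features import extract_feature_matrix
from mammotex.synthetic import generate_arrays

ids, labels, images = generate_arrays(n_per_class=15, size=96, seed=1)
print(f"dataset: {len(images)} images, classes F/G/D x 15")

X = extract_feature_matrix(images, DescriptorConfig("elbp"))
print(f"features: {X.shape[0]} x {X.shape[1]} (8 orientations x 256 bins)")

res = run_cv(X, np.array(labels), classifier="bayes", runs=2, folds=5, seed=1)
print(f"per-run accuracy (%): {[round(a, 1) for a in res.per_run_accuracy]}")
print(f"mean +/- std: {res.mean:.1f} +/- {res.std:.2f}")
print(f"weighted Az: {res.az:.3f}")
print("pooled confusion (rows = truth F/G/D):")
print(res.confusion)

# Accuracy near 100% reflects the strongly separated class presets; the
# confusion matrix shows where residual mixing (if any) occurs.
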