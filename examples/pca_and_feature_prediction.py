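"""Cross-region signature analysis: PCA and molecular-feature prediction.

Builds a region-by-dimension signature matrix, z-scores each dimension
(units differ across dimensions), extracts the principal axes of regional
variation, and predicts a synthetic molecular feature from the R1 and
MTsat derivatives under leave-one-out cross-validation.
"""

import numpy as np
import pandas as pd

from mdmtv import predict_feature_loo, signature_pca

rng = np.random.default_rng(8)
regions = ["thalamus", "pallidum", "putamen", "hippocampus",
           "frontal-wm", "parietal-wm", "occipital-ctx"]
matrix = pd.DataFrame(
    {
        "dR1/dMTV": rng.normal(2.2, 0.6, size=7),
        "dMTsat/dMTV": rng.normal(12.0, 3.0, size=7),
        "dMD/dMTV": rng.normal(-1.5e-3, 4e-4, size=7),
        "dR2/dMTV": rng.normal(30.0, 6.0, size=7),
    },
    index=regions,
)

pca = signature_pca(matrix)
print("variance explained per PC:",
      np.round(pca.explained_variance_ratio, 3))
print("PC1 loadings:")
print(pca.loadings["PC1"].round(3).to_string())

# a feature that truly is a weighted sum of the R1/MTsat derivatives,
# plus measurement noise
feature = (
    0.5 * matrix["dR1/dMTV"] + 0.4 * matrix["dMTsat/dMTV"]
    + rng.normal(0, 0.1, size=7)
)
result = predict_feature_loo(matrix[["dR1/dMTV", "dMTsat/dMTV"]], feature)
print()
print("leave-one-out predictions vs observed:")
print(pd.DataFrame({"predicted": result.predicted.round(3),
                    "observed": result.observed.round(3)}).to_string())
print(f"LOO R2 (adjusted): {result.r2_loo_adj:.3f}")

print()
print("PC1 captures the dominant axis of signature variation across")
print("regions; the LOO R2 measures genuinely out-of-sample prediction of")
print("the molecular feature from the two MDM dimensions.")
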