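"""Serially fuse the two selected subsets and reduce with PCA.

Serial fusion concatenates the DE-selected block (width Y) and the
PSO-selected block (width Z) over the same samples into a K = Y + Z matrix;
PCA then keeps only the top-k variance directions.
"""

import numpy as np

from brainfuse import (DEConfig, FeatureMatrix, FitnessSpec, PSOConfig,
                       SyntheticFeatureSpec, de_run, make_feature_fixture,
                       pca_fit, pca_transform, pso_run, serial_fuse)

fm, _ = make_feature_fixture(SyntheticFeatureSpec(seed=0))
fitness = FitnessSpec(seed=0)
de = de_run(fm, DEConfig(seed=0), fitness)
pso = pso_run(fm, PSOConfig(seed=0), fitness)


def subset(mask):
    return FeatureMatrix(X=fm.X[:, mask.selected], y=fm.y,
                         feature_ids=[fm.feature_ids[j] for j in mask.indices])


fused = serial_fuse(subset(de.mask), subset(pso.mask), "de", "pso")
print(f"fused width K = {fused.d} = Y({de.mask.count}) + Z({pso.mask.count})")

k = 10
model = pca_fit(fused.X, k)
Z = pca_transform(model, fused.X)
share = model.explained_variance.sum() / np.var(fused.X, axis=0, ddof=1).sum()
print(f"PCA keeps k={k} of {fused.d} directions, "
      f"explaining {100 * share:.1f}% of the variance")
print("per-component variance:",
      np.round(model.explained_variance, 2).tolist())
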