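"""The whole pipeline in one call: select, fuse, reduce, evaluate four arms.

The report compares classifiers on the original features, the DE subset, the
PSO subset, and the fused-then-PCA representation — the comparison at the
heart of the method: keep the accuracy, shrink the representation.
"""

import warnings

from sklearn.exceptions import ConvergenceWarning

from brainfuse import parse_config, run_pipeline

warnings.filterwarnings("ignore", category=ConvergenceWarning)

cfg = parse_config(None, {
    "seed": 0,
    "input.synthetic": {},          # default study conditions (200 x 60)
    "pca.k": 20,
    "evaluate.classifiers": ["linear_discriminant", "cubic_svm",
                             "bagged_trees", "medium_nn"],
})
report = run_pipeline(cfg)

sel = report["selection"]
print(f"DE selected {sel['de']['count']} cols (err {sel['de']['best_fitness']:.3f}); "
      f"PSO selected {sel['pso']['count']} cols (err {sel['pso']['best_fitness']:.3f}); "
      f"fused width {report['fused_width']}")
for arm, payload in report["arms"].items():
    best = max(payload["classifiers"].values(),
               key=lambda c: c["metrics"]["accuracy"])
    width = payload["pca_k"] or payload["n_features"]
    print(f"{arm:>9} arm ({width:>3} cols): best {best['name']:>20} "
          f"{best['metrics']['accuracy']:6.2f}% accuracy")
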