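"""Sensitivity-anchored LOSO evaluation of the feature-set configurations.

Generates a cohort with a genuine activity effect (standardized shift 1.0 on
relative amplitude and mean heart rate), builds the patient feature matrix,
and evaluates clinical-only vs combined configurations with a gradient-
boosted-trees model.  The decision threshold is calibrated to sensitivity
0.9 on the pooled out-of-fold probabilities.
"""

from actipredict import CohortConfig, EvalConfig, ModelSpec, generate_cohort, \
    labels_vector
from actipredict.models import REDUCED_GRIDS
from actipredict.pipeline import build_feature_matrix, evaluate_feature_set

cohort = generate_cohort(CohortConfig(n_patients=48, effect_size=1.0, seed=0))
X, types, sets = build_feature_matrix(cohort)
y = labels_vector(cohort)
print(f"feature matrix: {X.shape[0]} patients x {X.shape[1]} columns")

for feature_set in ("clinical_only", "combined"):
    spec = ModelSpec("gradient_boosted_trees",
                     {k: list(v) for k, v in
                      REDUCED_GRIDS["gradient_boosted_trees"].items()}, seed=0)
    res = evaluate_feature_set(X, y, types, sets, spec,
                               EvalConfig(feature_set=feature_set))
    m = res.metrics
    print(f"{feature_set:14s} AUROC={m['auroc']:.3f} sens={m['sensitivity']:.2f} "
          f"spec={m['specificity']:.2f} precision={m['precision']:.2f} "
          f"F1={m['f1']:.2f}")
# With the injected activity signal, the combined configuration should beat
# clinical-only on AUROC; sensitivity sits at/above the 0.9 anchor by
# construction of the threshold.
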