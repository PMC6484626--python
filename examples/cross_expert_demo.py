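"""Cross-expert demo: single-expert vs majority-vote training labels.

Trains the classifier once per label source (each annotator, then the
majority vote) under patient-level cross-validation and scores
quadratic-weighted kappa against every annotator on held-out patients.
Diagonal cells (train on A, evaluate on A) tend to beat the rest of their
row, and the majority-trained row tends to beat every single-trained row
overall — single-expert evaluation overstates agreement.
"""

import histocv as h

config = h.SimConfig(n_patients=100, patches_per_core=20, seed=11)
cohort = h.simulate_cohort(config)
annotations = h.simulate_annotations(cohort, h.default_profiles(), seed=11)

result = h.cross_expert_experiment(
    cohort, annotations, h.FoldSpec(10, "patient", seed=11), classifier_kind="knn"
)

print("quadratic-weighted kappa, trainer (rows) x evaluator (columns):")
print(result.agreement.round(2))
print()
overall = result.agreement["overall"]
best_single = overall.drop("majority").idxmax()
print(f"best single-expert overall kappa: {overall[best_single]:.2f} ({best_single})")
print(f"majority-vote-trained overall:    {overall['majority']:.2f} "
      f"({h.interpret_kappa(overall['majority'])} agreement)")
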