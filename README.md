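# histocv

Evaluation protocols for histopathology patch classifiers — and a
simulation framework that shows what goes wrong when they are skipped.

## The problem

Digitized tissue slides are far too large to classify whole, so they are
tiled into small patches, and models (for prostate cancer: 4-class Gleason
grading — benign, grade 3, grade 4, grade 5) are trained and evaluated per
patch. Two evaluation shortcuts are common in this literature and both
flatter the model:

1. **Patch-level cross-validation.** When patches are shuffled into folds
   individually, patches from the same patient land on both sides of the
   train/test split. Patches of one patient share appearance (staining,
   sectioning, tissue morphology), so the model is partly recognising the
   patient, not the disease. The only split that measures the clinically
   relevant question — *can a new patient be graded?* — groups all of a
   patient's patches in one fold.
2. **Single-expert labels.** Gleason grading has high interobserver
   variability. A model trained and scored against one pathologist learns
   that pathologist's style and overstates its agreement with experts in
   general, relative to training on a multi-expert majority vote.

`histocv` implements the full evaluation protocol around these two issues
as a tested library: grouped k-fold partitioning at patient, core, or
patch level with leakage audits; a simulated multi-annotator panel with
per-class confusion matrices, partial core coverage, and majority-vote
consensus; per-fold accuracy/sensitivity/specificity for cancer detection
(benign vs cancer) and grading (G3 vs G4–5); quadratic-weighted Cohen κ;
and the paired McNemar test for comparing CV schemes on the same patches.
Because real tissue-microarray data of this kind are not public, the
package ships a hierarchical cohort simulator (patients → cores → patches,
with additive patient/core/patch random effects) whose pinned default
scenario reproduces both phenomena end to end.

## Core statistics

For two CV schemes evaluated on the same patches, with `b` patches only
scheme 1 gets right and `c` patches only scheme 2 gets right, the McNemar
statistic tests H₀: E[b] = E[c] — exactly via Binomial(b+c, ½) for small
b+c, else via the continuity-corrected χ² = (|b−c|−1)²/(b+c) on 1 df.

Agreement between ordinal 4-class label vectors is quadratic-weighted κ:

    κ = 1 − (Σᵢⱼ wᵢⱼ Oᵢⱼ) / (Σᵢⱼ wᵢⱼ Eᵢⱼ),   wᵢⱼ = (i−j)² / (C−1)²

with O the observed joint proportion table over the severity-ordered
classes, and E the product of its marginals.

## Worked example

`examples/leakage_demo.py` evaluates one 1-nearest-neighbour classifier on
one simulated cohort under two fold groupings:

```
patient-level CV detection accuracy:  82.2%
patch-level CV detection accuracy:    93.4%
inflation from leakage:               11.2 percentage points
McNemar p (same patches, paired):    <.001
```

Same classifier, same patches — the 11-point gap is pure evaluation bias
from same-patient patches in the training folds. The other examples cover
the annotator panel (`annotator_panel.py`), the cross-expert experiment
(`cross_expert_demo.py`, where the majority-vote-trained model's overall κ
beats every single-expert-trained model), the toy image mode
(`toy_histology_images.py`), and the full report-writing pipeline
(`full_study.py`).

A minimal API session:

```python
import histocv as h

cohort = h.simulate_cohort(h.SimConfig(n_patients=80, seed=1))
ann = h.simulate_annotations(cohort, h.default_profiles(), seed=1)
truth = h.consensus_labels(h.majority_vote(ann))
comp = h.compare_cv_methods(
    cohort, truth,
    [h.FoldSpec(20, "patient", 1), h.FoldSpec(20, "patch", 1)],
)
print(comp.metrics)                       # mean (SD) rates per scheme/task
print(comp.pvalues["detection"])          # pairwise McNemar p matrix
```

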