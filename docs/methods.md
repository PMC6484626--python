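# Methods

## The simulation model

A cohort is a three-level hierarchy: `n_patients` patients each contribute
1 or 2 tissue cores (50/50 mix by default, giving a cores/patients ratio
of ≈1.5, close to the 333/231 ≈ 1.44 typical of tissue-microarray
studies), and each core is tiled into `patches_per_core` patches. Each
patch carries a true class drawn i.i.d. from the prevalence vector
(default 0.40 benign, 0.30 G3, 0.20 G4, 0.10 G5) and a `d`-dimensional
feature vector

    x = μ(class) + u(patient) + v(core) + ε(patch)

with μ(c) = δ·e_{c mod d} (scaled unit basis vectors, pairwise distance
δ√2), u ~ N(0, σ_p² I), v ~ N(0, σ_c² I), ε ~ N(0, σ_e² I). The additive
patient/core shifts are the minimal mechanism that produces cross-
validation leakage: a same-patient patch is systematically closer in
feature space than any other-patient patch, so a memorising classifier
(k-NN with k = 1) benefits whenever fold grouping lets same-patient
patches into its training set.

Randomness is organised as child streams keyed by a stable SHA-256 hash
of entity ids under one root seed. Patient- and core-level draws each own
a stream; a core's stream draws all of its patches in one vectorised
call. Consequences: identical configs give byte-identical cohorts, and
enlarging `n_patients` leaves existing patients' data unchanged.

### The pinned default scenario

All demonstrations and regression values are anchored to one named
configuration (`histocv.DEFAULT_SCENARIO`): 200 patients, 1–2 cores each,
50 patches/core (≈15 000 patches), prevalence (0.4, 0.3, 0.2, 0.1), d = 8,
δ = 1, σ_p = 0.4, σ_c = 0.25, σ_e = 0.2, classifier k-NN with k = 1, seed
20190442. The noise scales were calibrated once so that the 1-NN
classifier sits in the regime reported for real CNN-based Gleason
studies, which is the regime the protocol arguments are about: strong but
imperfect within-patient signal (patch-level 20-fold CV detection
accuracy in the low 90s %), a genuine but attenuated cross-patient signal
(patient-level CV around 80–84 %), a double-digit leakage gap with
decisive McNemar evidence, and cross-expert κ in the moderate band
(0.40–0.55). Larger patient effects (σ_p ≳ δ) drive cross-patient
performance to chance, at which point κ comparisons degenerate into
marginal-distribution artifacts and no ordering among label sources is
meaningful; the calibrated scenario deliberately avoids that regime.
These values are frozen; tests assert orderings and invariants, not the
calibrated magnitudes.

### Image mode

An optional toy renderer draws 64×64 RGB patches: an eosin-pink textured
background with white elliptical "gland lumens" whose count/size decrease
monotonically with grade (benign 8 large → G5 none), plus patient- and
core-level shifts added to the channel means — a cartoon of staining
batch effects. Seven descriptors (3 channel means, 3 channel variances,
edge density above a gradient threshold of 0.08 on the [0,1] scale) feed
the identical downstream pipeline as directly simulated features. The
renderer makes no claim to visual realism; it exists so the feature
pipeline can be exercised end to end from rasters.

## The annotator panel

Each annotator is a 4×4 row-stochastic confusion matrix (row = true
class) plus a core coverage fraction; coverage is realised per core
(exactly `round(coverage × n_cores)` cores via a seeded permutation), and
labels are drawn independently per patch from the confusion row. The
default panel of six mirrors a realistic grading board — four full-
coverage annotators and two partial (191/333 and 92/333 of cores) — and
gives each member a *distinct systematic style* (strict under-grader,
strong over-grader, accurate/neutral, G3-compressor, mild over-grader,
noisy under-grader). Distinct styles matter: the only annotator-specific
signal a classifier can learn is the systematic part of the confusion, so
a panel with near-duplicate profiles makes the cross-expert diagonal-
dominance comparison degenerate by construction. Benign↔cancer confusion
is kept rare and the G3/G4 boundary carries most of the disagreement,
matching the clinical folklore of Gleason grading.

Majority vote takes the modal label among non-missing votes; ties break
toward the more severe class by default (clinically conservative;
least-severe and seeded-random rules are selectable), and patches with
fewer than `min_votes` votes are flagged undefined rather than erroring.
Undefined-consensus patches are excluded from *all* experiments so every
scheme is compared on one patch universe (McNemar pairing requires it).

## Partitioning and leakage audit

Folds are built by shuffle-and-deal at the declared grouping level: a
seeded permutation of the units, the first `n mod k` folds taking
⌈n/k⌉ units and the rest ⌊n/k⌋. No class stratification (plain random
shuffling is what the protocol under study uses). Hence 231 patients into
20 folds gives sizes {11, 12}, and 333 cores gives exactly 13 folds of 17
and 7 of 16. The audit reports, per fold, how many patients (or cores)
have patches both in that fold and elsewhere — identically zero when the
grouping level is at least as coarse as the audit level, and essentially
always nonzero for patch-level folds.

## Metrics

Detection binarises benign vs {G3, G4, G5}; grading excludes benign-truth
patches and scores G3 vs {G4, G5} with high-grade as positive. A benign
*prediction* on a cancer patch counts as low-grade/negative under grading
— the only binary-consistent mapping, but a package convention worth
flagging, since which class a study calls "positive" is often left
unstated. Rates are percentages per fold; summaries are mean (SD) across
folds with the n−1 denominator; a fold whose rate has a zero denominator
(e.g. no positives in a small test fold) is skipped for that rate only.

Quadratic-weighted κ uses w_ij = (i−j)²/(C−1)² over the severity order
benign < G3 < G4 < G5, κ = 1 − Σw·O / Σw·E with E the marginal product
table. Pairs with a missing side are dropped. Two identical constant
vectors give κ = 1 by convention; zero expected disagreement with nonzero
observed raises. Interpretation bands follow the conventional scale
(≤0 accidental, 0.1–0.2 slight, 0.21–0.4 fair, 0.41–0.6 moderate,
0.61–0.8 substantial, 0.81–1.0 near-perfect); the conventional scale
leaves (0, 0.1) unnamed, reported here as "below slight".

The McNemar test uses the exact doubled-tail binomial p below b+c = 25
and the continuity-corrected χ² above (both variants callable
explicitly); b = c = 0 returns p = 1 by convention. Comparisons are
flagged at the 0.001 significance threshold. Note one boundary fact: near
b ≈ c the exact two-sided p clamps at 1 while the corrected χ² p tops out
near 0.95, so the two variants only agree tightly away from the null's
centre.

## The experiments

`run_cv_experiment` fits the classifier k times (once per fold) and pools
held-out predictions, so each included patch is predicted exactly once;
`compare_cv_methods` runs several schemes on identical patches and emits
the per-scheme metric table plus all pairwise discordance tables and
p-values. `cross_expert_experiment` (patient-level folds only, by design)
trains once per label source — each annotator, restricted to patches that
annotator graded, then the majority vote — and scores κ against every
annotator on the held-out patches that evaluator graded; the partial-
coverage annotators therefore contribute fewer pairs, as in the unequal
real-world annotation counts. The "overall" column pools (prediction,
label) pairs across evaluators before computing κ (a per-evaluator mean
is available via `overall_rule="mean"`; outputs label which rule was
used).

Classifiers: nearest-centroid (per-class means, severity tie-break) and
k-NN (stable-sort neighbour ties → smallest training index; label-vote
ties → more severe class). Both are deliberately simple reference models
behind a two-method `fit`/`predict` contract that external models can
implement. Euclidean metric, no internal feature scaling — the simulator
controls scales, and hidden normalisation would couple the modules.

## What the synthetic cohort does and does not show

The simulator reproduces the *mechanisms* — hierarchical batch effects,
annotator confusion with partial coverage — not histology. Patch classes
are i.i.d. within a core (no spatial label correlation), annotator errors
are independent across patches given the true class (no within-core error
correlation, no drift), and patient effects are additive mean shifts.
Passing tests therefore demonstrate that the evaluation machinery detects
leakage and single-expert bias when they are present by construction, and
stays quiet in the matched null scenario (σ_p = σ_c = 0, where the
patch-vs-patient gap collapses below 2 pp); they say nothing about effect
sizes in any real dataset. Absolute accuracies from real CNN studies are
not reproduction targets.

## Numerical and design choices

- SD across folds uses ddof = 1; per-fold NaN rates are skipped, not
  zero-filled.
- Exact McNemar two-sided p = min(1, 2·min(tails)); the doubling
  convention is stated in output rather than silently assumed.
- Fold indices are 0-based; dealing order after the shuffle is
  deterministic, so published outputs are reproducible byte for byte.
- Degenerate folds (a test fold missing a class some metric needs) are
  handled by the metrics layer, not prevented by the partitioner; a
  *training* split missing a class raises, naming the fold.
- Problem sizes in the test suite and acceptance script (200 patients /
  ≈15 000 patches for the pinned scenario; 300-patch tables × 1000
  replicates for the type-I sweep) were chosen as the smallest sizes at
  which the binomial/χ² oracles and orderings are stable, keeping a full
  run in the tens of seconds on one CPU.
- The library is import-first: the `examples/` scripts are the intended
  entry points, and there is no console command.

## Known limitations

- No within-core spatial structure, so nothing here evaluates
  segmentation-style leakage (adjacent-patch overlap).
- Annotator model has no error correlation, which likely *understates*
  the benefit of majority voting on real panels.
- The cross-expert diagonal-dominance property is a "most rows, most
  seeds" phenomenon, as in real data — at some seeds a well-calibrated
  neutral annotator's row is dominated by its agreement with the panel at
  large.
- κ confidence intervals, ROC/AUC, nested or repeated CV are out of
  scope.
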