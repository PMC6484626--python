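"""End-to-end evaluation experiments.

Drives the full protocol on one cohort: run k-fold cross-validation under
several grouping levels on the same patches, tabulate per-fold
accuracy/sensitivity/specificity for the detection and grading tasks,
compare every pair of schemes with the McNemar test, and run the
cross-expert study (train on each annotator's labels, and on the majority
vote, then score quadratic-weighted kappa against every annotator on
held-out patients).

Every experiment predicts each included patch exactly once — the union of
held-out predictions over folds — which is what makes the per-patch
McNemar pairing valid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifier as clf
from .annotation import AnnotationMatrix, majority_vote
from .classes import MISSING_CODE
from .cohort import Cohort
from .metrics import (DETECTION, GRADING, MetricsSummary, TaskSpec, binarize,
                      fold_metrics, weighted_kappa)
from .partition import FoldAssignment, FoldSpec, make_folds
from .stats_compare import DiscordanceTable, McNemarResult, build_discordance, mcnemar_test

logger = logging.getLogger(__name__)

MAJORITY = "majority"


def scheme_name(spec: FoldSpec) -> str:
    """Conventional scheme label, e.g. '20-fold leave-patients-out'."""
    noun = {"patient": "patients", "core": "cores", "patch": "patches"}[spec.level]
    return f"{spec.k}-fold leave-{noun}-out"


# ---------------------------------------------------------------------------
# single CV experiment

def run_cv_experiment(
    cohort: Cohort,
    truth: pd.Series,
    spec: FoldSpec,
    classifier_kind: str = "knn",
    k_neighbors: int = 1,
    experiment_id: str | None = None,
) -> pd.DataFrame:
    """k-fold cross-validation of one classifier under one grouping level.

    ``truth`` is a Series of class labels indexed by patch id; patches
    without a defined truth label are excluded up front (count logged).
    Returns a prediction table with columns ``patch_id, predicted, fold,
    experiment`` covering every included patch exactly once.
    """
    experiment_id = experiment_id or scheme_name(spec)
    assignment = make_folds(cohort, spec)

    patches = cohort.patches
    in_truth = patches["patch_id"].isin(truth.index).to_numpy()
    n_excluded = int((~in_truth).sum())
    if n_excluded:
        logger.info("%s: excluding %d patches without truth labels",
                    experiment_id, n_excluded)
    included = patches.loc[in_truth]
    X = included[cohort.feature_columns].to_numpy(dtype=float)
    patch_ids = included["patch_id"].to_numpy()
    y = truth.loc[patch_ids].to_numpy()
    folds = assignment.patch_to_fold.loc[patch_ids].to_numpy()
    all_classes = set(y)

    predicted = np.empty(len(patch_ids), dtype=object)
    for f in range(spec.k):
        test_mask = folds == f
        train_mask = ~test_mask
        if not test_mask.any():
            continue
        missing = all_classes - set(y[train_mask])
        if missing:
            raise ValueError(
                f"training split for fold {f} is missing class(es) {sorted(missing)}"
            )
        model = clf.fit(classifier_kind, X[train_mask], y[train_mask],
                        k_neighbors=k_neighbors)
        predicted[test_mask] = clf.predict(model, X[test_mask])

    return pd.DataFrame({
        "patch_id": patch_ids,
        "predicted": predicted.astype(str),
        "fold": folds,
        "experiment": experiment_id,
    })


# ---------------------------------------------------------------------------
# scheme comparison (Table 2/3 analogues)

@dataclass
class CVComparison:
    """All outputs of a multi-scheme comparison on one cohort and truth."""

    schemes: list[str]
    predictions: dict  # scheme name -> prediction table
    summaries: dict  # (scheme, task name) -> MetricsSummary
    metrics: pd.DataFrame  # long table: scheme, task, mean/sd per rate
    discordance: dict  # task name -> {(scheme_i, scheme_j) -> DiscordanceTable}
    pvalues: dict  # task name -> DataFrame (lower-triangular p matrix)
    mcnemar: dict = field(default_factory=dict)  # task -> {(si, sj) -> McNemarResult}


def compare_cv_methods(
    cohort: Cohort,
    truth: pd.Series,
    specs: list[FoldSpec],
    classifier_kind: str = "knn",
    k_neighbors: int = 1,
    tasks: tuple[TaskSpec, ...] = (DETECTION, GRADING),
) -> CVComparison:
    """Evaluate every fold spec on the same cohort/truth and compare them.

    Produces per-scheme per-task mean (SD) rates and, for each task, the
    pairwise McNemar p-value matrix over schemes.
    """
    if len(specs) < 2:
        raise ValueError("at least two fold specs are required for a comparison")
    names = [scheme_name(s) for s in specs]
    if len(set(names)) != len(names):
        names = [f"{n} #{i}" for i, n in enumerate(names)]

    predictions = {}
    for name, spec in zip(names, specs):
        predictions[name] = run_cv_experiment(
            cohort, truth, spec, classifier_kind, k_neighbors, experiment_id=name
        )

    rows = []
    summaries = {}
    for name in names:
        table = predictions[name]
        y_true = truth.loc[table["patch_id"]].to_numpy()
        y_pred = table["predicted"].to_numpy()
        for task in tasks:
            t, p, mask = binarize(y_true, y_pred, task)
            summary = fold_metrics(t[mask], p[mask], table["fold"].to_numpy()[mask])
            summaries[(name, task.name)] = summary
            rows.append({
                "scheme": name, "task": task.name,
                "accuracy_mean": summary.mean["accuracy"],
                "accuracy_sd": summary.sd["accuracy"],
                "sensitivity_mean": summary.mean["sensitivity"],
                "sensitivity_sd": summary.sd["sensitivity"],
                "specificity_mean": summary.mean["specificity"],
                "specificity_sd": summary.sd["specificity"],
            })
    metrics = pd.DataFrame(rows)

    discordance: dict = {}
    pvalues: dict = {}
    mcnemar_results: dict = {}
    for task in tasks:
        discordance[task.name] = {}
        mcnemar_results[task.name] = {}
        pmat = pd.DataFrame(np.nan, index=names, columns=names)
        for i, ni in enumerate(names):
            for nj in names[:i]:
                pi = predictions[ni].set_index("patch_id")["predicted"]
                pj = predictions[nj].set_index("patch_id")["predicted"]
                table = build_discordance(pi, pj, truth, task, method1=ni, method2=nj)
                result = mcnemar_test(table)
                discordance[task.name][(ni, nj)] = table
                mcnemar_results[task.name][(ni, nj)] = result
                pmat.loc[ni, nj] = result.p
        pvalues[task.name] = pmat

    return CVComparison(
        schemes=names, predictions=predictions, summaries=summaries,
        metrics=metrics, discordance=discordance, pvalues=pvalues,
        mcnemar=mcnemar_results,
    )


# ---------------------------------------------------------------------------
# cross-expert experiment (Table 4 analogue)

@dataclass
class CrossExpertResult:
    """Trainer x evaluator agreement, plus the per-trainer prediction tables."""

    agreement: pd.DataFrame  # rows: annotators + "majority"; cols: annotators + "overall"
    predictions: dict  # trainer id -> prediction table
    overall_rule: str  # "pooled" or "mean"


def cross_expert_experiment(
    cohort: Cohort,
    annotations: AnnotationMatrix,
    fold_spec: FoldSpec,
    classifier_kind: str = "knn",
    k_neighbors: int = 1,
    overall_rule: str = "pooled",
    tie_rule: str = "most_severe",
) -> CrossExpertResult:
    """Train on each single annotator's labels and on the majority vote,
    then score quadratic-weighted kappa against every annotator.

    Grouping must be patient-level: the point of the experiment is
    generalisation to held-out patients.  Training on annotator A uses only
    held-in patches A actually labelled; evaluation against annotator B
    uses only held-out patches B labelled.  The "overall" column pools the
    (prediction, label) pairs across evaluators before computing kappa
    (``overall_rule="pooled"``), or averages per-evaluator kappas
    (``"mean"``).
    """
    if fold_spec.level != "patient":
        raise ValueError("cross-expert experiments require patient-level folds")
    if overall_rule not in ("pooled", "mean"):
        raise ValueError(f"unknown overall_rule: {overall_rule!r}")

    consensus = majority_vote(annotations, tie_rule=tie_rule)
    universe = consensus.index[~consensus["undefined"]]
    n_dropped = int(consensus["undefined"].sum())
    if n_dropped:
        logger.info("cross-expert: excluding %d patches with undefined consensus",
                    n_dropped)

    assignment = make_folds(cohort, fold_spec)
    patches = cohort.patches.set_index("patch_id").loc[universe]
    X = patches[cohort.feature_columns].to_numpy(dtype=float)
    folds = assignment.patch_to_fold.loc[universe].to_numpy()
    codes = annotations.codes.loc[universe]

    from .classes import CLASSES, CLASS_INDEX

    # label codes over the universe, MISSING_CODE where the trainer has none
    trainer_codes: dict[str, np.ndarray] = {}
    for a in annotations.annotator_ids:
        col = codes[a].to_numpy()
        if (col == MISSING_CODE).all():
            warnings.warn(f"annotator {a!r} labelled no patches; row dropped")
            continue
        trainer_codes[a] = col
    trainer_codes[MAJORITY] = np.array(
        [CLASS_INDEX[c] for c in consensus.loc[universe, "consensus"]]
    )

    evaluators = list(annotations.annotator_ids)
    agreement = pd.DataFrame(
        np.nan, index=list(trainer_codes), columns=evaluators + ["overall"]
    )
    predictions: dict[str, pd.DataFrame] = {}

    for trainer, label_codes in trainer_codes.items():
        have = label_codes != MISSING_CODE
        trainer_classes = {CLASSES[c] for c in label_codes[have]}

        predicted = np.empty(len(universe), dtype=object)
        for f in range(fold_spec.k):
            test_mask = folds == f
            train_mask = (~test_mask) & have
            y_train = np.array([CLASSES[c] for c in label_codes[train_mask]])
            missing = trainer_classes - set(y_train)
            if missing:
                raise ValueError(
                    f"trainer {trainer!r}: training split for fold {f} is missing "
                    f"class(es) {sorted(missing)}"
                )
            model = clf.fit(classifier_kind, X[train_mask], y_train,
                            k_neighbors=k_neighbors)
            predicted[test_mask] = clf.predict(model, X[test_mask])

        pred_codes = np.array([CLASS_INDEX[p] for p in predicted])
        predictions[trainer] = pd.DataFrame({
            "patch_id": universe.to_numpy(), "predicted": predicted.astype(str),
            "fold": folds, "experiment": f"cross-expert:{trainer}",
        })

        pooled_pred: list[np.ndarray] = []
        pooled_lab: list[np.ndarray] = []
        per_eval = []
        for ev in evaluators:
            ev_codes = codes[ev].to_numpy()
            m = ev_codes != MISSING_CODE
            if not m.any():
                continue
            result = weighted_kappa(pred_codes[m], ev_codes[m])
            agreement.loc[trainer, ev] = result.kappa
            per_eval.append(result.kappa)
            pooled_pred.append(pred_codes[m])
            pooled_lab.append(ev_codes[m])
        if overall_rule == "pooled":
            overall = weighted_kappa(
                np.concatenate(pooled_pred), np.concatenate(pooled_lab)
            ).kappa
        else:
            overall = float(np.mean(per_eval))
        agreement.loc[trainer, "overall"] = overall

    return CrossExpertResult(agreement=agreement, predictions=predictions,
                             overall_rule=overall_rule)
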