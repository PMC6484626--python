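"""Binary task metrics and quadratic-weighted Cohen kappa.

Two clinical binarisations of the 4-class Gleason labels are evaluated:

* detection — benign vs cancer; positive = {G3, G4, G5}, all patches kept.
* grading — low-grade vs high-grade among cancer; positive = {G4, G5},
  negative = {G3}; patches whose TRUE label is benign are excluded, and a
  benign PREDICTION on a cancer patch counts as low-grade (negative) —
  the only binary-consistent reading, and it is flagged here and in the
  docs because the convention is a package choice, not a universal one.

Per-fold accuracy/sensitivity/specificity are reported in percent as
mean (SD) across folds, SD with the n-1 denominator; a fold whose rate has
a zero denominator contributes nothing to that rate's mean/SD (skip-NaN
policy).

The quadratic-weighted kappa uses weights w_ij = (i - j)^2 / (C - 1)^2 on
the severity-ordered classes and the standard chance correction

    kappa = 1 - (sum_ij w_ij O_ij) / (sum_ij w_ij E_ij)

with O the observed joint proportion table and E the product of its
marginals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classes import CLASSES, N_CLASSES, CLASS_INDEX, MISSING_CODE


# ---------------------------------------------------------------------------
# task binarisation

@dataclass(frozen=True)
class TaskSpec:
    """A binary task over the 4-class label set."""

    name: str
    positive: frozenset
    negative: frozenset

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise ValueError("positive and negative class sets overlap")
        unknown = (self.positive | self.negative) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in task: {unknown}")

    @property
    def excluded(self) -> frozenset:
        return frozenset(CLASSES) - self.positive - self.negative


DETECTION = TaskSpec("detection", frozenset({"G3", "G4", "G5"}), frozenset({"benign"}))
GRADING = TaskSpec("grading", frozenset({"G4", "G5"}), frozenset({"G3"}))

TASKS = {"detection": DETECTION, "grading": GRADING}


def binarize(labels, predictions, task: TaskSpec):
    """Map aligned 4-class labels/predictions to binary vectors.

    Returns ``(truth_bin, pred_bin, mask)`` where ``mask`` marks included
    patches (true label not in the task's excluded set).  On included
    patches, a prediction from the excluded set counts as negative.
    """
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must be aligned")
    for arr in (labels, predictions):
        bad = ~np.isin(arr, CLASSES)
        if bad.any():
            raise ValueError(f"unknown class value: {arr[bad][0]!r}")
    pos = np.array([c in task.positive for c in CLASSES])
    excl = np.array([c in task.excluded for c in CLASSES])
    lab_idx = np.array([CLASS_INDEX[c] for c in labels])
    pred_idx = np.array([CLASS_INDEX[c] for c in predictions])
    mask = ~excl[lab_idx]
    return pos[lab_idx], pos[pred_idx], mask


# ---------------------------------------------------------------------------
# per-fold metrics

@dataclass
class MetricsSummary:
    """Per-fold rates (percent) plus mean (SD) across folds and pooled counts."""

    per_fold: pd.DataFrame  # index fold; columns n, tp, fp, tn, fn, accuracy, sensitivity, specificity
    mean: dict
    sd: dict
    pooled: dict  # tp, fp, tn, fn over all folds

    def __str__(self) -> str:
        parts = [
            f"{name} {self.mean[name]:.1f} ({self.sd[name]:.1f})%"
            for name in ("accuracy", "sensitivity", "specificity")
        ]
        return ", ".join(parts)


def _rate(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(len(num), np.nan)
    ok = den > 0
    out[ok] = 100.0 * num[ok] / den[ok]
    return out


def fold_metrics(truth_bin, pred_bin, patch_fold) -> MetricsSummary:
    """Accuracy/sensitivity/specificity per fold, in percent.

    ``patch_fold`` assigns each included patch to exactly one fold.
    """
    truth_bin = np.asarray(truth_bin, dtype=bool)
    pred_bin = np.asarray(pred_bin, dtype=bool)
    patch_fold = np.asarray(patch_fold)
    if len(truth_bin) == 0:
        raise ValueError("empty input")
    if not (len(truth_bin) == len(pred_bin) == len(patch_fold)):
        raise ValueError("inputs must be aligned")

    folds = np.unique(patch_fold)
    rows = []
    for f in folds:
        m = patch_fold == f
        t, p = truth_bin[m], pred_bin[m]
        tp = int((t & p).sum())
        tn = int((~t & ~p).sum())
        fp = int((~t & p).sum())
        fn = int((t & ~p).sum())
        rows.append({"fold": f, "n": int(m.sum()), "tp": tp, "fp": fp, "tn": tn, "fn": fn})
    per_fold = pd.DataFrame(rows).set_index("fold")
    per_fold["accuracy"] = _rate(
        (per_fold.tp + per_fold.tn).to_numpy(), per_fold.n.to_numpy()
    )
    per_fold["sensitivity"] = _rate(
        per_fold.tp.to_numpy(), (per_fold.tp + per_fold.fn).to_numpy()
    )
    per_fold["specificity"] = _rate(
        per_fold.tn.to_numpy(), (per_fold.tn + per_fold.fp).to_numpy()
    )

    mean, sd = {}, {}
    for name in ("accuracy", "sensitivity", "specificity"):
        vals = per_fold[name].to_numpy()
        vals = vals[~np.isnan(vals)]  # folds lacking the denominator are skipped
        mean[name] = float(np.mean(vals)) if len(vals) else float("nan")
        sd[name] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    pooled = {c: int(per_fold[c].sum()) for c in ("tp", "fp", "tn", "fn")}
    return MetricsSummary(per_fold=per_fold, mean=mean, sd=sd, pooled=pooled)


# ---------------------------------------------------------------------------
# quadratic-weighted kappa

@dataclass
class KappaResult:
    kappa: float
    observed_disagreement: float
    expected_disagreement: float
    n: int
    n_classes: int

    @property
    def weights(self) -> np.ndarray:
        C = self.n_classes
        i, j = np.meshgrid(np.arange(C), np.arange(C), indexing="ij")
        return (i - j) ** 2 / (C - 1) ** 2


def _as_codes(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        return labels.astype(np.int64)
    return np.array([MISSING_CODE if l == "MISSING" else CLASS_INDEX[l] for l in labels])


def weighted_kappa(labels_a, labels_b, n_classes: int = N_CLASSES) -> KappaResult:
    """Quadratic-weighted Cohen kappa between two label vectors.

    Accepts class-name strings or integer severity codes; pairs where
    either side is MISSING are dropped.  Identical non-degenerate vectors
    give kappa = 1; independent marginals give kappa = 0.
    """
    a = _as_codes(labels_a)
    b = _as_codes(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    keep = (a != MISSING_CODE) & (b != MISSING_CODE)
    a, b = a[keep], b[keep]
    n = len(a)
    if n == 0:
        raise ValueError("no usable label pairs")
    if (a >= n_classes).any() or (b >= n_classes).any():
        raise ValueError("label code out of range for the class set")

    observed = np.zeros((n_classes, n_classes))
    np.add.at(observed, (a, b), 1.0)
    observed /= n
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    C = n_classes
    i, j = np.meshgrid(np.arange(C), np.arange(C), indexing="ij")
    w = (i - j) ** 2 / (C - 1) ** 2
    obs_dis = float((w * observed).sum())
    exp_dis = float((w * expected).sum())
    if exp_dis == 0.0:
        if obs_dis > 0.0:
            raise ValueError("degenerate marginals: zero expected disagreement "
                             "with nonzero observed disagreement")
        kappa = 1.0  # both raters constant and identical
    else:
        kappa = 1.0 - obs_dis / exp_dis
    return KappaResult(
        kappa=float(kappa),
        observed_disagreement=obs_dis,
        expected_disagreement=exp_dis,
        n=n,
        n_classes=n_classes,
    )


#: agreement bands for interpreting kappa; values in (0, 0.1) fall in a gap
#: of the conventional scale and are labelled "below slight"
KAPPA_BANDS = (
    (-1.0, 0.0, "accidental"),
    (0.0, 0.1, "below slight"),
    (0.1, 0.2, "slight"),
    (0.2, 0.4, "fair"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "substantial"),
    (0.8, 1.0, "near-perfect"),
)


def interpret_kappa(kappa: float) -> str:
    """Conventional agreement band for a kappa value in [-1, 1]."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError("kappa must be in [-1, 1]")
    if kappa <= 0.0:
        return "accidental"
    for lo, hi, name in KAPPA_BANDS[1:]:
        if lo < kappa <= hi:
            return name
    raise AssertionError("unreachable")
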