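"""Grouped k-fold partitioning at patient, core or patch level.

``make_folds`` shuffles the units of the chosen grouping level with a
seeded permutation and deals them into k folds of near-equal size
(``floor(n/k)`` or ``ceil(n/k)`` units each); every patch inherits the fold
of its unit, so all patches of a patient (or core) share a fold when the
grouping level says they must.  ``audit_leakage`` counts, per fold, the
units of a coarser level whose patches leak across fold boundaries —
patient-level folds audit clean by construction, patch-level folds do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import child_rng

LEVELS = ("patient", "core", "patch")


@dataclass(frozen=True)
class FoldSpec:
    """k folds at one grouping level, under one seed."""

    k: int
    level: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level: {self.level!r} (expected one of {LEVELS})")


@dataclass
class FoldAssignment:
    """A realised partition: unit -> fold plus the induced patch -> fold."""

    level: str
    k: int
    seed: int
    unit_to_fold: pd.Series  # index = unit id, value = fold in [0, k)
    patch_to_fold: pd.Series  # index = patch_id, value = fold in [0, k)

    def fold_sizes(self, of: str = "unit") -> np.ndarray:
        """Number of units (or patches) per fold, indexed by fold."""
        mapping = self.unit_to_fold if of == "unit" else self.patch_to_fold
        return np.bincount(mapping.to_numpy(), minlength=self.k)

    def test_patches(self, fold: int) -> np.ndarray:
        """Patch ids held out in ``fold``."""
        return self.patch_to_fold.index.to_numpy()[self.patch_to_fold.to_numpy() == fold]

    def to_csv(self, unit_path: str | Path, patch_path: str | Path | None = None) -> None:
        units = self.unit_to_fold.rename("fold").rename_axis("unit_id").reset_index()
        units.insert(1, "level", self.level)
        units.to_csv(unit_path, index=False)
        if patch_path is not None:
            (self.patch_to_fold.rename("fold").rename_axis("patch_id")
             .reset_index().to_csv(patch_path, index=False))


def make_folds(cohort, spec: FoldSpec) -> FoldAssignment:
    """Shuffle-and-deal the units of ``spec.level`` into ``spec.k`` folds.

    After a seeded shuffle the first ``n mod k`` folds receive
    ``ceil(n/k)`` units and the rest ``floor(n/k)``; e.g. 231 patients into
    20 folds gives sizes in {11, 12}, and 333 cores into 20 folds gives 13
    folds of 17 and 7 of 16.
    """
    units = cohort.units(spec.level)
    n = len(units)
    if spec.k > n:
        raise ValueError(f"k={spec.k} exceeds the number of {spec.level} units ({n})")

    rng = child_rng(spec.seed, "folds", spec.level, str(spec.k))
    shuffled = units[rng.permutation(n)]
    base, extra = divmod(n, spec.k)
    folds = np.empty(n, dtype=np.int64)
    start = 0
    for f in range(spec.k):
        size = base + (1 if f < extra else 0)
        folds[start:start + size] = f
        start += size
    unit_to_fold = pd.Series(folds, index=pd.Index(shuffled, name="unit_id")).sort_index()

    patches = cohort.patches
    if spec.level == "patch":
        patch_folds = unit_to_fold.loc[patches["patch_id"]].to_numpy()
    else:
        key = "patient_id" if spec.level == "patient" else "core_id"
        patch_folds = unit_to_fold.loc[patches[key]].to_numpy()
    patch_to_fold = pd.Series(
        patch_folds, index=pd.Index(patches["patch_id"], name="patch_id")
    )
    return FoldAssignment(
        level=spec.level, k=spec.k, seed=spec.seed,
        unit_to_fold=unit_to_fold, patch_to_fold=patch_to_fold,
    )


def audit_leakage(assignment: FoldAssignment, cohort, audit_level: str) -> pd.DataFrame:
    """Count per fold the audit-level units whose patches span other folds.

    Returns a DataFrame indexed by fold with columns ``leaked_units`` and
    ``total_units`` (units with any patch in that fold).  All zeros iff the
    assignment is clean at ``audit_level``.
    """
    if audit_level not in ("patient", "core"):
        raise ValueError("audit_level must be 'patient' or 'core'")
    key = "patient_id" if audit_level == "patient" else "core_id"

    patches = cohort.patches
    folds = assignment.patch_to_fold.loc[patches["patch_id"]].to_numpy()
    frame = pd.DataFrame({"unit": patches[key].to_numpy(), "fold": folds})
    spans = frame.groupby("unit")["fold"].nunique()
    leaky_units = set(spans.index[spans > 1])

    per_fold = frame.drop_duplicates().groupby("fold")["unit"].agg(
        total_units="nunique",
        leaked_units=lambda u: sum(x in leaky_units for x in u),
    )
    return per_fold.reindex(range(assignment.k), fill_value=0)
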