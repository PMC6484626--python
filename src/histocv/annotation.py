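"""Simulated expert annotators, majority-vote consensus, and agreement.

Each annotator is described by a 4x4 row-stochastic confusion matrix (row =
true class, column = assigned class) and a core coverage fraction.  Coverage
is decided per core — an annotator either grades a whole core or skips it —
mirroring how pathologists contour entire tissue cores.  Labels are drawn
independently per patch from the confusion row of the patch's true class.

The default panel of six profiles emulates a realistic grading board:
benign vs cancer is rarely confused, most disagreement sits on the G3/G4
boundary, one annotator systematically under-grades and one over-grades,
and two partial-coverage annotators grade only 191/333 and 92/333 of the
cores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .classes import CLASSES, N_CLASSES, MISSING, MISSING_CODE, CLASS_INDEX


@dataclass(frozen=True)
class AnnotatorProfile:
    """One simulated annotator: id, confusion matrix, core coverage."""

    id: str
    confusion: np.ndarray
    coverage: float = 1.0

    def __post_init__(self) -> None:
        conf = np.asarray(self.confusion, dtype=float)
        if conf.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"confusion must be {N_CLASSES}x{N_CLASSES}")
        if (conf < 0).any():
            raise ValueError("confusion entries must be >= 0")
        if not np.allclose(conf.sum(axis=1), 1.0, rtol=0, atol=1e-12):
            raise ValueError("confusion rows must sum to 1 within 1e-12")
        object.__setattr__(self, "confusion", conf)
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")


def default_profiles() -> list[AnnotatorProfile]:
    """The six-annotator default panel (4 full coverage, 2 partial)."""
    rows = {
        # strict under-grader: shifts everything one grade down
        "path1": [[0.97, 0.03, 0.00, 0.00],
                  [0.25, 0.70, 0.05, 0.00],
                  [0.02, 0.38, 0.55, 0.05],
                  [0.00, 0.05, 0.40, 0.55]],
        # strong over-grader: shifts everything one grade up
        "path2": [[0.80, 0.17, 0.03, 0.00],
                  [0.02, 0.63, 0.30, 0.05],
                  [0.00, 0.05, 0.65, 0.30],
                  [0.00, 0.01, 0.09, 0.90]],
        # accurate and neutral
        "path3": [[0.97, 0.03, 0.00, 0.00],
                  [0.04, 0.88, 0.08, 0.00],
                  [0.00, 0.08, 0.84, 0.08],
                  [0.00, 0.01, 0.11, 0.88]],
        # compresses toward G3: liberal on benign, conservative on G4
        "path4": [[0.82, 0.18, 0.00, 0.00],
                  [0.02, 0.90, 0.08, 0.00],
                  [0.00, 0.30, 0.62, 0.08],
                  [0.00, 0.05, 0.25, 0.70]],
        # mild over-grader, moderate noise, partial coverage
        "path5": [[0.90, 0.08, 0.02, 0.00],
                  [0.03, 0.72, 0.22, 0.03],
                  [0.00, 0.10, 0.70, 0.20],
                  [0.00, 0.02, 0.16, 0.82]],
        # noisy under-grader, smallest coverage
        "path6": [[0.93, 0.06, 0.01, 0.00],
                  [0.15, 0.70, 0.13, 0.02],
                  [0.03, 0.30, 0.57, 0.10],
                  [0.00, 0.08, 0.32, 0.60]],
    }
    coverage = {"path1": 1.0, "path2": 1.0, "path3": 1.0, "path4": 1.0,
                "path5": 191 / 333, "path6": 92 / 333}
    return [
        AnnotatorProfile(id=name, confusion=np.array(rows[name]), coverage=coverage[name])
        for name in rows
    ]


@dataclass
class AnnotationMatrix:
    """Patch x annotator label table.

    ``codes`` holds integer class codes with :data:`MISSING_CODE` marking
    cores the annotator did not grade; rows are indexed by patch id.
    """

    codes: pd.DataFrame  # int codes, index = patch_id, columns = annotator ids

    @property
    def annotator_ids(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def patch_ids(self) -> np.ndarray:
        return self.codes.index.to_numpy()

    def labels_of(self, annotator_id: str) -> pd.Series:
        """String labels of one annotator (MISSING where not graded)."""
        codes = self.codes[annotator_id]
        out = codes.map(lambda c: MISSING if c == MISSING_CODE else CLASSES[c])
        out.name = annotator_id
        return out

    def to_csv(self, path) -> None:
        """patch_id + one column per annotator; MISSING as empty field."""
        out = pd.DataFrame(index=self.codes.index)
        for a in self.codes.columns:
            col = self.codes[a].map(lambda c: "" if c == MISSING_CODE else CLASSES[c])
            out[a] = col
        out.index.name = "patch_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "AnnotationMatrix":
        raw = pd.read_csv(path, index_col="patch_id", dtype=str, keep_default_na=False)
        codes = pd.DataFrame(index=raw.index)
        for a in raw.columns:
            codes[a] = raw[a].map(lambda s: MISSING_CODE if s == "" else CLASS_INDEX[s])
        return cls(codes=codes.astype(np.int64))


def simulate_annotations(
    cohort, profiles: list[AnnotatorProfile], seed: int
) -> AnnotationMatrix:
    """Draw each annotator's labels over their covered cores.

    For each annotator, exactly ``round(coverage * n_cores)`` cores are
    selected (a seeded permutation's prefix); every patch of a covered core
    receives a label drawn from the confusion row of its true class, all
    other patches are MISSING.
    """
    if len(profiles) == 0:
        raise ValueError("at least one annotator profile is required")
    ids = [p.id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("annotator ids must be unique")

    core_ids = cohort.cores["core_id"].to_numpy()
    patch_cores = cohort.patches["core_id"].to_numpy()
    true_codes = np.array([CLASS_INDEX[c] for c in cohort.patches["true_class"]])
    n_patches = len(true_codes)

    codes = pd.DataFrame(index=pd.Index(cohort.patches["patch_id"], name="patch_id"))
    for prof in profiles:
        rng = child_rng(seed, "annotator", prof.id)
        n_covered = int(round(prof.coverage * len(core_ids)))
        covered = set(rng.permutation(core_ids)[:n_covered])
        col = np.full(n_patches, MISSING_CODE, dtype=np.int64)
        mask = np.fromiter((c in covered for c in patch_cores), dtype=bool, count=n_patches)
        if mask.any():
            # vectorised draw from the confusion row of each true class
            cum = np.cumsum(prof.confusion, axis=1)
            u = rng.random(int(mask.sum()))
            col[mask] = (u[:, None] > cum[true_codes[mask]]).sum(axis=1)
        codes[prof.id] = col
    return AnnotationMatrix(codes=codes)


def majority_vote(
    annotations: AnnotationMatrix,
    tie_rule: str = "most_severe",
    min_votes: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-patch modal label among non-missing votes.

    Returns a DataFrame indexed by patch_id with columns ``consensus``
    (string label, or MISSING when undefined), ``n_votes`` and
    ``undefined`` (True when fewer than ``min_votes`` votes were cast).

    Ties are resolved by ``tie_rule``: ``"most_severe"`` (default — the
    clinically conservative choice), ``"least_severe"``, or ``"random"``
    (requires ``seed``).
    """
    if tie_rule not in ("most_severe", "least_severe", "random"):
        raise ValueError(f"unknown tie_rule: {tie_rule!r}")
    if tie_rule == "random" and seed is None:
        raise ValueError("tie_rule='random' requires a seed")

    codes = annotations.codes.to_numpy()
    n_patches = codes.shape[0]
    # counts[i, c] = votes for class c on patch i
    counts = np.zeros((n_patches, N_CLASSES), dtype=np.int64)
    for c in range(N_CLASSES):
        counts[:, c] = (codes == c).sum(axis=1)
    n_votes = counts.sum(axis=1)

    consensus = np.full(n_patches, MISSING_CODE, dtype=np.int64)
    rng = child_rng(seed, "tie-break") if tie_rule == "random" else None
    defined = n_votes >= max(min_votes, 1)
    top = counts.max(axis=1)
    for i in np.nonzero(defined)[0]:
        tied = np.nonzero(counts[i] == top[i])[0]
        if len(tied) == 1:
            consensus[i] = tied[0]
        elif tie_rule == "most_severe":
            consensus[i] = tied[-1]
        elif tie_rule == "least_severe":
            consensus[i] = tied[0]
        else:
            consensus[i] = rng.choice(tied)

    out = pd.DataFrame(index=annotations.codes.index.copy())
    out["consensus"] = [MISSING if c == MISSING_CODE else CLASSES[c] for c in consensus]
    out["n_votes"] = n_votes
    out["undefined"] = ~defined
    return out


def consensus_labels(consensus: pd.DataFrame) -> pd.Series:
    """Defined consensus labels only (undefined patches dropped)."""
    defined = consensus.loc[~consensus["undefined"]]
    return defined["consensus"].rename("consensus")


def pairwise_annotator_agreement(annotations: AnnotationMatrix) -> pd.DataFrame:
    """Symmetric annotator x annotator quadratic-weighted-kappa table.

    Each pair is compared on the patches both labelled; a pair with no
    common patches gets NaN.  Diagonal cells are 1 by definition.
    """
    from .metrics import weighted_kappa

    ids = annotations.annotator_ids
    table = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ca = annotations.codes[a].to_numpy()
            cb = annotations.codes[b].to_numpy()
            both = (ca != MISSING_CODE) & (cb != MISSING_CODE)
            if not both.any():
                kappa = np.nan
            else:
                kappa = weighted_kappa(ca[both], cb[both]).kappa
            table.loc[a, b] = table.loc[b, a] = kappa
    return table
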