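"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import histocv as h

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# independent oracles

def kappa_oracle(a, b, n_classes: int = 4) -> float:
    """Brute-force quadratic-weighted kappa: build the contingency table by
    explicit loops and evaluate the defining formula by direct summation."""
    a = list(a)
    b = list(b)
    n = len(a)
    table = [[0.0] * n_classes for _ in range(n_classes)]
    for x, y in zip(a, b):
        table[x][y] += 1.0 / n
    row = [sum(table[i][j] for j in range(n_classes)) for i in range(n_classes)]
    col = [sum(table[i][j] for i in range(n_classes)) for j in range(n_classes)]
    num = den = 0.0
    for i in range(n_classes):
        for j in range(n_classes):
            w = (i - j) ** 2 / (n_classes - 1) ** 2
            num += w * table[i][j]
            den += w * row[i] * col[j]
    return 1.0 - num / den


def nearest_neighbor_oracle(train_X, train_y, query, k=1):
    """Exhaustive k-NN: all pairwise distances, stable sort, majority vote
    with most-severe tie-break."""
    dists = [float(np.linalg.norm(np.asarray(q) - np.asarray(t)))
             for t in train_X for q in [query]]
    order = sorted(range(len(train_X)), key=lambda i: (dists[i], i))[:k]
    votes = {}
    for i in order:
        votes[train_y[i]] = votes.get(train_y[i], 0) + 1
    top = max(votes.values())
    tied = [c for c, v in votes.items() if v == top]
    return max(tied, key=lambda c: h.CLASS_INDEX[c])


def build_cohort(n_patients: int, cores_each, patches_per_core: int = 1) -> h.Cohort:
    """Hand-assembled cohort with prescribed core counts and dummy features."""
    patients, cores, patches = [], [], []
    for p in range(n_patients):
        pid = f"P{p:04d}"
        patients.append({"patient_id": pid})
        n_cores = cores_each[p] if hasattr(cores_each, "__getitem__") else cores_each
        for c in range(n_cores):
            cid = f"{pid}-C{c}"
            cores.append({"core_id": cid, "patient_id": pid})
            for t in range(patches_per_core):
                patches.append({
                    "patch_id": f"{cid}-T{t:03d}", "core_id": cid,
                    "patient_id": pid, "true_class": "benign", "f0": 0.0,
                })
    return h.Cohort(
        patients=pd.DataFrame(patients),
        cores=pd.DataFrame(cores),
        patches=pd.DataFrame(patches),
    )


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def small_cohort() -> h.Cohort:
    """40 patients, mixed 1-2 cores, 10 patches/core, default noise."""
    return h.simulate_cohort(h.SimConfig(n_patients=40, patches_per_core=10, seed=5))


@pytest.fixture(scope="session")
def pinned_study() -> h.StudyResult:
    """The full pinned-scenario study; shared by the acceptance checks."""
    return h.run_full_study()
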