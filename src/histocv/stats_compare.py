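"""Paired comparison of two cross-validation schemes via the McNemar test.

Both schemes predict every patch exactly once, so their per-patch
correctness indicators form matched pairs.  The 2x2 discordance table
counts patches both got right (n11), only method 1 got right (b = n10),
only method 2 got right (c = n01), and both got wrong (n00).  The McNemar
null — equal marginal correctness — depends only on the discordant counts
b and c.

Two variants are provided.  The exact test treats b as
Binomial(b + c, 1/2) and doubles the smaller tail (clamped at 1); the
asymptotic test uses the continuity-corrected chi-square statistic
(|b - c| - 1)^2 / (b + c) on 1 df.  ``variant="auto"`` uses the exact test
when b + c < 25 and the chi-square otherwise.  P values are two-sided and
flagged against the significance threshold 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .metrics import TaskSpec, binarize

#: switch point between exact and asymptotic variants under variant="auto"
EXACT_SWITCH = 25

#: significance threshold for the comparison tables
ALPHA = 0.001


@dataclass(frozen=True)
class DiscordanceTable:
    """2x2 paired-correctness table for two methods on one patch set."""

    n11: int  # both correct
    n10: int  # method 1 only (b)
    n01: int  # method 2 only (c)
    n00: int  # both incorrect
    method1: str = "method1"
    method2: str = "method2"
    task: str = ""

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def b(self) -> int:
        return self.n10

    @property
    def c(self) -> int:
        return self.n01

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def swapped(self) -> "DiscordanceTable":
        return DiscordanceTable(self.n11, self.n01, self.n10, self.n00,
                                self.method2, self.method1, self.task)


@dataclass(frozen=True)
class McNemarResult:
    p: float
    variant: str  # "exact" or "chi2"
    statistic: float | None  # chi-square statistic, None for exact
    b: int
    c: int

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def build_discordance(preds_m1, preds_m2, truth, task: TaskSpec,
                      method1: str = "method1", method2: str = "method2") -> DiscordanceTable:
    """Tally the 2x2 paired-correctness table after task binarisation.

    ``preds_m1``/``preds_m2``/``truth`` are Series of class labels indexed
    by patch id; the two prediction tables must cover exactly the same
    patches, once each.
    """
    import pandas as pd

    preds_m1 = pd.Series(preds_m1)
    preds_m2 = pd.Series(preds_m2)
    truth = pd.Series(truth)
    for name, s in (("method 1", preds_m1), ("method 2", preds_m2), ("truth", truth)):
        if s.index.duplicated().any():
            raise ValueError(f"duplicate patch id in {name} table")
    if set(preds_m1.index) != set(preds_m2.index):
        raise ValueError("prediction tables cover different patch sets")
    if not set(preds_m1.index).issubset(set(truth.index)):
        raise ValueError("prediction for a patch with no truth label")

    idx = preds_m1.index
    truth = truth.loc[idx]
    preds_m2 = preds_m2.loc[idx]

    t1, p1, mask = binarize(truth.to_numpy(), preds_m1.to_numpy(), task)
    t2, p2, _ = binarize(truth.to_numpy(), preds_m2.to_numpy(), task)
    ok1 = (t1 == p1)[mask]
    ok2 = (t2 == p2)[mask]
    return DiscordanceTable(
        n11=int((ok1 & ok2).sum()),
        n10=int((ok1 & ~ok2).sum()),
        n01=int((~ok1 & ok2).sum()),
        n00=int((~ok1 & ~ok2).sum()),
        method1=method1, method2=method2, task=task.name,
    )


def mcnemar_test(table: DiscordanceTable, variant: str = "auto") -> McNemarResult:
    """Two-sided McNemar test on the discordant counts of ``table``.

    ``variant`` is ``"auto"`` (exact below b + c = 25, else chi-square),
    ``"exact"`` or ``"chi2"``.  With b = c = 0 the test is undefined and
    p = 1 is returned by convention.
    """
    if variant not in ("auto", "exact", "chi2"):
        raise ValueError(f"unknown variant: {variant!r}")
    b, c = table.b, table.c
    n_disc = b + c
    if n_disc == 0:
        return McNemarResult(p=1.0, variant="exact", statistic=None, b=b, c=c)
    if variant == "auto":
        variant = "exact" if n_disc < EXACT_SWITCH else "chi2"

    if variant == "exact":
        lo = stats.binom.cdf(min(b, c), n_disc, 0.5)
        hi = stats.binom.sf(max(b, c) - 1, n_disc, 0.5)
        p = min(1.0, 2.0 * min(lo, hi))
        return McNemarResult(p=float(p), variant="exact", statistic=None, b=b, c=c)

    statistic = (abs(b - c) - 1) ** 2 / n_disc
    p = stats.chi2.sf(statistic, df=1)
    return McNemarResult(p=float(p), variant="chi2", statistic=float(statistic), b=b, c=c)
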