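"""Class-by-class tests and the combined global + classwise procedure.

Each ontology class is tested with a two-sided Fisher exact test on the
2x2 table [annotated in the class vs not] x [list A vs list B], followed by
Holm's step-down adjustment to control the family-wise error rate.  A
Pearson chi-square test of homogeneity on the 2xs table of per-class counts
is also provided — not as a recommended method, but as the classical
comparator whose type-I error is uncontrolled when classes overlap (a gene
annotated in several classes is counted in each, so the table columns are
not independent multinomial cells).

The combined decision procedure gates the classwise analysis behind the
global test:

1. run the global comparison; stop ("no_difference") if non-significant;
2. otherwise run Fisher + Holm; if any class survives, report them
   ("classes_identified");
3. otherwise either flag the class with the smallest unadjusted p-value
   ("suggested_class", default) or recommend re-testing at a less
   specific set of classes ("recommend_higher_level").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, hypergeom

from .comparison import ProfileComparison, ProfileComparisonResults
from .profiles import AnnotationIndex, ExpandedProfile, membership_matrix

__all__ = [
    "class_counts",
    "fisher_two_sided",
    "class_fisher_tests",
    "holm_adjust",
    "chisq_homogeneity",
    "CombinedDecision",
    "combined_procedure",
]


def class_counts(e: ExpandedProfile) -> np.ndarray:
    """Integer per-class counts (every gene annotated in the class)."""
    M, cnt = membership_matrix(e)
    return np.rint(M @ cnt).astype(int)


def holm_adjust(p: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the original order.

    Sort ascending, multiply the i-th smallest by (s - i), enforce the
    running maximum, cap at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    s = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(s)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (s - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def fisher_two_sided(a: int, b: int, n: int, m: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [n-a, m-b]].

    Defined by summation: conditional on the margins, add up the
    hypergeometric probabilities of every table at most as probable as the
    observed one (with the customary 1 + 1e-7 relative slack against
    floating-point ties).  Vectorised over the whole support, so it is much
    faster than a generic implementation for repeated small tables.
    """
    r = a + b
    lo, hi = max(0, r - m), min(r, n)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n + m, r, n)
    p_obs = pmf[a - lo]
    return float(min(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum(), 1.0))


def _fisher_raw(cA: np.ndarray, cB: np.ndarray, n: int, m: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Raw two-sided Fisher p-values per class; degenerate-margin flags."""
    s = cA.size
    raw = np.ones(s)
    degenerate = np.zeros(s, dtype=bool)
    for i in range(s):
        a, b = int(cA[i]), int(cB[i])
        if a + b == 0 or (n - a) + (m - b) == 0:
            degenerate[i] = True
            continue
        raw[i] = fisher_two_sided(a, b, n, m)
    return raw, degenerate


def class_fisher_tests(listA: Iterable[str], listB: Iterable[str],
                       ann: AnnotationIndex, alpha: float = 0.05,
                       *, model: ProfileComparison | None = None) -> pd.DataFrame:
    """Two-sided Fisher exact test per class, with Holm adjustment.

    Genes shared by both lists are counted in both columns of each 2x2
    table — the conventional practice for overlapping lists, even though
    the tables are then not strictly independent samples.  Classes with an
    empty margin (no gene of either list annotated) get p = 1 and are
    flagged in the ``degenerate`` column.

    Returns a DataFrame with one row per class:
    class_id, count_A, n, count_B, m, raw_p, holm_p, significant, degenerate.
    """
    if model is None:
        model = ProfileComparison(listA, listB, ann)
    n, m = model.n, model.m
    cA = class_counts(model.expanded_P)
    cB = class_counts(model.expanded_Q)
    raw, degenerate = _fisher_raw(cA, cB, n, m)
    holm = holm_adjust(raw)
    return pd.DataFrame({
        "class_id": model.class_order,
        "count_A": cA, "n": n,
        "count_B": cB, "m": m,
        "raw_p": raw,
        "holm_p": holm,
        "significant": holm < alpha,
        "degenerate": degenerate,
    })


def chisq_homogeneity(countsP: Sequence[int], countsQ: Sequence[int]
                      ) -> tuple[float, int, float]:
    """Pearson chi-square homogeneity test on a 2xs table of class counts.

    Classes with zero total count are dropped (with a warning) before
    computing the statistic; df = s' - 1 on the remaining columns.
    Included as the classical — and, for overlapping classes, invalid —
    global comparator.
    """
    cP = np.asarray(countsP, dtype=float)
    cQ = np.asarray(countsQ, dtype=float)
    if cP.shape != cQ.shape:
        raise ValueError("count vectors must have equal length")
    keep = (cP + cQ) > 0
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} zero-count class(es) "
                      "from the chi-square table", stacklevel=2)
    cP, cQ = cP[keep], cQ[keep]
    if cP.size < 2:
        raise ValueError("need at least two non-empty classes")
    nP, nQ = cP.sum(), cQ.sum()
    total = cP + cQ
    expP = nP * total / (nP + nQ)
    expQ = nQ * total / (nP + nQ)
    stat = float(np.sum((cP - expP) ** 2 / expP) + np.sum((cQ - expQ) ** 2 / expQ))
    df = cP.size - 1
    return stat, df, float(chi2.sf(stat, df))


@dataclass
class CombinedDecision:
    """Outcome of the gated global + class-by-class procedure."""

    global_result: ProfileComparisonResults
    classwise: pd.DataFrame | None
    outcome: str                       # no_difference | classes_identified |
    #                                    suggested_class | recommend_higher_level
    suggested_class: str | None = None

    def significant_classes(self) -> list[str]:
        if self.classwise is None:
            return []
        return list(self.classwise.loc[self.classwise["significant"], "class_id"])


def combined_procedure(listA: Iterable[str], listB: Iterable[str],
                       ann: AnnotationIndex, alpha: float = 0.05,
                       step3: str = "suggest") -> CombinedDecision:
    """Run the decision algorithm; classwise tests only after global rejection.

    ``step3`` chooses the fallback when the global test rejects but no
    class survives Holm: "suggest" (default) flags the smallest-raw-p
    class, "uplevel" recommends re-testing at a less specific level.
    """
    if step3 not in ("suggest", "uplevel"):
        raise ValueError("step3 must be 'suggest' or 'uplevel'")
    model = ProfileComparison(listA, listB, ann)
    result = model.fit(alpha=alpha)
    if not result.reject:
        return CombinedDecision(result, None, "no_difference")
    table = class_fisher_tests(listA, listB, ann, alpha=alpha, model=model)
    if table["significant"].any():
        return CombinedDecision(result, table, "classes_identified")
    if step3 == "uplevel":
        return CombinedDecision(result, table, "recommend_higher_level")
    best = table.loc[table["raw_p"].idxmin(), "class_id"]
    return CombinedDecision(result, table, "suggested_class", suggested_class=best)
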