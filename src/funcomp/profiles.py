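"""Expanded and contracted functional profiles of annotated gene lists.

A *functional profile* of a gene list over ``s`` ontology classes is the
vector of per-class annotation frequencies.  Because a single gene may be
annotated in several classes, the per-class frequencies are marginals of an
underlying *expanded* distribution over the non-empty subsets of classes:
each gene falls in exactly one subset cell (the set of classes it is
annotated in), so the expanded cell counts are multinomial.  Everything in
this package — covariances, the global test, the simulation engine — is
derived from the expanded representation; the contracted (per-class) vector
is what the distance between two lists is computed on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AnnotationIndex",
    "ExpandedProfile",
    "ContractedProfile",
    "PairDecomposition",
    "build_expanded",
    "contract",
    "pair_marginal",
    "squared_distance",
    "decompose_pair",
    "read_gene_list",
    "write_expanded_tsv",
    "read_expanded_tsv",
]


class AnnotationIndex:
    """Mapping gene identifier -> set of class identifiers, over a fixed,
    ordered universe of ``s`` target classes.

    Parameters
    ----------
    mapping
        Gene identifier to an iterable of class identifiers.  Classes not in
        ``class_order`` are dropped (the index is restricted to the target
        classes).
    class_order
        Ordered list of the ``s`` target class identifiers; fixes the
        coordinate system of every profile vector built from this index.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]], class_order: Sequence[str]):
        class_order = list(class_order)
        if len(class_order) == 0:
            raise ValueError("class_order must contain at least one class")
        if len(set(class_order)) != len(class_order):
            raise ValueError("class_order contains duplicate class identifiers")
        self.class_order: list[str] = class_order
        self._index = {c: i for i, c in enumerate(class_order)}
        universe = set(class_order)
        self.mapping: dict[str, frozenset[str]] = {
            g: frozenset(set(terms) & universe) for g, terms in mapping.items()
        }

    @property
    def s(self) -> int:
        return len(self.class_order)

    def classes_of(self, gene: str) -> frozenset[str]:
        return self.mapping.get(gene, frozenset())

    def subset_key(self, classes: Iterable[str]) -> tuple[int, ...]:
        """Canonical (sorted index tuple) key for a class subset."""
        return tuple(sorted(self._index[c] for c in classes))

    def __len__(self) -> int:
        return len(self.mapping)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AnnotationIndex({len(self.mapping)} genes, s={self.s})"


@dataclass
class ExpandedProfile:
    """Joint counts over non-empty class subsets; the multinomial object.

    ``counts`` maps a canonical subset key — a sorted tuple of class indices
    into ``class_order`` — to the number of genes annotated in exactly that
    set of target classes.  ``n`` is the number of annotated genes, i.e. the
    sum of the counts.  When unannotated genes are kept (see
    :func:`build_expanded`), they occupy the empty-subset cell ``()`` and
    are included in ``n``; they contribute to no class marginal.
    """

    n: int
    counts: dict[tuple[int, ...], int]
    class_order: list[str]
    n_unannotated: int = 0

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != self.n:
            raise ValueError(f"counts sum to {total}, expected n={self.n}")
        for key, c in self.counts.items():
            if c < 0:
                raise ValueError("negative count in expanded profile")
            if tuple(sorted(key)) != tuple(key):
                raise ValueError(f"subset key {key} is not canonical (sorted)")

    @property
    def s(self) -> int:
        return len(self.class_order)

    def frequencies(self) -> dict[tuple[int, ...], float]:
        """Relative cell frequencies (sum to 1 when n > 0)."""
        if self.n == 0:
            return {}
        return {k: c / self.n for k, c in self.counts.items()}

    def cells(self) -> list[tuple[int, ...]]:
        return sorted(self.counts)


@dataclass
class ContractedProfile:
    """Per-class marginal annotation frequencies (the functional profile).

    ``p[i]`` is the fraction of the list's annotated genes carrying class
    ``class_order[i]`` — counting every gene annotated in the class, not
    only those annotated exclusively in it.  Entries may sum to more than 1
    because classes overlap.
    """

    n: int
    p: np.ndarray
    class_order: list[str]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.class_order),):
            raise ValueError("profile length does not match class_order")
        if np.any(self.p < -1e-12) or np.any(self.p > 1 + 1e-12):
            raise ValueError("marginal frequencies must lie in [0, 1]")

    @property
    def s(self) -> int:
        return len(self.class_order)

    def counts(self) -> np.ndarray:
        """Absolute per-class counts n * p (rounded to nearest integer)."""
        return np.rint(self.n * self.p).astype(int)


@dataclass
class PairDecomposition:
    """Decomposition of two gene lists sharing k genes.

    ``P0`` is the expanded profile of the k shared genes, ``P1`` of the
    n - k genes exclusive to the first list, ``Q1`` of the m - k genes
    exclusive to the second.  The full-list profiles recompose exactly:
    n*P = k*P0 + (n-k)*P1 on counts, and symmetrically for the second list.
    """

    n: int
    m: int
    k: int
    P0: ExpandedProfile
    P1: ExpandedProfile
    Q1: ExpandedProfile
    class_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.m):
            raise ValueError("k cannot exceed min(n, m)")
        if not self.class_order:
            self.class_order = self.P0.class_order

    @property
    def s(self) -> int:
        return len(self.class_order)

    def expanded_P(self) -> ExpandedProfile:
        """Expanded profile of the full first list (shared + exclusive)."""
        return _merge_expanded(self.P0, self.P1)

    def expanded_Q(self) -> ExpandedProfile:
        return _merge_expanded(self.P0, self.Q1)


def _merge_expanded(a: ExpandedProfile, b: ExpandedProfile) -> ExpandedProfile:
    counts = dict(a.counts)
    for key, c in b.counts.items():
        counts[key] = counts.get(key, 0) + c
    return ExpandedProfile(a.n + b.n, counts, a.class_order,
                           a.n_unannotated + b.n_unannotated)


def build_expanded(genes: Iterable[str], ann: AnnotationIndex,
                   include_unannotated: bool = False) -> ExpandedProfile:
    """Count each gene once, in the cell of its full set of target classes.

    By default genes with no annotation among the target classes are
    excluded from the counts; their number is recorded in
    ``n_unannotated`` and a warning is emitted.  With
    ``include_unannotated=True`` they are kept in an explicit empty-subset
    cell instead, so n counts every submitted gene.  Duplicate identifiers
    are collapsed with a warning.

    Raises
    ------
    ValueError
        If no gene carries any annotation among the target classes.
    """
    gene_list = list(genes)
    unique = list(dict.fromkeys(gene_list))
    if len(unique) != len(gene_list):
        warnings.warn(
            f"{len(gene_list) - len(unique)} duplicate gene identifier(s) collapsed",
            stacklevel=2,
        )
    counts: dict[tuple[int, ...], int] = {}
    n_unann = 0
    for g in unique:
        classes = ann.classes_of(g)
        if not classes:
            n_unann += 1
            if include_unannotated:
                counts[()] = counts.get((), 0) + 1
            continue
        key = ann.subset_key(classes)
        counts[key] = counts.get(key, 0) + 1
    n = sum(counts.values())
    if n - counts.get((), 0) == 0:
        raise ValueError("no annotated genes: every gene lacks target-class annotation")
    if n_unann and not include_unannotated:
        warnings.warn(f"{n_unann} gene(s) without target-class annotation excluded",
                      stacklevel=2)
    return ExpandedProfile(n, counts, list(ann.class_order), n_unann)


def membership_matrix(e: ExpandedProfile) -> tuple[np.ndarray, np.ndarray]:
    """Indicator matrix M (s x cells) and cell count vector, in cell order.

    ``M[i, j] = 1`` iff class ``i`` belongs to subset cell ``j``; the
    contracted profile is ``M @ cell_frequencies``.
    """
    cells = e.cells()
    s = e.s
    M = np.zeros((s, len(cells)))
    cnt = np.zeros(len(cells))
    for j, key in enumerate(cells):
        cnt[j] = e.counts[key]
        for i in key:
            M[i, j] = 1.0
    return M, cnt


def contract(e: ExpandedProfile, class_order: Sequence[str] | None = None) -> ContractedProfile:
    """Marginalise an expanded profile to per-class frequencies.

    The marginal for class i sums the relative frequencies of every subset
    cell containing i.
    """
    if class_order is not None and list(class_order) != list(e.class_order):
        raise ValueError("class_order mismatch with expanded profile")
    if e.n == 0:
        raise ValueError("cannot contract an empty profile (n = 0)")
    p = np.zeros(e.s)
    for key, c in e.counts.items():
        for i in key:
            p[i] += c
    p /= e.n
    return ContractedProfile(e.n, p, list(e.class_order))


def pair_marginal(e: ExpandedProfile, i: int, j: int) -> float:
    """Fraction of genes annotated in both class i and class j.

    This is the joint marginal needed by the off-diagonal covariance terms.
    """
    if i == j:
        raise ValueError("pair_marginal requires i != j; use the single-class marginal")
    if e.n == 0:
        raise ValueError("empty profile")
    c = sum(cnt for key, cnt in e.counts.items() if i in key and j in key)
    return c / e.n


def squared_distance(P: ContractedProfile, Q: ContractedProfile) -> float:
    """Squared Euclidean distance between two contracted profiles.

    Symmetric, non-negative, zero iff the vectors coincide; bounded by s.
    """
    if P.class_order != Q.class_order:
        raise ValueError("profiles are over different class sets")
    diff = P.p - Q.p
    return float(diff @ diff)


def decompose_pair(listA: Iterable[str], listB: Iterable[str],
                   ann: AnnotationIndex,
                   include_unannotated: bool = False) -> PairDecomposition:
    """Split two gene lists into shared and exclusive expanded profiles.

    By default overlap is computed among *annotated* genes: a gene excluded
    from both lists for lack of annotation does not contribute to k.  With
    ``include_unannotated=True`` all genes count (the empty-cell policy of
    :func:`build_expanded`).  Empty components (k = 0, or a list fully
    contained in the other) yield empty expanded profiles with n = 0.
    """
    def keep(g):
        return include_unannotated or ann.classes_of(g)

    A = [g for g in dict.fromkeys(listA) if keep(g)]
    B = [g for g in dict.fromkeys(listB) if keep(g)]
    if not A or not B:
        raise ValueError("no annotated genes in one of the lists")
    setB = set(B)
    shared = [g for g in A if g in setB]
    onlyA = [g for g in A if g not in setB]
    setA = set(A)
    onlyB = [g for g in B if g not in setA]

    def _expanded(genes: list[str]) -> ExpandedProfile:
        if not genes:
            return ExpandedProfile(0, {}, list(ann.class_order))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return build_expanded(genes, ann, include_unannotated)

    return PairDecomposition(
        n=len(A), m=len(B), k=len(shared),
        P0=_expanded(shared), P1=_expanded(onlyA), Q1=_expanded(onlyB),
        class_order=list(ann.class_order),
    )


# ---------------------------------------------------------------------------
# plain-text I/O

def read_gene_list(path) -> list[str]:
    """Read a gene list: one identifier per line, '#' starts a comment."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return genes


def write_expanded_tsv(e: ExpandedProfile, path) -> None:
    """Write an expanded profile as TSV: subset (semicolon-joined IDs), count."""
    with open(path, "w") as fh:
        fh.write("subset\tcount\n")
        for key in e.cells():
            label = ";".join(e.class_order[i] for i in key)
            fh.write(f"{label}\t{e.counts[key]}\n")


def read_expanded_tsv(path, class_order: Sequence[str]) -> ExpandedProfile:
    """Read an expanded profile written by :func:`write_expanded_tsv`."""
    index = {c: i for i, c in enumerate(class_order)}
    counts: dict[tuple[int, ...], int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("subset"):
            raise ValueError("expected header line 'subset\\tcount'")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            label, cnt = line.split("\t")
            key = tuple(sorted(index[c] for c in label.split(";"))) if label else ()
            counts[key] = counts.get(key, 0) + int(cnt)
    return ExpandedProfile(sum(counts.values()), counts, list(class_order))
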