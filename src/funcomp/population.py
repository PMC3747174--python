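"""Population (theoretical) expanded profiles and two-list populations.

A population profile is a probability vector over expanded cells — the
multinomial law that sample expanded profiles are drawn from.  A pair
population additionally separates the law of the shared component (the k
genes common to both lists) from the laws of the two exclusive components,
which is what both the simulation engine and the approximate power
computation need.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covariance import JointCovariance
from .profiles import ExpandedProfile

__all__ = ["PopulationProfile", "PairPopulation"]


@dataclass
class PopulationProfile:
    """Multinomial cell probabilities over non-empty class subsets."""

    cells: list[tuple[int, ...]]
    probs: np.ndarray
    class_order: list[str]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.cells) != self.probs.size:
            raise ValueError("cells and probs length mismatch")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("cell probabilities must be non-negative and sum to 1")
        for key in self.cells:
            if tuple(sorted(key)) != tuple(key):
                raise ValueError(f"non-canonical subset key {key}")

    @property
    def s(self) -> int:
        return len(self.class_order)

    @classmethod
    def from_expanded(cls, e: ExpandedProfile) -> "PopulationProfile":
        """Observed relative frequencies taken as the population law."""
        if e.n == 0:
            raise ValueError("cannot build a population from an empty profile")
        cells = e.cells()
        probs = np.array([e.counts[c] for c in cells], dtype=float) / e.n
        return cls(cells, probs, list(e.class_order))

    @classmethod
    def pooled(cls, a: ExpandedProfile, b: ExpandedProfile) -> "PopulationProfile":
        """Pooled-count population of two expanded profiles (the shared
        null law used in the type-I-error simulations)."""
        counts: dict[tuple[int, ...], int] = dict(a.counts)
        for key, c in b.counts.items():
            counts[key] = counts.get(key, 0) + c
        cells = sorted(counts)
        total = a.n + b.n
        probs = np.array([counts[c] for c in cells], dtype=float) / total
        return cls(cells, probs, list(a.class_order))

    def membership_matrix(self) -> np.ndarray:
        M = np.zeros((self.s, len(self.cells)))
        for j, key in enumerate(self.cells):
            for i in key:
                M[i, j] = 1.0
        return M

    def contracted(self) -> np.ndarray:
        """Population per-class marginal vector P."""
        return self.membership_matrix() @ self.probs

    def covariance(self) -> np.ndarray:
        """Per-gene covariance: sigma_ii = p_i(1-p_i), sigma_ij = p_ij - p_i p_j."""
        M = self.membership_matrix()
        p = M @ self.probs
        joint = (M * self.probs) @ M.T
        sigma = joint - np.outer(p, p)
        np.fill_diagonal(sigma, p * (1.0 - p))
        return sigma

    def sample(self, n: int, rng: np.random.Generator) -> ExpandedProfile:
        """One multinomial draw of n genes over the expanded cells."""
        if n == 0:
            return ExpandedProfile(0, {}, list(self.class_order))
        draw = rng.multinomial(n, self.probs)
        counts = {c: int(v) for c, v in zip(self.cells, draw) if v > 0}
        return ExpandedProfile(n, counts, list(self.class_order))


@dataclass
class PairPopulation:
    """Population laws for two lists sharing k genes.

    ``pop0`` governs the shared component (drawn once, reused in both
    lists), ``pop1`` and ``popQ1`` the exclusive components.  Components
    with zero weight (k = 0, n = k or m = k) may be None.
    """

    pop0: PopulationProfile | None
    pop1: PopulationProfile | None
    popQ1: PopulationProfile | None

    @classmethod
    def disjoint(cls, popP: PopulationProfile, popQ: PopulationProfile) -> "PairPopulation":
        return cls(pop0=None, pop1=popP, popQ1=popQ)

    @classmethod
    def null(cls, pop: PopulationProfile) -> "PairPopulation":
        """All three components share one law (profile equality holds)."""
        return cls(pop0=pop, pop1=pop, popQ1=pop)

    def _component(self, which: str, weight: int) -> PopulationProfile | None:
        pop = getattr(self, which)
        if weight > 0 and pop is None:
            raise ValueError(f"population component {which} required (weight {weight})")
        return pop

    def mean_profiles(self, n: int, m: int, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Population contracted vectors P = (k/n)P0 + ((n-k)/n)P1 etc."""
        self._check(n, m, k)
        s = None
        for pop in (self.pop0, self.pop1, self.popQ1):
            if pop is not None:
                s = pop.s
                break
        p0 = self.pop0.contracted() if k > 0 else np.zeros(s)
        P = (k / n) * p0 + ((n - k) / n) * (self.pop1.contracted() if n > k else np.zeros(s))
        Q = (k / m) * p0 + ((m - k) / m) * (self.popQ1.contracted() if m > k else np.zeros(s))
        return P, Q

    def joint_covariance(self, n: int, m: int, k: int) -> JointCovariance:
        """Population-level analogue of the plug-in joint covariance."""
        self._check(n, m, k)
        s = (self.pop0 or self.pop1 or self.popQ1).s
        S0 = self.pop0.covariance() if k > 0 else np.zeros((s, s))
        S1 = self.pop1.covariance() if n - k > 0 else np.zeros((s, s))
        SQ1 = self.popQ1.covariance() if m - k > 0 else np.zeros((s, s))
        A = (k / n) * S0 + ((n - k) / n) * S1
        C = (k / m) * S0 + ((m - k) / m) * SQ1
        return JointCovariance(A=A, B=S0, C=C, n=n, m=m, k=k)

    def _check(self, n: int, m: int, k: int) -> None:
        if k > min(n, m):
            raise ValueError("k cannot exceed min(n, m)")
        self._component("pop0", k)
        self._component("pop1", n - k)
        self._component("popQ1", m - k)
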