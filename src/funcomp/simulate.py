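"""Monte-Carlo engine for type-I-error and power studies.

A scenario fixes a pair population (shared / exclusive multinomial laws
over expanded cells), list sizes n, m with overlap k, a significance level
and a replicate count.  Each replicate draws the shared expanded component
once — reused in both lists, which is what induces the cross-covariance
block between overlapping profiles — plus independent exclusive
components, then runs four procedures:

* the global profile-distance test;
* class-by-class Fisher tests with Holm adjustment (rejection = at least
  one significant class);
* the Pearson chi-square homogeneity comparator;
* the "additional detections" event of the combined procedure: global
  rejection with no Holm-significant class.

Rates are tallied with binomial Monte-Carlo standard errors and are fully
reproducible: one top-level seed spawns one child RNG stream per replicate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .classwise import _fisher_raw, chisq_homogeneity, class_counts, holm_adjust
from .comparison import ProfileComparison
from .population import PairPopulation, PopulationProfile
from .profiles import ExpandedProfile, PairDecomposition

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "random_population",
    "shifted_population",
    "sample_expanded",
    "simulate_pair",
    "run_scenario",
]


def random_population(s: int, rng: np.random.Generator, *,
                      extra_cells: int | None = None,
                      max_classes: int = 3,
                      concentration: float = 1.0) -> PopulationProfile:
    """A synthetic expanded-cell population over s classes.

    Emulates the gross structure of ontology annotation at a fixed level:
    every class has a singleton cell, plus ``extra_cells`` multi-class
    cells (default s // 2) of 2..max_classes classes each — genes
    annotated in several classes are what distinguish expanded from
    contracted profiles.  Cell probabilities are Dirichlet(concentration),
    so smaller concentrations give sparser, more skewed profiles.
    """
    class_order = [f"C{i + 1:03d}" for i in range(s)]
    cells = [(i,) for i in range(s)]
    if extra_cells is None:
        extra_cells = s // 2
    seen = set(cells)
    while len(cells) < s + extra_cells:
        size = int(rng.integers(2, max_classes + 1)) if max_classes >= 2 else 1
        size = min(size, s)
        key = tuple(sorted(rng.choice(s, size=size, replace=False).tolist()))
        if key not in seen:
            seen.add(key)
            cells.append(key)
    probs = rng.dirichlet(np.full(len(cells), concentration))
    return PopulationProfile(cells, probs, class_order)


def shifted_population(pop: PopulationProfile, shift: float,
                       rng: np.random.Generator) -> PopulationProfile:
    """Perturb a population's cell probabilities to build an alternative.

    Moves a fraction ``shift`` of the probability mass along a random
    direction (renormalised), giving a nearby population with a strictly
    positive profile distance for power studies.
    """
    if not 0.0 < shift < 1.0:
        raise ValueError("shift must be in (0, 1)")
    direction = rng.dirichlet(np.ones(pop.probs.size))
    probs = (1.0 - shift) * pop.probs + shift * direction
    return PopulationProfile(list(pop.cells), probs, list(pop.class_order))


def sample_expanded(pop: PopulationProfile, n: int,
                    rng: np.random.Generator) -> ExpandedProfile:
    """One multinomial draw of n genes over the population's expanded cells."""
    return pop.sample(n, rng)


def simulate_pair(population: PairPopulation, n: int, m: int, k: int,
                  rng: np.random.Generator) -> PairDecomposition:
    """Draw one overlapping list pair: shared component drawn once.

    The k shared genes are one multinomial draw reused in both lists; the
    exclusive components are independent draws of sizes n - k and m - k.
    """
    if k > min(n, m):
        raise ValueError("k cannot exceed min(n, m)")
    population._check(n, m, k)
    some = population.pop0 or population.pop1 or population.popQ1
    order = list(some.class_order)
    empty = ExpandedProfile(0, {}, order)
    P0 = population.pop0.sample(k, rng) if k > 0 else empty
    P1 = population.pop1.sample(n - k, rng) if n - k > 0 else empty
    Q1 = population.popQ1.sample(m - k, rng) if m - k > 0 else empty
    return PairDecomposition(n=n, m=m, k=k, P0=P0, P1=P1, Q1=Q1,
                             class_order=order)


@dataclass
class ScenarioConfig:
    """One simulation scenario: population, sizes, level, replicates, seed."""

    population: PairPopulation
    n: int
    m: int
    k: int = 0
    alpha: float = 0.05
    replicates: int = 10_000
    seed: int = 0
    null_true: bool | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.m):
            raise ValueError("k cannot exceed min(n, m)")
        if self.null_true is None:
            p0, p1, q1 = (self.population.pop0, self.population.pop1,
                          self.population.popQ1)
            self.null_true = (p1 is q1) or (
                p1 is not None and q1 is not None
                and p1.cells == q1.cells and np.array_equal(p1.probs, q1.probs))

    @classmethod
    def from_json(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            obj = json.load(fh)
        class_order = obj["class_order"]
        cells = [tuple(sorted(class_order.index(c) for c in cell))
                 for cell in obj["cells"]]

        def pop(key):
            probs = obj.get(key)
            if probs is None:
                return None
            return PopulationProfile(cells, np.asarray(probs, dtype=float),
                                     class_order)

        population = PairPopulation(pop0=pop("pop0"), pop1=pop("pop1"),
                                    popQ1=pop("popQ1"))
        return cls(population=population, n=obj["n"], m=obj["m"],
                   k=obj.get("k", 0), alpha=obj.get("alpha", 0.05),
                   replicates=obj.get("replicates", 10_000),
                   seed=obj.get("seed", 0), label=obj.get("label", ""))


@dataclass
class ScenarioResult:
    """Per-procedure rejection rates with Monte-Carlo standard errors."""

    config: ScenarioConfig = field(repr=False)
    replicates: int = 0
    global_rate: float = 0.0
    cbc_rate: float = 0.0            # any Holm-significant class
    chisq_rate: float = 0.0
    additional_rate: float = 0.0     # global reject, no Holm-significant class
    cbc_not_global_rate: float = 0.0  # Holm-significant, global not rejected
    chisq_failures: int = 0

    def se(self, rate: float) -> float:
        return float(np.sqrt(rate * (1.0 - rate) / self.replicates))

    def to_dict(self) -> dict:
        return {
            "label": self.config.label,
            "replicates": self.replicates,
            "class_by_class": self.cbc_rate,
            "chi_square": self.chisq_rate,
            "new_global": self.global_rate,
            "additional_significant": self.additional_rate,
            "cbc_not_global": self.cbc_not_global_rate,
            "se_class_by_class": self.se(self.cbc_rate),
            "se_chi_square": self.se(self.chisq_rate),
            "se_new_global": self.se(self.global_rate),
            "se_additional": self.se(self.additional_rate),
        }

    def to_tsv_row(self, header: bool = False) -> str:
        d = self.to_dict()
        lines = []
        if header:
            lines.append("\t".join(d))
        lines.append("\t".join(str(v) for v in d.values()))
        return "\n".join(lines) + "\n"


def run_scenario(cfg: ScenarioConfig) -> ScenarioResult:
    """Run all four procedures over the scenario's replicates."""
    if cfg.replicates < 100:
        warnings.warn("fewer than 100 replicates: Monte-Carlo standard errors "
                      "will dominate the estimates", stacklevel=2)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
    n_global = n_cbc = n_chisq = n_add = n_cbc_only = 0
    chisq_failures = 0
    alpha = cfg.alpha
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ss in streams:
            rng = np.random.default_rng(ss)
            dec = simulate_pair(cfg.population, cfg.n, cfg.m, cfg.k, rng)
            model = ProfileComparison.from_decomposition(dec)
            res = model.fit(alpha=alpha)
            cA = class_counts(model.expanded_P)
            cB = class_counts(model.expanded_Q)
            raw, _ = _fisher_raw(cA, cB, cfg.n, cfg.m)
            any_cbc = bool(np.any(holm_adjust(raw) < alpha))
            try:
                _, _, chi_p = chisq_homogeneity(cA, cB)
                chi_rej = chi_p < alpha
            except ValueError:
                chisq_failures += 1
                chi_rej = False
            n_global += res.reject
            n_cbc += any_cbc
            n_chisq += chi_rej
            n_add += res.reject and not any_cbc
            n_cbc_only += any_cbc and not res.reject
    R = cfg.replicates
    return ScenarioResult(
        config=cfg, replicates=R,
        global_rate=n_global / R, cbc_rate=n_cbc / R, chisq_rate=n_chisq / R,
        additional_rate=n_add / R, cbc_not_global_rate=n_cbc_only / R,
        chisq_failures=chisq_failures,
    )
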