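# Methods

## The model

`funcomp` compares two gene lists through their *functional profiles*: for
a fixed set of `s` ontology classes A₁…A_s (typically a Gene Ontology
level cut, or any set of "interesting" classes), the profile of a list is
the vector P̂ = (p̂₁, …, p̂_s) of per-class annotation frequencies. Because
one gene may be annotated in several classes, these marginals are not a
multinomial vector — they can sum to more than 1 and their components are
correlated through multi-class genes. The multinomial object underneath is
the *expanded profile*: joint counts over the non-empty subsets of classes,
where each gene occupies exactly one cell (the full set of classes it is
annotated in). Every distributional result in the package is derived from
this expanded representation.

Dissimilarity between two lists is the squared Euclidean distance between
their contracted profiles, d(P̂, Q̂) = Σᵢ (p̂ᵢ − q̂ᵢ)². The hypotheses are

    H₀: d(P, Q) = 0   vs   H₁: d(P, Q) > 0

for the population profiles P and Q.

### Null distribution of the global statistic

The statistic is V = (nm/(n+m)) · d(P̂, Q̂) for list sizes n and m. Writing
the stacked deviation D = √(nm/(n+m)) · (P̂ − P, Q̂ − Q), the central limit
theorem for the expanded multinomial gives D →d N(0, Σ_PQ), and under H₀

    V = Dᵗ J D,   J = [[I_s, −I_s], [−I_s, I_s]],

so V is asymptotically a weighted sum Σᵢ βᵢ χ²₁ᵢ of independent
one-degree-of-freedom chi-squares, the weights being the non-zero
eigenvalues of J·Σ_PQ. Since J = KᵗK with K = [I_s, −I_s], those equal the
eigenvalues of the symmetric s×s matrix K Σ_PQ Kᵗ, which is what the code
diagonalises.

### Covariance structure with shared genes

Two lists may share k genes. Decomposing each list into its shared and
exclusive parts (P̂ = (k/n)·P̂₀ + ((n−k)/n)·P̂₁, and symmetrically for Q̂),
the joint covariance is assembled from per-subsample profile covariances
Σ₀, Σ₁, Σ_Q1 — each with entries σᵢᵢ = pᵢ(1−pᵢ) and σᵢⱼ = pᵢⱼ − pᵢpⱼ,
where pᵢⱼ is the fraction of genes annotated in both classes — as

    Σ_PQ = [[ m/(n+m)·A,  k/(n+m)·B ],
            [ k/(n+m)·Bᵗ, n/(n+m)·C ]],
    A = (k/n)Σ₀ + ((n−k)/n)Σ₁,  B = Σ₀,  C = (k/m)Σ₀ + ((m−k)/m)Σ_Q1.

The cross-block is entirely driven by the shared component; for disjoint
lists (k = 0) the matrix is block-diagonal. Weights with empty subsamples
(k = 0, n = k, m = k) are defined as zero and the corresponding covariance
is never evaluated. Estimation is plug-in from the observed subsamples; no
pooling under H₀ is applied (a pooled variant is deliberately not the
default, because the confidence interval and power computations need the
unpooled form and the test is then internally consistent).

### Confidence interval and power

Under the alternative, √(nm/(n+m)) · (d(P̂,Q̂) − d(P,Q)) is asymptotically
N(0, σ²) with σ² = 4·(P−Q, Q−P)ᵗ Σ_PQ (P−Q, Q−P). The reported interval is

    d(P̂,Q̂) ± z_α · σ̂ · √(1/n + 1/m),

a 1 − 2α interval (z_α the upper-α normal quantile; the default α = 0.05
gives a 90% interval). The lower limit is *not* truncated at zero — near
H₀ the normal approximation legitimately produces small negative lower
limits, and truncation would bias empirical coverage checks.

The approximate power at a population alternative evaluates the rejection
region {V > v(α, s)} under the same normal approximation. The estimated
distance decomposes as d + linear + quadratic term; the linear term is
N(0, σ²(1/n+1/m)) and the quadratic term is kept through its mean,
Σβᵢ·(n+m)/(nm). Dropping the mean correction underestimates power
noticeably at moderate n (in our validation scenario: 0.66 predicted vs
0.86 simulated without the correction, 0.88 with it).

## Computing the mixture tail

P(Σβᵢχ²₁ᵢ > x) is computed by, in order:

1. **Closed form** when all positive weights are equal: the mixture is a
   scaled χ² with as many degrees of freedom as positive weights. This
   covers s = 1, where the global test collapses exactly onto the unpooled
   two-proportion z-test (p = P(χ²₁ > z²)).
2. **Ruben's series**: the distribution is expanded as a mixture
   Σ_k a_k χ²_{s+2k} on the scale of the smallest weight. All mixture
   coefficients are non-negative and sum to one, so the truncation error
   is bounded by the unaccumulated mass; the series is cut when that mass
   drops below 1e-10 (cap 120 000 terms; the series is skipped when the
   leading coefficient underflows, which signals slow convergence).
3. **Characteristic-function inversion** (Imhof's integral evaluated by a
   midpoint/trapezoid sum, as in Davies' method): the step is 2π/(x + c)
   where c bounds the far tail via the Chernoff bound on the mixture mgf
   (aliasing error ≤ P(V > c)), and the sum is cut at an analytic envelope
   of the integrand (ρ(u) ≥ u^{j/2}·Π√βᵢ over the j largest weights). The
   integrand is evaluated in log space so spectra with thousands of
   weights cannot overflow. With two distinct weights the integrand decays
   only like u⁻², so the grid becomes impractically long and the routine
   declines — Ruben always converges quickly there instead.
4. **Seeded Monte Carlo** (10⁶ squared-normal draws, fixed internal seed)
   as a deterministic last resort for spectra where both exact routes
   stall (requires an enormous weight spread *and* many weights).

Routes 2 and 3 are ordered by the weight spread β_max/β_min: Ruben needs
roughly 20·β_max/β_min terms, so beyond a spread of 500 the inversion goes
first. Wide spreads are not exotic — they are the norm for overlapping
lists, where the reduced matrix (mA − kB − kBᵗ + nC)/(n+m) nearly cancels
and small eigenvalues appear; the routing keeps per-test cost at
milliseconds there. The two routes agree to ~1e-11 on random spectra; the
accuracy target for the engine is 1e-6 absolute and the internal
tolerances are set to 1e-9.
Quantiles v(α, s) are obtained by bracketing (doubling from Σβ) plus Brent
refinement on the tail function.

Eigenvalues of the reduced matrix below 1e-12 × (largest eigenvalue) are
truncated to zero; more negative values (numerically impossible for a
valid covariance, but conceivable with degenerate inputs) are clipped with
a warning. An all-zero spectrum means the statistic is identically zero —
this happens for identical annotated lists — and the p-value is reported
as 1 with a warning.

## Class-by-class testing and the decision procedure

Each class is tested with a two-sided Fisher exact test on the 2×2 table
[in class vs not] × [list A vs list B], two-sidedness defined by summation
of all conditional table probabilities not exceeding the observed one
(with the customary 1 + 1e-7 relative tie slack). Genes shared by the two
lists are counted in both columns — the field's convention for
overlapping lists, documented here as a caveat since the two columns are
then not independent samples. Classes with an empty margin get p = 1 and
a `degenerate` flag. Family-wise error is controlled with Holm's
step-down adjustment.

The combined procedure gates the classwise analysis behind the global
test: (1) if the global test does not reject, stop — no classwise tests
are run, so the procedure's type-I error is dominated by the global
test's; (2) otherwise run Fisher + Holm and report any surviving classes;
(3) if none survives, either flag the class with the smallest unadjusted
p-value (default) or recommend re-testing at a less specific class set
(`step3="uplevel"`).

A Pearson chi-square homogeneity test on the 2×s table of per-class
counts is included purely as the classical comparator: with overlapping
classes its columns are not multinomial cells, its size is uncontrolled,
and the simulation engine exists partly to demonstrate that. Zero-count
classes are dropped before computing the statistic (df = s′ − 1).

## The simulation engine and what it emulates

Scenario populations are multinomial laws over expanded cells. Each
replicate draws the k shared genes **once** and reuses that draw in both
lists — the only coupling consistent with the decomposition identities and
with the B = Σ₀ cross-block — plus independent exclusive components of
sizes n − k and m − k. One top-level seed spawns an independent child
stream per replicate, so results are exactly reproducible and
order-independent.

The synthetic population generator (`random_population`) emulates the
gross structure of level-cut GO annotation: one singleton cell per class
plus s/2 multi-class cells of two or three classes (multi-class genes are
the reason expanded profiles exist), with Dirichlet(1) cell
probabilities. It does **not** emulate: the extreme class-count skew of
deep GO levels (hundreds of near-empty classes), annotation
incompleteness and bias, or dependence between annotation and list
membership. Passing calibration tests on these synthetics therefore
demonstrates correctness of the distributional machinery under the
multinomial model, not robustness to annotation artefacts in real data.

Default study conditions used by the test suite and the acceptance
script: null calibration at s = 20, n = m = 150, k = 0 and at s = 10,
n = 110, m = 99, k = 46 (sizes patterned on a published overlapping-lists
comparison), 2000 replicates at α = 0.05; power and coverage studies at
s = 8–10, n = m = 150–200, 1000–2000 replicates. Replicate counts were
chosen so binomial standard errors (~0.005 at rate 0.05, 2000 replicates)
are small relative to the acceptance bands.

## Numerical and design choices

- Expanded cells are keyed by sorted tuples of class indices, so profiles
  are independent of input order; class order itself is fixed by the
  `AnnotationIndex` (lexicographic when built from an ontology cut).
- n and m count genes with at least one annotation among the target
  classes; unannotated genes are excluded with a warning. The alternative
  policy — keeping them in an explicit empty cell so that n counts all
  submitted genes — is available via `include_unannotated=True` (this is
  also what makes the single-class case reduce to the textbook
  two-proportion z-test, whose variance needs p̂ < 1).
- Duplicate identifiers within a list are collapsed with a warning;
  identifiers are case-sensitive opaque strings.
- A small-sample warning fires when min(n, m) < 30 or when a class's
  expected count is below 5 in either list; the method is purely
  asymptotic and nothing in the package corrects for small samples.
- Ontology levels count the namespace root as level 1, so "level 2" is
  the root's children; a term reachable at several depths is assigned its
  minimum is_a depth. Only is_a edges are followed by default (part_of
  behind a flag); obsolete terms are dropped and alt_ids resolved.
- The chi-square comparator's construction (textbook homogeneity test,
  df = s′ − 1 after dropping empty columns) is a documented choice; it is
  a negative control, not a recommended method.

## Known limitations

- All inference is asymptotic; no exact or permutation variant is
  provided.
- The distance interval is calibrated (empirical coverage ≈ 0.90 at the
  nominal 1 − 2α = 0.90) when the true distance is large relative to its
  sampling noise; as d approaches 0 the quadratic term's upward bias in
  d̂ makes the interval conservative (coverage drifting toward ~0.95 in
  our simulations) — the same near-null regime in which the lower limit
  can go negative.
- Fisher tables for overlapping lists double-count shared genes (see
  above); the gated procedure inherits this convention in step 2.
- Near-singular joint covariances (many empty classes) are handled only
  by eigenvalue truncation; no shrinkage estimation is offered.
- Equivalence testing (demonstrating near-equality of profiles) is out of
  scope; the test demonstrates difference only.
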