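# Methods

## The question and the data model

The package analyses the *space-phylogeny matrix* of a vegetation plot: the
pairing, over all unordered pairs of individual plants within a plot, of
their physical separation (Euclidean distance on the plot's x/y
coordinates, metres) with the phylogenetic separation of their species
(patristic distance on a dated tree, millions of years, Ma). Inputs are

* an ultrametric rooted phylogeny in newick with branch lengths on every
  edge (typically genus-level, one exemplar tip per genus); and
* stem-map tables: one row per individual with plot id, species, regional
  status (`indigenous`/`alien`), optional family, and coordinates inside a
  plot of known dimensions (default 5 × 5 m), plus per-plot metadata giving
  the vegetation type (`forest`/`grassland`).

Tree inference and dating are out of scope: the tree is an input. Species
absent from the tree can be resolved to their genus tip when one exists
(`resolve_to_genus`); congeners then have patristic distance zero, which is
the correct degenerate behaviour for a genus-level tree.

## Tree quantities

**Patristic distance** between tips i and j is computed as
depth(i) + depth(j) − 2·depth(MRCA). **Faith's PD** of a set S is the sum
of branch lengths over the union of the tips' root paths — i.e. the minimal
spanning subtree *including the root*, the convention of the classic
community-phylogenetics toolchain; `rooted=False` gives the MRCA-spanning
variant for comparison. On an ultrametric tree PD of a single species
equals the root age, PD is monotone under adding species, and PD of all
tips equals the total branch length; these invariants are property-tested.

Ultrametricity is validated at read time with relative tolerance 1e-6 on
the spread of root-to-tip depths. Violations warn rather than fail (dated
empirical trees carry rounding); `strict_ultrametric=True` escalates to an
error. Polytomies are accepted as-is; path sums are well defined regardless
of resolution.

## Pair matrices and the Mantel test

Each heterospecific pair of individuals inherits the patristic distance of
its two species; conspecific pairs get 0 and are **included by default** —
the zero-distance pairs are precisely how spatial aggregation of
conspecifics enters the statistic. `include_conspecific=False` masks them,
for the variant analysis restricted to heterospecific pairs; the mask is a
property of species identity and stays fixed under permutation.

The Mantel statistic is Pearson's r over the vectorised upper triangles.
The null distribution jointly permutes rows and columns of the physical
matrix by a random permutation of individual labels — the permutation unit
is the individual, which the individual-level construction dictates. The
p-value uses the add-one rule, p = (1 + #{r\* ≥ r}) / (1 + n_perm), so it is
never zero and is floored at 1/(n_perm + 1). The default alternative is
one-sided "greater" (attraction of relatives); "two-sided" and "less" cover
the repulsion hypothesis. With n = 4–6 individuals the Monte-Carlo p is
tested against the exact p from all n! permutations, and under the κ = 0
generator the rejection rate at α = 0.05 calibrates to ≈ 0.05.

Zero variance in either distance vector (e.g. a single-species plot with
coincident stems) raises a degeneracy error and flags the plot; it is never
silently reported as r = 0.

## The PD randomization null

A plot of richness k is compared against `n_rep` (default 10,000) random
assemblages of k species drawn uniformly *without* abundance weighting from
the species pool — richness is the only constraint. The pool defaults to
all species observed across every plot of both vegetation types (a
grassland–forest mix); a per-vegetation pool is available by passing a
different pool. Tail probabilities are rank-based with ties counted
inclusively and add-one smoothing; classification is two-sided at overall
α = 0.05: clustered if p_low ≤ 0.025, overdispersed if p_high ≤ 0.025,
otherwise neither. A degenerate null (star tree: every k-subset has
identical PD) therefore classifies as neither rather than as both.
Replicates are vectorised through a leaf × edge incidence matrix, making
10,000 replicates per plot cheap.

`run_pd_suite` repeats the classification under three configurations —
full data, aliens removed, graminoids removed — recomputing the pool per
configuration. "Graminoids" defaults to family Poaceae; the broader
Poaceae + Cyperaceae set is available via `configs` (both readings of
"grasses" occur in field practice, the narrow one is the default rerun).
A plot emptied by a filter is marked unevaluable and the rest proceed.

## Comparative layer

One-way ANOVA (classical between/within mean squares, via
`scipy.stats.f_oneway` after explicit degeneracy checks) compares forest
and grassland on any per-plot variable. Mantel r is then modelled with four
Gaussian GLMs — identity link, so they are ordinary least squares with
classical standard errors — one per covariate (richness, PD, density,
ln(% alien + 1)), each with terms vegetation + covariate +
vegetation × covariate: 4 × 3 = twelve non-intercept hypothesis tests. A
single additive model over all covariates is available behind
`full_model=True` but is not the default: twenty plots cannot support the
full interaction surface. Covariates are fitted on their raw scales. The
log transform of percent alien uses ln(pct + 1) so zero-alien plots are
representable; the offset is an argument.

## The synthetic-data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream claim is verified.

* **Tree** — pure-birth (Yule) topology: exponential waiting times with
  rate equal to the lineage count, uniform choice of the splitting lineage,
  node times rescaled so the root age is exact. The waiting-time process is
  exposed (`yule_event_times`) and tested against its analytic expectation
  (mean time-to-present = Σ_{k=2..n} 1/k).
* **Niche centres** — two independent Brownian traits along the tree
  (per-edge variance ∝ branch length), affinely rescaled to the plot
  square. BM is the package's choice of coupling mechanism: any mechanism
  making patristic and spatial distance positively associated would serve;
  BM is standard and analytically tractable.
* **Plots** — richness and total abundance drawn uniformly from
  vegetation-specific ranges; abundances follow a geometric rank series
  (ratio 0.8) assigned in random species order, with every species
  guaranteed one individual and totals conserved. Each individual is placed
  at its species centre plus isotropic Gaussian noise (σ, default 0.75 m)
  with probability κ, otherwise uniformly; out-of-plot draws are resampled,
  not clipped, keeping density smooth at the edges.
* **Defaults** emulate the motivating study design: 20 plots of 5 × 5 m,
  ten per vegetation type, a 200-species pool on a 150 Ma tree, richness
  10–35, 100–250 individuals per forest plot and 200–400 per grassland plot
  (grassland denser), and 9% of pool species alien (≈ 18 of 194). With
  rank-shuffled abundances the alien share of *individuals* lands near the
  species share (~7–10%), slightly above the ~6% a field study records when
  aliens are rarer than average — a known, accepted simplification. Aliens
  are phylogenetically unconstrained by default ("aliens blend in");
  `alien_clade=True` confines them to one clade to simulate the
  alternative. `grassland_shallow_clade=True` restricts grassland species
  to the lowest-crown-age clade holding 15–45% of the pool, reproducing the
  low-PD, clustered grassland signature.

κ is the recoverable parameter: mean per-plot Mantel r is strictly
increasing over κ ∈ {0, 0.5, 1} (≈ 0.00 / 0.09 / 0.39 under the scaled-down
acceptance conditions), the κ = 0 rejection rate is ≈ α, and κ = 1 makes
most plots significant. Everything is reproducible from a single seed via
`numpy.random.SeedSequence` spawning; same seed, byte-identical output
files.

What the generator does **not** emulate: real point-pattern features such
as clumped recruitment independent of phylogeny, size structure, edge
effects from surveying, measurement error in coordinates (the ≤5 cm field
error is not modelled — coordinates are taken at face value), or
environmental gradients within the plot. Passing tests therefore certify
the statistical machinery, not the ecological realism of any particular
field system.

## Numerical and problem-size choices

Permutation and randomization defaults are 999 and 10,000 as in standard
practice; the validation suites scale down to keep runtimes in minutes on
one CPU — Mantel calibration uses 1000 plots of 25–40 individuals at 199
permutations (α = 0.05 remains exactly attainable since 10/200 = 0.05),
the PD-null calibration 500 assemblages at 1000 replicates, and the κ-
recovery sweep 50 four-plot studies per κ with the r statistic alone (no
permutations needed for a mean). Tie handling in the PD null uses a 1e-9
relative tolerance so exact-tie degenerate nulls are counted inclusively.

## Limitations

* Plots are analysed independently; no spatial autocorrelation between
  plots, no mixed models.
* No abundance-weighted or trait-informed null models.
* The Mantel test's known conservatism/liberality under strong
  autocorrelation within matrices is inherited, not corrected.
* The GLM layer assumes Gaussian errors for r; with ~20 plots this is a
  small-sample analysis and is treated as such (per-covariate models, no
  full model by default).
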