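# Methods

## Diversity currency

All three diversity dimensions are measured as branch-length sums on a
tree, so one optimization engine serves taxonomic (TD), phylogenetic
(PD) and functional (FD) diversity:

* α-diversity of an assemblage is the total branch length of the minimal
  subtree connecting the root and every species present. The root path
  is included, which makes the star-tree/richness equivalence exact
  (each of k species on a unit star tree contributes exactly its own
  branch) and keeps single-species PD positive. Units are whatever the
  tree's branch lengths carry: species counts on a star tree, time on a
  dated phylogeny, Gower distance on a functional tree.
* β-diversity between two assemblages partitions the Jaccard-family
  total dissimilarity into replacement and richness-difference
  components, `β_total = (B+C)/(A+B+C)`, `β_repl = 2·min(B,C)/(A+B+C)`,
  `β_rich = |B−C|/(A+B+C)`, computed on branch sets: a branch belongs to
  an assemblage iff it lies on a root-to-present-tip path, `A` is the
  shared length, `B`/`C` the unique lengths. The identity
  `β_total = β_repl + β_rich` holds by construction and is enforced to
  1e-12 in tests. Both assemblages empty yields (0, 0, 0).

Diversity is incidence-based throughout: abundances in sample matrices
are collapsed to presence/absence before any diversity computation.
Abundance-weighted variants are out of scope.

## Trees

* **Star tree**: every species attached to the root by a branch of unit
  (or user-chosen) length.
* **Linnaean surrogate tree**: with `r` supra-specific ranks, each rank
  step is `depth / r` (default depth 1), giving an ultrametric tree in
  which congeners are `2·depth/r` apart. The worked arithmetic of equal
  rank steps forces the coarsest rank to coincide with the root level;
  when several coarsest-rank taxa exist they attach to the root with
  zero-length stems, so species sharing no rank are `2·depth` apart.
  Nesting is validated (each taxon maps to exactly one parent taxon).
* **Neighbor joining** (functional trees, or any distance input) uses
  the Saitou–Nei agglomeration from scikit-bio. Labels are sorted before
  agglomeration so the result is independent of input row order.
  Negative branch-length estimates — possible for non-additive input —
  are clamped to zero with a warning, since downstream diversity sums
  require non-negative lengths. The unrooted NJ result is rooted at the
  midpoint of its diameter path: deterministic, label-order independent,
  and the natural choice when no outgroup exists. Rooting does affect
  branch-length sums slightly; any other convention can be applied by
  rooting externally and passing the tree in.

## Functional distances

Weighted Gower dissimilarity over mixed trait types: numeric
contributions are `|xᵢ−xₖ|` scaled by the trait's observed range over
the **whole** table (stable under subsetting of pairs; a zero-range
trait contributes 0), binary and categorical contributions are 0/1.
Per-trait weights are user input (e.g. the 1/n-types convention for
families of related binary traits is expressed through the weight
vector, not hard-coded); they matter only up to a common factor. Pairs
missing a trait drop it and renormalize the remaining weights — the
conventional treatment for patchy bibliographic trait data; a pair
sharing no trait is an error rather than a silent guess.
Size-correlated morphometric traits can be replaced by their OLS
residuals against a body-size proxy (`residualize`) before distance
computation.

## The optimizer

Reference data are (near-)complete inventories: samples tagged with
(site, method), pooled per site to give each site's "true" diversity.
An allocation `(n₁…n_k)` of sample units per method is scored by drawing
`n_m` samples per method and site uniformly without replacement, pooling
to a community, computing its α (or the three β matrices across sites),
and standardizing per site by the true value so every site weighs
equally in the average. The β bias of an allocation is the mean over the
three components of the mean absolute deviation from the true pairwise
matrices; efficiency `1 − bias` is therefore bounded in [0, 1] and
directly comparable with the α proportion axis.

* **Monte Carlo**: default 1000 runs (the recommended floor for final
  analyses; explorations can use fewer). The reported standard error is
  the standard deviation of per-run scores over √runs.
* **Exact enumeration**: when the number of distinct sample subsets is
  at most `exact_threshold` (default 1000) the expectation is computed
  by full enumeration instead (SE 0). For α the expectation factorizes
  over sites, so the per-site subset count is what is bounded; for β the
  product over sites is bounded, since site draws are coupled through
  the pairwise matrices.
* **Random numbers**: one master seed; permutation streams are derived
  per (site, method, run). Every allocation is scored against the same
  draws (common random numbers), so adding candidates never perturbs
  other scores, results are bit-reproducible, and each run's drawn
  subset grows monotonically along nested sequences — expected α
  proportion is non-decreasing along a nested sequence even under Monte
  Carlo, not just in expectation.
* **Exhaustive search** enumerates every allocation containing the
  starting pool (constrained optimization), groups by cost, and keeps
  the best score per cost level; ties go to the lexicographically
  smallest method-count vector. The enumeration cap (default 10⁶)
  guards against combinatorial blow-up; past it the nested variant is
  the documented alternative.
* **Nested (greedy) search** adds, at each step, one sample of the
  method with the highest score gain per cost unit, producing a nested
  protocol sequence and its accumulation curve. Ties prefer the cheaper
  method, then the lexicographically first name. A zero-cost candidate
  with positive gain is taken before any priced one.
* **Random-protocol envelope**: at each effort level, protocols drawn by
  assigning each unit to a uniformly random method with remaining
  capacity are scored, and empirical quantiles (default 2.5/50/97.5%)
  returned as the band an optimized curve should be judged against.

"True" diversity is the observed total over all samples; no
nonparametric richness estimator is built in. Where an extrapolated
truth is preferred, compute per-site true values externally and scale —
the standardization makes only relative values matter.

Costs: `Σ_m [fixed_m·1(n_m>0) + variable_m·n_m]`, fixed charged once on
first use of a method with no economies of scale, currency an opaque
unit (money, person-hours, days). Method-presence decisions (use a
method at all sites or not at all) are expressed as allocations over
per-site units with pools of size 1 — no special code path.

## Synthetic surveys

`simulate_survey` emulates the features that make protocol choice
non-trivial: method-specific detection biases (per-method × per-species
detection probabilities, e.g. disjoint clades per method), a
right-skewed lognormal abundance distribution (defaults: log-mean 2.0,
log-sd 1.2), compositional turnover between sites (each species is,
with probability `turnover`, a single-site specialist), a Yule phylogeny,
and a mixed numeric/binary/categorical trait table with a size-correlated
trait. Recording is presence ~ Bernoulli(detection), with counts drawn
from a zero-truncated Poisson of the species' latent abundance, so the
configured detection probability is exactly the per-sample recording
rate — a property the test suite verifies by convergence.

What it does **not** emulate: spatial structure, temporal
autocorrelation, observer fatigue, abundance-dependent detectability,
or any taxon-specific biology. Passing tests demonstrate the machinery
is correct under known structure, not that any particular field system
behaves this way.

`planted_optimum_scenario` is the optimizer's ground-truth harness: two
equal-cost methods detecting disjoint star-tree clades of branch length
3 and 1, per-sample detection 0.9, one site. The expected captured
proportion of `(n_A, n_B)` has the closed form
`[(1−0.1^{n_A})·3 + (1−0.1^{n_B})·1] / 4`, so the best split at any
budget is known independently of the optimizer; at budget 2 it is one
sample of each method.

## Problem sizes and tolerances

The shipped test and acceptance runs use deliberately small instances —
toy surveys of 2 sites × 2 methods × 2 samples for oracle comparisons
(≤ 16 distinct subsets, fully enumerable), 10,000 Monte-Carlo runs for
the 3-standard-error agreement checks, 100 replicates for planted-optimum
recovery, and 100 random 4–8 taxon trees for NJ additivity at 1e-9 —
sizes at which exact brute-force oracles are computable and the whole
suite runs in seconds. Real analyses scale the same code up; with many
methods and samples the exhaustive search grows combinatorially and the
nested search (linear in samples × methods) is the practical tool.

Numerical conventions: β identity asserted to 1e-12; ultrametricity and
Newick round-trips to 1e-9; Gower asymmetry from floating point is
symmetrized by averaging; deterministic combinations report SE 0.

## Known limitations

* Single scalar cost axis; no joint money/time/personnel constraints.
* Incidence-based only; no abundance-weighted diversity.
* No kernel-density hypervolume FD; trees are the FD representation.
* Greedy nested sequences can be suboptimal at a given cost (verified
  against the exhaustive optimum in tests, never above it).
* The Monte-Carlo resampling treats the reference inventory as the
  population; sampling error in the reference itself is not propagated.
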