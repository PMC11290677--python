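# surveyopt

Cost-aware optimization of biodiversity sampling protocols.

Ecologists inventorying or monitoring a community rarely rely on a single
method: spiders are sampled by beating, sweeping, ground searching and
pitfall traps; bats by mist nets and acoustic recorders. Each method is
biased toward a different part of the assemblage and carries different
fixed costs (gear) and variable costs (effort per sample). `surveyopt`
answers the design question this raises: **given a budget, how many sample
units of each method should a protocol use?**

Two goals are distinguished:

* **Inventorying (α-sampling)** — maximize the expected proportion of a
  site's true diversity captured, at every cost level.
* **Monitoring (β-sampling)** — minimize the bias between sampled and true
  β-diversity across sites or times, reported as efficiency `1 − bias`.

Both are optimized for three diversity dimensions under one currency:
diversity of an assemblage is the sum of branch lengths of the minimal
root-spanning subtree on

* a unit **star tree** (taxonomic diversity, TD — equals species richness),
* a phylogeny or Linnaean surrogate tree (phylogenetic diversity, PD),
* a **functional tree** from weighted Gower trait distances via
  neighbor joining (functional diversity, FD).

β-diversity is partitioned into antithetic processes,
`β_total = β_repl + β_rich` with

```
β_total = (B + C) / (A + B + C)      # Jaccard-family total dissimilarity
β_repl  = 2·min(B, C) / (A + B + C)  # species/branch replacement
β_rich  = |B − C| / (A + B + C)      # richness difference
```

where `A` is branch length shared by both assemblages' subtrees and `B`,
`C` the lengths unique to each.

The optimizer scores an allocation `(n₁, …, n_k)` of sample units per
method by re-sampling the reference data without replacement (Monte Carlo,
or exact subset enumeration when pools are small), standardizing each
site's sampled diversity by its true (pooled) diversity, and averaging
over sites. Allocation cost is `Σ_m [fixed_m·1(n_m>0) + variable_m·n_m]`.
Searches are exhaustive (all allocations, best per cost level) or nested
greedy (add, at each step, the sample with the steepest gain per cost
unit, yielding one protocol usable at any budget).

## Worked example

Simulate a two-method bat-like survey (mist nets detect species 1–12,
acoustic recorders species 9–16, two sites, six samples per site and
method) and optimize an inventorying protocol under the itemized
two-method cost model:

```python
import surveyopt as so

cfg = so.SimConfig(
    n_species=16, n_sites=2, samples_per_site=6, seed=11,
    detection={
        "mist_nets": {f"sp{i:02d}": 0.6 for i in range(1, 13)},
        "acoustic": {f"sp{i:02d}": 0.5 for i in range(9, 17)},
    },
    turnover=0.25,
)
survey = so.simulate_survey(cfg)

costs = so.CostModel({
    "mist_nets": so.MethodCost(fixed=520, variable=384),
    "acoustic": so.MethodCost(fixed=883.20, variable=1062),
})
ocfg = so.OptimizerConfig(runs=1000, seed=1)
res = so.optim_alpha_exhaustive(survey.samples, survey.tree, costs, ocfg)
print(res.to_frame().head(8).to_string(index=False))
best = res.best(budget=4000)
print("best under $4000:", best.combination, round(best.value, 3))
```

prints

```
  cost  acoustic  mist_nets  proportion  se
   0.0         0          0    0.000000 0.0
 904.0         0          1    0.678440 0.0
1288.0         0          2    0.800559 0.0
1672.0         0          3    0.833656 0.0
1945.2         1          0    0.573156 0.0
2056.0         0          4    0.840418 0.0
2440.0         0          5    0.840418 0.0
2824.0         0          6    0.840418 0.0
best under $4000: 1xacoustic+3xmist_nets 0.943
```

Each row is the best allocation at one cost level: a single mist-net site
costs 904 (520 fixed + 384) and already captures 68% of the pooled
phylogenetic diversity, mist nets alone saturate at 84% (they never
detect species 13–16), and the cheapest way past that plateau is adding
one acoustic site — 3 mist-net + 1 acoustic samples capture 94.3% of the
diversity for under $4000. Standard errors are zero here because the
sample pools are small enough for exact subset enumeration. The same
survey optimized for monitoring (`so.optim_beta`) scores allocations by
`1 − bias` against the true β-diversity matrices, and
`so.random_protocol_envelope` gives the 95% band of unplanned method
choices to judge the optimized curve against.

The same machinery runs from the shell on CSV/Newick/YAML inputs:

```bash
surveyopt simulate --seed 11 --out-dir survey/
surveyopt optim-alpha --samples survey/samples_long.csv \
    --tree survey/phylogeny.nwk --costs costs.yaml \
    --runs 1000 --seed 1 --out-dir results/
surveyopt report PD=results/optim_alpha_curve.csv --budget 4000
```

Every run writes a `manifest.json` (input hashes, configuration, seed,
version) so any published protocol can be reproduced exactly.

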