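"""Cost-aware optimization of multi-method sampling protocols.

Given (near-)complete multi-method survey data for one or more sites, a
tree carrying the diversity currency (taxonomic, phylogenetic or
functional), and a per-method cost model, find the allocation of sample
units per method that

* **inventorying (alpha-sampling)** — maximizes the expected proportion of
  each site's true diversity captured, per unit cost; or
* **monitoring (beta-sampling)** — minimizes the expected bias between
  sampled and true partitioned beta diversity across sites, reported as
  efficiency ``1 - bias``.

"True" diversity is the diversity of the full pooled data per site; the
proportion captured by a candidate allocation is estimated by repeatedly
re-sampling the data without replacement (Monte Carlo, at least 1000
repetitions recommended) or, for small pools, by exact enumeration of
all sample subsets.  Per-site proportions are standardized to [0, 1]
before averaging so every site weighs equally.

Two search strategies are provided: exhaustive enumeration of all
allocations (keeping, per cost level, the one with least bias) and a
nested greedy that adds, at each step, one sample of the method with the
highest expected gain per cost unit, yielding a nested sequence of
protocols usable at any budget.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .costs import Combination, CostModel, combination_cost
from .diversity import BetaTriple, Community, TreeIndex

__all__ = [
    "SampleMatrix",
    "OptimizerConfig",
    "OptEntry",
    "OptResult",
    "EnumerationCapError",
    "true_alpha",
    "expected_alpha_proportion",
    "optim_alpha_exhaustive",
    "optim_alpha_nested",
    "beta_bias",
    "optim_beta",
]

LONG_COLUMNS = ["sample_id", "site", "method", "species", "abundance"]


class EnumerationCapError(RuntimeError):
    """Raised when exhaustive enumeration would exceed the configured cap."""


class SampleMatrix:
    """Samples x species abundances, each sample tagged (method, site).

    Wraps a long-format DataFrame with columns ``sample_id, site, method,
    species, abundance``.  Abundances are collapsed to incidence before
    any diversity computation; rows with abundance 0 register the sample
    (useful for empty samples) without recording the species.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in LONG_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"sample matrix missing columns {missing}")
        frame = frame[LONG_COLUMNS].copy()
        for col in ("sample_id", "site", "method", "species"):
            if frame[col].isna().any() or (frame[col].astype(str) == "").any():
                raise ValueError(f"missing values in column {col!r}")
            frame[col] = frame[col].astype(str)
        ab = pd.to_numeric(frame["abundance"])
        if (ab < 0).any():
            raise ValueError("negative abundance")
        if not np.allclose(ab, np.round(ab)):
            raise ValueError("abundances must be integer counts")
        frame["abundance"] = ab.astype(int)
        if frame.duplicated(["sample_id", "species"]).any():
            raise ValueError("duplicate (sample_id, species) rows")
        tags = frame.groupby("sample_id")[["site", "method"]].nunique()
        if (tags > 1).any().any():
            raise ValueError("a sample_id maps to more than one site or method")
        self.frame = frame.sort_values(LONG_COLUMNS[:4], kind="mergesort").reset_index(drop=True)

        self.sites: list[str] = sorted(frame["site"].unique())
        self.methods: list[str] = sorted(frame["method"].unique())
        self.species: list[str] = sorted(frame.loc[frame["abundance"] > 0, "species"].unique())
        # (site, method) -> ordered list of per-sample species sets
        self._samples: dict[tuple[str, str], list[frozenset]] = {
            (s, m): [] for s in self.sites for m in self.methods
        }
        present = frame[frame["abundance"] > 0]
        sp_by_sample = present.groupby("sample_id")["species"].agg(frozenset)
        meta = frame[["sample_id", "site", "method"]].drop_duplicates().sort_values("sample_id")
        for sid, site, method in meta.itertuples(index=False):
            self._samples[(site, method)].append(sp_by_sample.get(sid, frozenset()))

    def n_samples(self, site: str, method: str) -> int:
        return len(self._samples[(site, method)])

    def sample_species(self, site: str, method: str) -> list[frozenset]:
        return list(self._samples[(site, method)])

    def pooled_community(self, site: str) -> Community:
        if site not in self.sites:
            raise KeyError(f"unknown site {site!r}")
        sp = self.frame[(self.frame["site"] == site) & (self.frame["abundance"] > 0)]["species"]
        return Community(sp, label=site)

    def max_combination(self) -> Combination:
        """Largest allocation feasible at every site simultaneously."""
        return Combination(
            {m: min(self.n_samples(s, m) for s in self.sites) for m in self.methods}
        )

    def __repr__(self) -> str:
        n = self.frame["sample_id"].nunique()
        return (
            f"<SampleMatrix: {n} samples, {len(self.sites)} sites, "
            f"{len(self.methods)} methods, {len(self.species)} species>"
        )


@dataclass(frozen=True)
class OptimizerConfig:
    """Monte-Carlo and enumeration settings.

    runs:
        Monte-Carlo repetitions per candidate allocation (>= 1000
        recommended for final analyses; fewer for exploratory runs).
    seed:
        Master seed. Random subsampling streams are derived per
        (site, method, run), so every allocation sees the same draws
        (common random numbers) and results are bit-reproducible.
    enumeration_cap:
        Maximum number of allocations an exhaustive search may enumerate.
    exact_threshold:
        When the number of distinct sample subsets is at most this, the
        expectation is computed by exact enumeration instead of Monte
        Carlo (standard error 0).
    """

    runs: int = 1000
    seed: int = 0
    enumeration_cap: int = 10**6
    exact_threshold: int = 1000

    def __post_init__(self):
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass(frozen=True)
class OptEntry:
    cost: float
    combination: Combination
    value: float
    se: float
    method_added: Optional[str] = None  # nested runs only


@dataclass
class OptResult:
    """Optimization output: per cost level, the best allocation found.

    For exhaustive runs, ``entries`` holds the per-cost winners and
    ``evaluated`` every allocation scored (the full point cloud of the
    cost / diversity trade-off).  For nested runs, ``entries`` is the
    greedy accumulation sequence.  ``value`` is the expected proportion
    of diversity (alpha) or the efficiency ``1 - bias`` (beta).
    """

    kind: str  # "alpha" | "beta"
    mode: str  # "exhaustive" | "nested"
    methods: list[str]
    entries: list[OptEntry]
    evaluated: Optional[pd.DataFrame] = None

    @property
    def value_name(self) -> str:
        return "proportion" if self.kind == "alpha" else "efficiency"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"cost": e.cost}
            row.update({m: e.combination[m] for m in self.methods})
            row[self.value_name] = e.value
            row["se"] = e.se
            if self.mode == "nested":
                row["method_added"] = e.method_added
            rows.append(row)
        return pd.DataFrame(rows)

    def best(self, budget: Optional[float] = None) -> OptEntry:
        """Highest-value entry with cost <= budget (ties -> cheaper)."""
        pool = [e for e in self.entries if budget is None or e.cost <= budget]
        if not pool:
            raise ValueError("no entry within budget")
        return max(pool, key=lambda e: (e.value, -e.cost))


# ---------------------------------------------------------------------------
# sampling engine


def _check_feasible(comb: Combination, data: SampleMatrix) -> None:
    for m in comb.counts:
        if m not in data.methods:
            raise KeyError(f"method {m!r} not present in data")
    for site in data.sites:
        for m, n in comb.counts.items():
            avail = data.n_samples(site, m)
            if n > avail:
                raise ValueError(
                    f"combination requests {n} samples of {m!r} at site {site!r}, "
                    f"only {avail} available"
                )


class _Engine:
    """Shared machinery: per-sample edge masks and common-random-number
    permutation streams for subsampling without replacement."""

    def __init__(self, data: SampleMatrix, tree: TreeNode, cfg: OptimizerConfig):
        self.data = data
        self.cfg = cfg
        self.idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
        # per (site, method): (n_samples, n_edges) boolean edge incidence
        self.sample_edges: dict[tuple[str, str], np.ndarray] = {}
        for site in data.sites:
            for method in data.methods:
                samples = data.sample_species(site, method)
                mat = np.zeros((len(samples), self.idx.lengths.size), dtype=bool)
                for i, sp in enumerate(samples):
                    mat[i] = self.idx.edge_mask(self.idx.species_mask(sp))
                self.sample_edges[(site, method)] = mat
        self._perms: dict[tuple[str, str], np.ndarray] = {}

    def perms(self, site: str, method: str) -> np.ndarray:
        """(runs, pool) permutation array; run r's draw of n samples is the
        first n entries of row r.  Streams depend only on (seed, site,
        method), never on the allocation being scored."""
        key = (site, method)
        if key not in self._perms:
            ss = np.random.SeedSequence(
                [self.cfg.seed, 7919, self.data.sites.index(site), self.data.methods.index(method)]
            )
            rng = np.random.default_rng(ss)
            pool = self.data.n_samples(site, method)
            self._perms[key] = np.argsort(rng.random((self.cfg.runs, pool)), axis=1)
        return self._perms[key]

    def site_union_runs(self, site: str, comb: Combination) -> np.ndarray:
        """(runs, n_edges) boolean: edges covered by each run's draw."""
        out = np.zeros((self.cfg.runs, self.idx.lengths.size), dtype=bool)
        for method, n in comb.counts.items():
            if n == 0:
                continue
            sel = self.perms(site, method)[:, :n]  # (runs, n)
            out |= self.sample_edges[(site, method)][sel].any(axis=1)
        return out

    def site_subset_count(self, site: str, comb: Combination) -> int:
        return math.prod(
            math.comb(self.data.n_samples(site, m), n) for m, n in comb.counts.items()
        )

    def site_unions_exact(self, site: str, comb: Combination) -> np.ndarray:
        """(n_subsets, n_edges) boolean union mask for every distinct subset."""
        per_method = []
        for method, n in comb.counts.items():
            mat = self.sample_edges[(site, method)]
            subs = [
                mat[list(rows)].any(axis=0) if rows else np.zeros(mat.shape[1], dtype=bool)
                for rows in itertools.combinations(range(mat.shape[0]), n)
            ]
            per_method.append(subs)
        unions = []
        for parts in itertools.product(*per_method):
            u = np.zeros(self.idx.lengths.size, dtype=bool)
            for p in parts:
                u |= p
            unions.append(u)
        return np.array(unions) if unions else np.zeros((1, self.idx.lengths.size), dtype=bool)


class _AlphaEngine(_Engine):
    def __init__(self, data, tree, cfg):
        super().__init__(data, tree, cfg)
        self.true = {}
        for site in data.sites:
            t = self.idx.alpha_from_mask(self.idx.species_mask(data.pooled_community(site).species))
            if t <= 0:
                raise ValueError(f"site {site!r} has zero pooled diversity")
            self.true[site] = t

    def use_exact(self, comb: Combination) -> bool:
        return all(
            self.site_subset_count(site, comb) <= self.cfg.exact_threshold
            for site in self.data.sites
        )

    def score(self, comb: Combination) -> tuple[float, float]:
        """(expected proportion of true diversity, Monte-Carlo SE)."""
        _check_feasible(comb, self.data)
        if self.use_exact(comb):
            # per-site independence: the expectation factorizes over sites
            props = [
                (self.site_unions_exact(site, comb) @ self.idx.lengths).mean() / self.true[site]
                for site in self.data.sites
            ]
            return float(np.mean(props)), 0.0
        per_run = np.zeros(self.cfg.runs)
        for site in self.data.sites:
            alphas = self.site_union_runs(site, comb) @ self.idx.lengths
            per_run += alphas / self.true[site]
        per_run /= len(self.data.sites)
        return float(per_run.mean()), float(per_run.std(ddof=1) / math.sqrt(self.cfg.runs))


class _BetaEngine(_Engine):
    def __init__(self, data, tree, cfg):
        if len(data.sites) < 2:
            raise ValueError("beta-sampling needs at least 2 sites")
        super().__init__(data, tree, cfg)
        pooled = [
            self.idx.edge_mask(self.idx.species_mask(data.pooled_community(s).species))
            for s in data.sites
        ]
        self.true_triples = self._pair_triples(pooled)

    def _pair_triples(self, edge_masks: Sequence[np.ndarray]) -> np.ndarray:
        """(n_pairs, 3) array of (total, repl, rich) over site pairs i<j."""
        L = self.idx.lengths
        rows = []
        for e1, e2 in itertools.combinations(edge_masks, 2):
            a = L @ (e1 & e2)
            b = L @ (e1 & ~e2)
            c = L @ (e2 & ~e1)
            denom = a + b + c
            if denom == 0:
                rows.append((0.0, 0.0, 0.0))
            else:
                rows.append(((b + c) / denom, 2 * min(b, c) / denom, abs(b - c) / denom))
        return np.array(rows)

    def _bias_of(self, edge_masks: Sequence[np.ndarray]) -> float:
        """Mean over the three beta components of the mean absolute
        deviation from the true values over site pairs."""
        return float(np.abs(self._pair_triples(edge_masks) - self.true_triples).mean())

    def use_exact(self, comb: Combination) -> bool:
        total = math.prod(self.site_subset_count(s, comb) for s in self.data.sites)
        return total <= self.cfg.exact_threshold

    def score(self, comb: Combination) -> tuple[float, float]:
        """(bias, Monte-Carlo SE of the bias)."""
        _check_feasible(comb, self.data)
        if self.use_exact(comb):
            per_site = [
                list(self.site_unions_exact(site, comb)) for site in self.data.sites
            ]
            biases = [self._bias_of(masks) for masks in itertools.product(*per_site)]
            return float(np.mean(biases)), 0.0
        unions = [self.site_union_runs(site, comb) for site in self.data.sites]
        biases = np.array(
            [self._bias_of([u[r] for u in unions]) for r in range(self.cfg.runs)]
        )
        return float(biases.mean()), float(biases.std(ddof=1) / math.sqrt(self.cfg.runs))


# ---------------------------------------------------------------------------
# public operations


def true_alpha(data: SampleMatrix, site: str, tree) -> float:
    """Diversity of the complete pooled inventory at a site — the
    denominator against which sampled diversity is standardized."""
    from .diversity import alpha

    return alpha(data.pooled_community(site), tree)


def expected_alpha_proportion(
    comb: Combination, data: SampleMatrix, tree, cfg: OptimizerConfig
) -> float:
    """Expected proportion of true diversity captured by an allocation,
    averaged over Monte-Carlo subsampling runs and then over sites."""
    return _AlphaEngine(data, tree, cfg).score(comb)[0]


def beta_bias(comb: Combination, data: SampleMatrix, tree, cfg: OptimizerConfig) -> float:
    """Expected absolute deviation of sampled from true partitioned beta
    diversity, averaged over the three components (total, replacement,
    richness difference) and over site pairs.  Efficiency is 1 - bias."""
    return _BetaEngine(data, tree, cfg).score(comb)[0]


def _enumerate_combinations(
    data: SampleMatrix, cfg: OptimizerConfig, pool: Combination
) -> list[Combination]:
    maxc = data.max_combination()
    ranges = []
    for m in data.methods:
        lo = pool[m]
        hi = maxc[m]
        if lo > hi:
            raise ValueError(f"pool requests more {m!r} samples than available everywhere")
        ranges.append(range(lo, hi + 1))
    n_comb = math.prod(len(r) for r in ranges)
    if n_comb > cfg.enumeration_cap:
        raise EnumerationCapError(
            f"{n_comb} combinations exceed the enumeration cap "
            f"({cfg.enumeration_cap}); use the nested (greedy) optimizer"
        )
    return [
        Combination(dict(zip(data.methods, counts)))
        for counts in itertools.product(*ranges)
    ]


def _exhaustive(engine, data, cost_model, cfg, pool, kind) -> OptResult:
    pool = pool or Combination({})
    combos = _enumerate_combinations(data, cfg, pool)
    rows = []
    for comb in combos:
        cost = combination_cost(comb, cost_model)
        raw, se = engine.score(comb)
        value = raw if kind == "alpha" else 1.0 - raw
        rows.append((cost, comb, value, se))
    evaluated = pd.DataFrame(
        [
            {"cost": cost, **{m: comb[m] for m in data.methods}, "value": value, "se": se}
            for cost, comb, value, se in rows
        ]
    )
    best: dict[float, tuple] = {}
    for cost, comb, value, se in rows:
        cur = best.get(cost)
        cand_key = (-value, comb.key(data.methods))
        if cur is None or cand_key < cur[0]:
            best[cost] = (cand_key, OptEntry(cost, comb, value, se))
    entries = [best[c][1] for c in sorted(best)]
    return OptResult(kind=kind, mode="exhaustive", methods=data.methods, entries=entries, evaluated=evaluated)


def _nested(engine, data, cost_model, cfg, pool, steps, kind) -> OptResult:
    current = pool or Combination({})
    maxc = data.max_combination()
    _check_feasible(current, data)
    raw, se = engine.score(current)
    value = raw if kind == "alpha" else 1.0 - raw
    entries = [OptEntry(combination_cost(current, cost_model), current, value, se)]
    remaining = sum(maxc[m] - current[m] for m in data.methods)
    if steps is None:
        steps = remaining
    if steps > remaining:
        raise ValueError(f"steps={steps} exceeds the {remaining} remaining samples")
    cur_cost = combination_cost(current, cost_model)
    cur_value = value
    for _ in range(steps):
        candidates = [m for m in data.methods if current[m] < maxc[m]]
        if not candidates:
            warnings.warn("no samples remain; nested sequence stopped early")
            break
        scored = []
        for m in candidates:
            cand = current.add(m)
            raw, se = engine.score(cand)
            v = raw if kind == "alpha" else 1.0 - raw
            dcost = combination_cost(cand, cost_model) - cur_cost
            if dcost > 0:
                gain = (v - cur_value) / dcost
            else:  # free sample: take any improvement first
                gain = math.inf if v > cur_value else 0.0
            scored.append((gain, -dcost, m, cand, v, se))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        _, neg_dcost, m, cand, v, se = scored[0]
        current = cand
        cur_cost -= neg_dcost
        cur_value = v
        entries.append(OptEntry(cur_cost, current, v, se, method_added=m))
    return OptResult(kind=kind, mode="nested", methods=data.methods, entries=entries)


def optim_alpha_exhaustive(
    data: SampleMatrix,
    tree,
    cost_model: CostModel,
    cfg: OptimizerConfig,
    pool: Optional[Combination] = None,
) -> OptResult:
    """Enumerate all allocations containing ``pool``; per cost value,
    return the allocation with the highest expected diversity proportion
    (equivalently, the least bias)."""
    return _exhaustive(_AlphaEngine(data, tree, cfg), data, cost_model, cfg, pool, "alpha")


def optim_alpha_nested(
    data: SampleMatrix,
    tree,
    cost_model: CostModel,
    cfg: OptimizerConfig,
    pool: Optional[Combination] = None,
    steps: Optional[int] = None,
) -> OptResult:
    """Greedy nested sequence: at each step add one sample of the method
    with the steepest accumulation-curve slope (gain per cost unit)."""
    return _nested(_AlphaEngine(data, tree, cfg), data, cost_model, cfg, pool, steps, "alpha")


def random_protocol_envelope(
    data: SampleMatrix,
    tree,
    cost_model: CostModel,
    cfg: OptimizerConfig,
    kind: str = "alpha",
    n_random: int = 100,
    quantiles: tuple[float, float, float] = (0.025, 0.5, 0.975),
) -> pd.DataFrame:
    """Score of a *random* choice of methods at each effort level.

    At each total sample count, ``n_random`` protocols are drawn by
    assigning each sample unit to a uniformly random method with
    remaining capacity, and scored like any candidate allocation.  The
    returned quantiles (default 2.5%, median, 97.5%) form the envelope an
    optimized protocol should be judged against: an accumulation curve
    near or above the upper band indicates genuine gains over unplanned
    sampling.
    """
    if kind == "alpha":
        engine: _Engine = _AlphaEngine(data, tree, cfg)
    elif kind == "beta":
        engine = _BetaEngine(data, tree, cfg)
    else:
        raise ValueError("kind must be 'alpha' or 'beta'")
    maxc = data.max_combination()
    total_max = sum(maxc[m] for m in data.methods)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 15485863]))
    lo_q, mid_q, hi_q = quantiles
    rows = []
    cache: dict[tuple, float] = {}
    for effort in range(total_max + 1):
        values = []
        for _ in range(n_random):
            counts = {m: 0 for m in data.methods}
            for _unit in range(effort):
                open_methods = [m for m in data.methods if counts[m] < maxc[m]]
                counts[open_methods[rng.integers(len(open_methods))]] += 1
            comb = Combination(counts)
            key = comb.key(data.methods)
            if key not in cache:
                raw, _ = engine.score(comb)
                cache[key] = raw if kind == "alpha" else 1.0 - raw
            values.append(cache[key])
        rows.append(
            {
                "effort": effort,
                "lower": float(np.quantile(values, lo_q)),
                "median": float(np.quantile(values, mid_q)),
                "upper": float(np.quantile(values, hi_q)),
            }
        )
    return pd.DataFrame(rows)


def optim_beta(
    data: SampleMatrix,
    tree,
    cost_model: CostModel,
    cfg: OptimizerConfig,
    pool: Optional[Combination] = None,
    mode: str = "exhaustive",
    steps: Optional[int] = None,
) -> OptResult:
    """Optimize a monitoring protocol: the same machinery as the alpha
    search, scored by efficiency ``1 - beta bias``."""
    engine = _BetaEngine(data, tree, cfg)
    if mode == "exhaustive":
        return _exhaustive(engine, data, cost_model, cfg, pool, "beta")
    if mode == "nested":
        return _nested(engine, data, cost_model, cfg, pool, steps, "beta")
    raise ValueError("mode must be 'exhaustive' or 'nested'")
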