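"""Synthetic multi-method survey generator.

Emulates the structure that makes protocol optimization non-trivial in
real surveys: several sampling methods, each biased toward a different
subset of the assemblage (e.g. mist nets catching phyllostomids while
acoustic recorders pick up aerial insectivores), uneven species
abundances, and compositional turnover between sites.  Every generated
object (sample matrix, phylogeny, trait table, taxonomy) shares one
species set, so all downstream stages can be exercised end to end with
no external data.

The recording mechanism per sample is: species ``s`` (if in the site's
pool) is detected by method ``m`` with probability ``detect[m][s]``; when
detected, its recorded count is drawn from a zero-truncated Poisson with
the species' latent abundance as mean.  The detection probability is
thus exactly the per-sample recording rate, and abundances only shape
the counts (diversity itself is incidence-based).
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Union

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from skbio import TreeNode

from .costs import Combination
from .optimizer import SampleMatrix
from .traits import TraitTable
from .trees import read_newick, star_tree, validate_tree

__all__ = ["SimConfig", "SurveyData", "simulate_survey", "planted_optimum_scenario"]

Detection = Union[float, Mapping[str, float], np.ndarray]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated multi-method survey.

    n_species, n_sites:
        Size of the regional species pool and number of surveyed sites.
    detection:
        Per method: a scalar probability applied to every species, a
        mapping species -> probability, or an array aligned to the sorted
        species labels.  Method bias is expressed here (e.g. one method
        detecting only one clade).
    samples_per_site:
        Sample units collected per (site, method).
    abundance_mean_log, abundance_sd_log:
        Lognormal latent-abundance parameters on the natural-log scale.
        Defaults give a realistic right-skewed abundance distribution
        (median ~7 individuals per sample-scale unit, ~30-fold spread).
    turnover:
        In [0, 1]: probability that a species is a site specialist found
        at exactly one (random) site rather than shared by all sites.
        0 -> all sites share the full pool; 1 -> disjoint site pools.
    seed:
        Master seed; identical configs give identical surveys.
    tree:
        Optional Newick string for the phylogeny; by default a Yule
        (pure-birth) tree with ``n_species`` tips is simulated.
    """

    n_species: int = 24
    n_sites: int = 3
    detection: Mapping[str, Detection] = field(
        default_factory=lambda: {"method_a": 0.5, "method_b": 0.5}
    )
    samples_per_site: int = 8
    abundance_mean_log: float = 2.0
    abundance_sd_log: float = 1.2
    turnover: float = 0.2
    seed: int = 0
    tree: Optional[str] = None

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not 0.0 <= self.turnover <= 1.0:
            raise ValueError("turnover must be in [0, 1]")
        if not self.detection:
            raise ValueError("at least one method required")

    def species_labels(self) -> list[str]:
        width = len(str(self.n_species))
        return [f"sp{str(i + 1).zfill(width)}" for i in range(self.n_species)]

    def detection_matrix(self) -> pd.DataFrame:
        """(method x species) detection probabilities, validated."""
        species = self.species_labels()
        rows = {}
        for method, det in self.detection.items():
            if isinstance(det, Mapping):
                probs = np.array([float(det.get(s, 0.0)) for s in species])
            else:
                probs = np.broadcast_to(np.asarray(det, dtype=float), (len(species),)).copy()
            if (probs < 0).any() or (probs > 1).any():
                raise ValueError(f"detection probabilities for {method!r} outside [0, 1]")
            rows[method] = probs
        mat = pd.DataFrame(rows, index=species).T
        if not (mat.to_numpy() > 0).any():
            raise ValueError("zero detection everywhere: no species can ever be recorded")
        return mat


class SurveyData(NamedTuple):
    samples: SampleMatrix
    tree: TreeNode
    traits: TraitTable
    taxonomy: pd.DataFrame


def _yule_tree(species: list[str], seed: int) -> TreeNode:
    t = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=len(species),
        rng=_random.Random(seed),
    )
    for tip, name in zip(sorted(t.leaf_node_iter(), key=lambda n: n.taxon.label), species):
        tip.taxon.label = name
    newick = t.as_string(schema="newick", suppress_rooting=True)
    tree = TreeNode.read([newick])
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return validate_tree(tree)


def _zero_truncated_poisson(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Sample from Poisson(lam) conditioned on being >= 1 (inverse CDF on
    the truncated distribution; exact for any lam > 0)."""
    lam = np.asarray(lam, dtype=float)
    out = np.empty(lam.shape, dtype=int)
    # for means this large the zero class is numerically empty
    big = lam > 30.0
    if big.any():
        out[big] = np.maximum(rng.poisson(lam[big]), 1)
    small = ~big
    if small.any():
        lam_s = lam[small]
        u = rng.uniform(np.exp(-lam_s), 1.0)  # skip the zero class
        k = np.zeros(lam_s.shape, dtype=int)
        pmf = np.exp(-lam_s)
        cdf = pmf.copy()
        remaining = u > cdf
        while remaining.any():
            k[remaining] += 1
            pmf = pmf * lam_s / np.maximum(k, 1)
            cdf = cdf + pmf
            remaining = u > cdf
        out[small] = np.maximum(k, 1)
    return out


def _taxonomy(species: list[str], genus_size: int = 3, family_size: int = 3) -> pd.DataFrame:
    rows = []
    for i, sp in enumerate(species):
        g = i // genus_size
        f = g // family_size
        rows.append({"species": sp, "genus": f"gen{g + 1:02d}", "family": f"fam{f + 1:02d}"})
    return pd.DataFrame(rows)


def _traits(species: list[str], rng: np.random.Generator) -> TraitTable:
    n = len(species)
    size = rng.lognormal(1.0, 0.5, n)
    appendage = 0.4 * size + rng.normal(0.0, 0.2, n)  # size-correlated
    df = pd.DataFrame(
        {
            "body_size": size,
            "appendage_length": appendage,
            "nocturnal": rng.integers(0, 2, n),
            "guild": rng.choice(["herbivore", "predator", "omnivore"], n),
        },
        index=pd.Index(species, name="species"),
    )
    kinds = {
        "body_size": "numeric",
        "appendage_length": "numeric",
        "nocturnal": "binary",
        "guild": "categorical",
    }
    return TraitTable(df, kinds)


def simulate_survey(cfg: SimConfig) -> SurveyData:
    """Generate a label-consistent (samples, phylogeny, traits, taxonomy)
    bundle from a :class:`SimConfig`. Deterministic given the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 104729]))
    species = cfg.species_labels()
    detect = cfg.detection_matrix()
    methods = list(detect.index)

    tree = (
        read_newick(cfg.tree)
        if cfg.tree is not None
        else _yule_tree(species, int(rng.integers(2**31)))
    )
    if cfg.tree is not None and sorted(t.name for t in tree.tips()) != species:
        raise ValueError("supplied tree tips do not match the species labels")

    abundance = rng.lognormal(cfg.abundance_mean_log, cfg.abundance_sd_log, cfg.n_species)

    # site pools: each species is either shared by all sites or a
    # single-site specialist, with probability = turnover
    specialist = rng.random(cfg.n_species) < cfg.turnover
    home_site = rng.integers(0, cfg.n_sites, cfg.n_species)
    pools = np.ones((cfg.n_sites, cfg.n_species), dtype=bool)
    for s in np.flatnonzero(specialist):
        pools[:, s] = False
        pools[home_site[s], s] = True

    rows = []
    sample_no = 0
    for site_i in range(cfg.n_sites):
        site = f"site{site_i + 1:02d}"
        for method in methods:
            probs = detect.loc[method].to_numpy()
            for _ in range(cfg.samples_per_site):
                sample_no += 1
                sid = f"s{sample_no:05d}"
                detected = (rng.random(cfg.n_species) < probs) & pools[site_i]
                idx = np.flatnonzero(detected)
                if idx.size:
                    counts = _zero_truncated_poisson(rng, abundance[idx])
                    for j, c in zip(idx, counts):
                        rows.append((sid, site, method, species[j], int(c)))
                else:  # register the (empty) sample
                    rows.append((sid, site, method, species[0], 0))
    frame = pd.DataFrame(rows, columns=["sample_id", "site", "method", "species", "abundance"])
    samples = SampleMatrix(frame)

    traits = _traits(species, np.random.default_rng(np.random.SeedSequence([cfg.seed, 1299709])))
    taxonomy = _taxonomy(species)
    return SurveyData(samples, tree, traits, taxonomy)


def planted_optimum_scenario(budget: int, seed: int) -> tuple[SimConfig, Combination]:
    """A two-method scenario whose alpha-optimal allocation is known.

    Method A detects (with probability ``p = 0.9`` per sample) only a
    clade carrying 3/4 of the tree's branch length; method B detects only
    the complementary clade (1/4 of the length).  Both methods cost the
    same per sample with no fixed cost, one site.  The expected captured
    proportion of an allocation (nA, nB) is

        [(1 - (1-p)^nA) * L_A + (1 - (1-p)^nB) * L_B] / (L_A + L_B)

    summed over species, which is maximized over nA + nB = budget by the
    allocation returned alongside the config.
    """
    if budget < 2:
        raise ValueError("budget must be >= 2")
    n_a, n_b = 6, 2
    width = len(str(n_a + n_b))
    species = [f"sp{str(i + 1).zfill(width)}" for i in range(n_a + n_b)]
    clade_a, clade_b = species[:n_a], species[n_a:]
    # star tree with clade A carrying total length 3 and clade B length 1,
    # so A holds 75% of the tree but a first sample of B still gains more
    # than a second sample of A
    newick = (
        "("
        + ",".join(f"{s}:{3.0 / n_a}" for s in clade_a)
        + ","
        + ",".join(f"{s}:{1.0 / n_b}" for s in clade_b)
        + ");"
    )
    p = 0.9
    cfg = SimConfig(
        n_species=len(species),
        n_sites=1,
        detection={
            "method_a": {s: p for s in clade_a},
            "method_b": {s: p for s in clade_b},
        },
        samples_per_site=budget,
        turnover=0.0,
        seed=seed,
        tree=newick,
    )
    len_a, len_b = 3.0, 1.0
    total = len_a + len_b

    def expected(na: int, nb: int) -> float:
        return ((1 - (1 - p) ** na) * len_a + (1 - (1 - p) ** nb) * len_b) / total

    best = max(
        ((na, budget - na) for na in range(budget + 1)),
        key=lambda ab: (expected(*ab), ab),
    )
    return cfg, Combination({"method_a": best[0], "method_b": best[1]})
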