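"""Alpha and partitioned beta diversity of communities measured on trees.

Diversity of an assemblage is the sum of branch lengths of the minimal
subtree connecting the root and all species present.  On a unit star tree
this is species richness (taxonomic diversity); on a phylogeny or a
functional tree it is phylogenetic / functional diversity.

Beta diversity between two assemblages is partitioned into species (or
branch) replacement and richness-difference components,

    beta_total = beta_repl + beta_rich,

with beta_total = (B + C) / (A + B + C), beta_repl = 2 min(B, C) / (A + B + C)
and beta_rich = |B - C| / (A + B + C), where A is the branch length shared
by both assemblages' subtrees and B, C the lengths unique to each.  On a
unit star tree beta_total reduces to the Jaccard dissimilarity of the two
species sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = ["Community", "BetaTriple", "TreeIndex", "alpha", "beta_pair", "beta_matrices"]


@dataclass(frozen=True)
class Community:
    """Incidence assemblage: the set of species present, optionally tagged
    with the site or sampling event it came from."""

    species: frozenset
    label: Optional[str] = None

    def __init__(self, species: Iterable[str], label: Optional[str] = None):
        object.__setattr__(self, "species", frozenset(species))
        object.__setattr__(self, "label", label)

    def __len__(self) -> int:
        return len(self.species)


class BetaTriple(NamedTuple):
    total: float
    repl: float
    rich: float


class TreeIndex:
    """Precomputed edge incidence of a tree for fast diversity sums.

    Maps each tip to the set of edges on its root path, as a boolean
    (edges x species) matrix; every alpha / beta evaluation is then a
    masked sum over edge lengths.  Build once per tree and reuse across
    the thousands of subsample evaluations an optimization performs.
    """

    def __init__(self, tree: TreeNode):
        self.tree = tree
        edges = [n for n in tree.traverse(include_self=False)]
        self.lengths = np.array([e.length or 0.0 for e in edges])
        tips = sorted(tree.tips(), key=lambda t: t.name)
        self.species = [t.name for t in tips]
        self._index = {name: i for i, name in enumerate(self.species)}
        edge_idx = {id(e): j for j, e in enumerate(edges)}
        self.incidence = np.zeros((len(edges), len(tips)), dtype=bool)
        for i, tip in enumerate(tips):
            node = tip
            while node.parent is not None:
                self.incidence[edge_idx[id(node)], i] = True
                node = node.parent
        self.total_length = float(self.lengths.sum())

    def species_mask(self, species: Iterable[str]) -> np.ndarray:
        mask = np.zeros(len(self.species), dtype=bool)
        for s in species:
            try:
                mask[self._index[s]] = True
            except KeyError:
                raise KeyError(f"species {s!r} is not a tip of the tree") from None
        return mask

    def edge_mask(self, species_mask: np.ndarray) -> np.ndarray:
        """Edges lying on a root-to-present-tip path."""
        return self.incidence[:, species_mask].any(axis=1)

    def alpha_from_mask(self, species_mask: np.ndarray) -> float:
        return float(self.lengths @ self.edge_mask(species_mask))

    def beta_from_masks(self, m1: np.ndarray, m2: np.ndarray) -> BetaTriple:
        e1 = self.edge_mask(m1)
        e2 = self.edge_mask(m2)
        a = float(self.lengths @ (e1 & e2))
        b = float(self.lengths @ (e1 & ~e2))
        c = float(self.lengths @ (e2 & ~e1))
        denom = a + b + c
        if denom == 0.0:
            return BetaTriple(0.0, 0.0, 0.0)
        return BetaTriple((b + c) / denom, 2.0 * min(b, c) / denom, abs(b - c) / denom)


def _as_index(tree) -> TreeIndex:
    return tree if isinstance(tree, TreeIndex) else TreeIndex(tree)


def alpha(community: Community, tree) -> float:
    """Branch-length diversity of a community on a tree.

    Sum of branch lengths of the minimal subtree connecting the root and
    all present tips (root path included, so a single species on a unit
    star tree scores 1). Empty community -> 0.
    """
    idx = _as_index(tree)
    return idx.alpha_from_mask(idx.species_mask(community.species))


def beta_pair(c1: Community, c2: Community, tree) -> BetaTriple:
    """Partitioned beta diversity between two communities on a tree."""
    idx = _as_index(tree)
    return idx.beta_from_masks(idx.species_mask(c1.species), idx.species_mask(c2.species))


class BetaMatrices(NamedTuple):
    total: pd.DataFrame
    repl: pd.DataFrame
    rich: pd.DataFrame


def beta_matrices(communities: Sequence[Community], tree) -> BetaMatrices:
    """Pairwise beta partitions across a set of communities.

    Returns three symmetric zero-diagonal matrices (total, replacement,
    richness difference), labelled by community label or position.
    """
    if len(communities) < 2:
        raise ValueError("need at least 2 communities")
    idx = _as_index(tree)
    labels = [c.label if c.label is not None else str(i) for i, c in enumerate(communities)]
    masks = [idx.species_mask(c.species) for c in communities]
    n = len(communities)
    out = np.zeros((3, n, n))
    for i in range(n):
        for j in range(i + 1, n):
            t = idx.beta_from_masks(masks[i], masks[j])
            out[:, i, j] = out[:, j, i] = t
    return BetaMatrices(*(pd.DataFrame(m, index=labels, columns=labels) for m in out))
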