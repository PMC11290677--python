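"""Tree construction and utilities.

Trees are the common currency for all three diversity dimensions:
taxonomic diversity uses a star tree (every species attached to the root
by a unit-length branch, so branch-length sums equal species richness),
phylogenetic diversity uses a dated or surrogate (Linnaean) phylogeny,
and functional diversity uses a neighbor-joining tree built from a trait
dissimilarity matrix.

Trees are represented as :class:`skbio.TreeNode`; distance matrices as
:class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

__all__ = [
    "TreeError",
    "star_tree",
    "linnaean_tree",
    "neighbor_joining",
    "total_length",
    "is_ultrametric",
    "read_newick",
    "write_newick",
    "validate_tree",
    "taxonomy_from_csv",
    "validate_taxonomy",
]


class TreeError(ValueError):
    """Raised for invalid trees, taxonomies or distance matrices."""


def validate_tree(tree: TreeNode) -> TreeNode:
    """Check tree invariants: unique non-empty tip labels, branch lengths >= 0.

    The root's own branch length is ignored (set to ``None``).
    Returns the tree for chaining.
    """
    tree.length = None
    labels = [tip.name for tip in tree.tips()]
    if not labels:
        raise TreeError("tree has no tips")
    if any(lab is None or lab == "" for lab in labels):
        raise TreeError("tree has unnamed tips")
    if len(set(labels)) != len(labels):
        raise TreeError("tip labels are not unique")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise TreeError(f"node {node.name!r} has no branch length")
        if node.length < 0:
            raise TreeError(f"negative branch length on node {node.name!r}")
    return tree


def star_tree(species: Sequence[str], branch_length: float = 1.0) -> TreeNode:
    """Star tree: each species attached directly to the root.

    With unit branch lengths, the branch-length diversity of a community
    equals its species richness, which is how taxonomic diversity is put
    on the same footing as phylogenetic and functional diversity.
    """
    species = list(species)
    if not species:
        raise TreeError("species list is empty")
    if len(set(species)) != len(species):
        raise TreeError("duplicate species labels")
    if branch_length <= 0:
        raise TreeError("branch_length must be positive")
    root = TreeNode()
    root.extend([TreeNode(name=s, length=float(branch_length)) for s in species])
    return validate_tree(root)


def validate_taxonomy(taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Validate a taxonomy table: finest rank (species) first, no missing
    cells, unique species, and consistent nesting (each taxon at rank k
    maps to exactly one taxon at rank k+1)."""
    if taxonomy.shape[1] < 2:
        raise TreeError("taxonomy needs at least a species column and one rank")
    if taxonomy.isna().any().any() or (taxonomy == "").any().any():
        raise TreeError("taxonomy has missing cells")
    species = taxonomy.iloc[:, 0]
    if species.duplicated().any():
        raise TreeError("duplicate species in taxonomy")
    cols = list(taxonomy.columns)
    for finer, coarser in zip(cols[:-1], cols[1:]):
        parents = taxonomy.groupby(finer, sort=False)[coarser].nunique()
        if (parents > 1).any():
            bad = parents[parents > 1].index[0]
            raise TreeError(
                f"inconsistent nesting: {finer} {bad!r} maps to multiple {coarser} taxa"
            )
    return taxonomy


def taxonomy_from_csv(path) -> pd.DataFrame:
    """Read a taxonomy table from CSV (header row; finest rank first)."""
    return validate_taxonomy(pd.read_csv(path, dtype=str))


def linnaean_tree(taxonomy: pd.DataFrame, depth: float = 1.0) -> TreeNode:
    """Ultrametric surrogate phylogeny from the Linnaean hierarchy.

    With ``r`` supra-specific ranks, each rank contributes an equal step of
    ``depth / r`` so every root-to-tip path has length ``depth``.  Taxa of
    the coarsest rank sit at the root level (zero-length stems when there
    is more than one), so two species sharing no rank are ``2 * depth``
    apart while congeners are ``2 * depth / r`` apart.
    """
    taxonomy = validate_taxonomy(taxonomy)
    if depth <= 0:
        raise TreeError("depth must be positive")
    ranks = list(taxonomy.columns)  # finest (species) first
    r = len(ranks) - 1
    step = depth / r

    root = TreeNode()
    # nodes[k] maps a taxon name at rank index k to its TreeNode
    nodes: dict[int, dict[str, TreeNode]] = {r: {}}
    for name in pd.unique(taxonomy[ranks[r]]):
        node = TreeNode(name=str(name), length=0.0)
        root.append(node)
        nodes[r][str(name)] = node
    for k in range(r - 1, -1, -1):
        nodes[k] = {}
        pairs = taxonomy[[ranks[k], ranks[k + 1]]].drop_duplicates()
        for name, parent in pairs.itertuples(index=False):
            node = TreeNode(name=str(name), length=step)
            nodes[k + 1][str(parent)].append(node)
            nodes[k][str(name)] = node
    return validate_tree(root)


def _two_taxon_tree(dm: DistanceMatrix) -> TreeNode:
    a, b = sorted(dm.ids)
    half = float(dm[a, b]) / 2.0
    root = TreeNode()
    root.extend([TreeNode(name=a, length=half), TreeNode(name=b, length=half)])
    return root


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining, midpoint-rooted.

    Labels are sorted before agglomeration so the result does not depend
    on input row order.  Negative branch-length estimates (possible for
    non-additive input) are clamped to zero with a warning, keeping all
    lengths usable as diversity increments.  Midpoint rooting is used
    because an unrooted tree has no defined branch-length sum from the
    root; it is deterministic and label-order independent.
    """
    if not isinstance(dm, DistanceMatrix):
        dm = DistanceMatrix(dm)  # validates symmetry / hollowness
    if len(dm.ids) < 2:
        raise TreeError("neighbor joining needs at least 2 taxa")
    order = sorted(dm.ids)
    dm = dm.filter(order)
    if len(order) == 2:
        return validate_tree(_two_taxon_tree(dm))
    unrooted = _skbio_nj(dm, neg_as_zero=False)
    clamped = False
    for node in unrooted.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn(
            "negative neighbor-joining branch lengths clamped to 0",
            stacklevel=2,
        )
    rooted = unrooted.root_at_midpoint()
    return validate_tree(rooted)


def total_length(tree: TreeNode) -> float:
    """Sum of all branch lengths (the tree-wide diversity ceiling)."""
    return float(
        sum(n.length or 0.0 for n in tree.traverse(include_self=False))
    )


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    """True iff all root-to-tip path lengths are equal within ``tol``."""
    depths = []
    for tip in tree.tips():
        d = 0.0
        node = tip
        while node.parent is not None:
            d += node.length or 0.0
            node = node.parent
        depths.append(d)
    return bool(max(depths) - min(depths) <= tol)


def read_newick(source) -> TreeNode:
    """Read and validate a Newick tree from a path or string."""
    if isinstance(source, str) and source.lstrip().startswith("("):
        tree = TreeNode.read([source])
    else:
        tree = TreeNode.read(str(source))
    return validate_tree(tree)


def write_newick(tree: TreeNode, path) -> None:
    """Write a tree as Newick with branch lengths."""
    tree.write(str(path))
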