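"""Functional-trait handling: weighted Gower dissimilarity and trait trees.

A functional tree is obtained by (1) optionally replacing size-correlated
morphometric variables by their residuals against a body-size proxy,
(2) computing a weighted Gower distance over mixed numeric / binary /
categorical traits, and (3) building a neighbor-joining tree from that
distance matrix, so functional diversity can be measured as a
branch-length sum exactly like phylogenetic diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix, TreeNode

from .trees import neighbor_joining

__all__ = ["TraitTable", "TraitError", "residualize", "gower_distance", "functional_tree"]

VALID_KINDS = ("numeric", "binary", "categorical")


class TraitError(ValueError):
    """Raised for invalid trait tables or degenerate inputs."""


@dataclass
class TraitTable:
    """Species x trait table with per-trait type and weight.

    Parameters
    ----------
    data:
        DataFrame indexed by species; one column per trait. Missing values
        (NaN / None) are allowed and handled by pairwise trait deletion.
    kinds:
        Mapping trait -> one of ``numeric``, ``binary``, ``categorical``.
        Traits absent from the mapping default to ``numeric`` for numeric
        dtypes and ``categorical`` otherwise.
    weights:
        Mapping trait -> non-negative weight; missing traits get weight 1.
        Weights only matter up to a common factor.
    """

    data: pd.DataFrame
    kinds: Mapping[str, str] = field(default_factory=dict)
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.data.index.duplicated().any():
            raise TraitError("duplicate species in trait table")
        kinds = {}
        for col in self.data.columns:
            kind = self.kinds.get(col)
            if kind is None:
                kind = "numeric" if pd.api.types.is_numeric_dtype(self.data[col]) else "categorical"
            if kind not in VALID_KINDS:
                raise TraitError(f"unknown trait kind {kind!r} for {col!r}")
            if kind == "numeric" and not pd.api.types.is_numeric_dtype(self.data[col]):
                raise TraitError(f"trait {col!r} declared numeric but is not")
            kinds[col] = kind
        self.kinds = kinds
        weights = {col: float(self.weights.get(col, 1.0)) for col in self.data.columns}
        if any(w < 0 for w in weights.values()):
            raise TraitError("negative trait weight")
        if not any(w > 0 for w in weights.values()):
            raise TraitError("all trait weights are zero")
        self.weights = weights

    @property
    def species(self) -> list[str]:
        return list(self.data.index.astype(str))

    @classmethod
    def from_csv(cls, path, config_path=None) -> "TraitTable":
        """Read a trait table from CSV (first column = species) with an
        optional YAML sidecar declaring each column's ``kind`` and ``weight``."""
        df = pd.read_csv(path, index_col=0)
        kinds: dict[str, str] = {}
        weights: dict[str, float] = {}
        if config_path is not None:
            with open(config_path) as fh:
                cfg = yaml.safe_load(fh) or {}
            for col, spec in cfg.get("traits", cfg).items():
                if "kind" in spec:
                    kinds[col] = spec["kind"]
                if "weight" in spec:
                    weights[col] = spec["weight"]
        return cls(df, kinds, weights)


def residualize(y: Sequence[float], x: Sequence[float]) -> np.ndarray:
    """Residuals of an ordinary least-squares fit of ``y`` on ``x``.

    Used to strip the body-size signal from size-correlated morphometric
    traits before computing functional distances (e.g. regressing each
    measurement on prosoma width in spiders). Residuals sum to zero.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise TraitError("x and y must be equal-length 1-d vectors")
    if y.size < 3:
        raise TraitError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise TraitError("x is constant; cannot residualize")
    slope, intercept = np.polyfit(x, y, 1)
    return y - (intercept + slope * x)


def gower_distance(traits: TraitTable) -> DistanceMatrix:
    """Weighted Gower distance over mixed trait types.

    Per pair (i, k): ``d = sum_j w_j * delta_j / sum_j w_j`` over the traits
    observed for both species.  Numeric ``delta`` is the absolute difference
    scaled by the trait's observed range over the whole table (so distances
    are stable under subsetting of pairs); binary and categorical ``delta``
    is 0 when equal, 1 otherwise.  Traits missing for either member of a
    pair are dropped and the weights renormalized for that pair.
    """
    df = traits.data
    n = len(df)
    if n < 2:
        raise TraitError("need at least 2 species")
    cols = list(df.columns)
    w = np.array([traits.weights[c] for c in cols])

    # per-trait (n, n) delta and comparability masks
    deltas = np.empty((len(cols), n, n))
    avail = np.empty((len(cols), n, n), dtype=bool)
    for j, col in enumerate(cols):
        vals = df[col]
        if traits.kinds[col] == "numeric":
            v = vals.to_numpy(dtype=float)
            ok = np.isfinite(v)
            rng = np.nanmax(v) - np.nanmin(v) if ok.any() else 0.0
            diff = np.abs(v[:, None] - v[None, :])
            deltas[j] = diff / rng if rng > 0 else 0.0
        else:
            v = vals.to_numpy(dtype=object)
            ok = np.array([x is not None and x == x for x in v])
            deltas[j] = (v[:, None] != v[None, :]).astype(float)
        avail[j] = ok[:, None] & ok[None, :]

    wj = w[:, None, None] * avail
    wsum = wj.sum(axis=0)
    if (wsum == 0).any():
        i, k = np.argwhere(wsum == 0)[0]
        raise TraitError(
            f"species pair ({df.index[i]!r}, {df.index[k]!r}) shares no comparable trait"
        )
    d = np.einsum("jik,jik->ik", wj, np.nan_to_num(deltas)) / wsum
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # remove float asymmetry
    return DistanceMatrix(d, ids=traits.species)


def functional_tree(traits: TraitTable) -> TreeNode:
    """Neighbor-joining tree on the weighted Gower distance matrix."""
    return neighbor_joining(gower_distance(traits))
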