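import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from surveyopt import Community, SampleMatrix
from surveyopt.datasets import amazonian_bat_costs, amazonian_bat_full_scheme


def random_binary_tree(rng: np.random.Generator, n_tips: int, lo=0.1, hi=1.0) -> TreeNode:
    """Random binary topology with strictly positive branch lengths."""
    nodes = [TreeNode(name=f"t{i + 1}", length=float(rng.uniform(lo, hi))) for i in range(n_tips)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(length=float(rng.uniform(lo, hi)))
        parent.extend([nodes[i], nodes[j]])
        nodes = [m for k, m in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    root.extend(nodes)
    return root


def random_community(rng: np.random.Generator, species, p=0.5) -> Community:
    return Community([s for s in species if rng.random() < p])


@pytest.fixture
def caterpillar():
    """((a:1,b:1):1,c:2); -- total length 5, ultrametric at depth 2."""
    return TreeNode.read(["((a:1,b:1):1,c:2);"])


@pytest.fixture
def bat_costs():
    return amazonian_bat_costs()


@pytest.fixture
def bat_full():
    return amazonian_bat_full_scheme()


def toy_samples(rows):
    """Build a SampleMatrix from (sample_id, site, method, species...) tuples."""
    records = []
    for sid, site, method, species in rows:
        if species:
            for sp in species:
                records.append((sid, site, method, sp, 1))
        else:
            records.append((sid, site, method, "zzz_placeholder", 0))
    return SampleMatrix(
        pd.DataFrame(records, columns=["sample_id", "site", "method", "species", "abundance"])
    )


@pytest.fixture
def two_method_survey():
    """One site, two methods with two samples each on species a-e."""
    return toy_samples(
        [
            ("s1", "site1", "A", ["a", "b"]),
            ("s2", "site1", "A", ["b", "c"]),
            ("s3", "site1", "B", ["d"]),
            ("s4", "site1", "B", ["d", "e"]),
        ]
    )
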