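"""Shared fixtures: small hand trees, random tree factory, synthetic datasets."""

import numpy as np
import pytest

from paleobrain.phylo_core import Phylogeny
from paleobrain.synthetic import SynthConfig, fixture_small, simulate_dataset


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    """((A:1,B:1):1,C:2); -- the standard worked example."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def six_tip_dataset():
    """Fixed hand-sized dataset with printed branch lengths and trait values."""
    return fixture_small()


@pytest.fixture(scope="session")
def default_dataset():
    """One study-shaped synthetic dataset under the default conditions."""
    return simulate_dataset(SynthConfig(seed=11))


def random_tree(
    rng: np.random.Generator,
    n_tips: int,
    height: float | None = None,
    ultrametric: bool = False,
) -> Phylogeny:
    """Random rooted binary tree built by coalescent-style pairwise merges.

    Tip ages are jittered unless ``ultrametric``; ``height`` rescales all
    branch lengths so the deepest root-to-tip path equals it.
    """
    labels = [f"t{i}" for i in range(n_tips)]
    heights = {
        i: 0.0 if ultrametric else float(rng.uniform(0.0, 0.3)) for i in range(n_tips)
    }
    parent: dict[int, int] = {}
    active = list(range(n_tips))
    next_id = n_tips
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        p = next_id
        next_id += 1
        heights[p] = max(heights[a], heights[b]) + float(rng.exponential(0.5)) + 0.05
        parent[a] = p
        parent[b] = p
        active = [x for x in active if x not in (a, b)] + [p]
    root = active[0]
    n_all = next_id
    par = np.full(n_all, -1, dtype=int)
    elen = np.zeros(n_all)
    for c, p in parent.items():
        par[c] = p
        elen[c] = heights[p] - heights[c]
    if height is not None:
        scale = height / heights[root]
        elen *= scale
        heights = {k: v * scale for k, v in heights.items()}
    return Phylogeny(
        labels=labels, parent=par, edge_length=elen, root_height=float(heights[root])
    )
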