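"""Stochastic time-calibration of a fixed topology from fossil age bins.

Fossil tip ages are known only to a stratigraphic interval (for North
American fossils, typically a NALMA bin).  Calibration draws each tip age
uniformly inside its first-appearance interval and then pushes every
internal node old enough to sit at least one minimum branch length (``mbl``)
above its oldest child.  Repeating the draw yields a set of calibrated
trees whose spread reflects the stratigraphic uncertainty; downstream
analyses consume the per-node mean-age average tree.

This is a deliberate simplification of likelihood-based time-scaling
(cal3-style methods that model branching, extinction and sampling rates):
the topology here is fixed, so all dating uncertainty lives in node ages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .phylo_core import Phylogeny, shared_path_matrix

AGE_BIN_COLUMNS = ["tip", "fad_early", "fad_late", "lad_early", "lad_late"]

#: Shared Pleistocene first-appearance interval applied to extant tips
#: (used for feasibility checks only; extant tip age is pinned at 0).
PLEISTOCENE_BIN = (2.58, 0.0117)


@dataclass
class AgeBinMatrix:
    """Per-tip stratigraphic interval bounds in Ma (early >= late)."""

    table: pd.DataFrame  # indexed by tip label, columns fad_early..lad_late

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AgeBinMatrix":
        df = frame.copy()
        if "tip" in df.columns:
            df = df.set_index("tip")
        missing = [c for c in AGE_BIN_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise ValidationError(f"age-bin table missing columns {missing}")
        df = df[AGE_BIN_COLUMNS[1:]].astype(float)
        if df.index.duplicated().any():
            raise ValidationError("duplicate tips in age-bin table")
        bad = df.index[(df.fad_early < df.fad_late) | (df.lad_early < df.lad_late)]
        if len(bad):
            raise ValidationError(f"early bound < late bound for tips {list(bad)}")
        bad = df.index[df.fad_late < df.lad_late]
        if len(bad):
            raise ValidationError(f"first appearance younger than last appearance for {list(bad)}")
        return cls(df)

    @classmethod
    def read_csv(cls, path) -> "AgeBinMatrix":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.rename_axis("tip").to_csv(path)

    def __contains__(self, tip: str) -> bool:
        return tip in self.table.index

    def fad_interval(self, tip: str) -> tuple[float, float]:
        row = self.table.loc[tip]
        return float(row.fad_early), float(row.fad_late)


def sample_calibrated_tree(
    topology: Phylogeny,
    ages: AgeBinMatrix,
    mbl: float = 0.1,
    seed: int = 0,
    node_incr: float = 2.0,
) -> Phylogeny:
    """Draw one calibrated tree: uniform tip ages + stochastic node dating.

    Tip age is sampled uniformly inside the first-appearance interval
    (an interval of [0, 0] pins the tip at the present).  Each internal
    node is then dated ``mbl`` plus an exponential waiting time (mean
    ``node_incr`` Myr) older than its oldest child.  This guarantees node
    ages strictly increase rootward and every edge is at least ``mbl``
    Myr, while avoiding the degenerate zero-length compression a pure
    minimum-branch-length rule produces in clades of extant tips.
    Deterministic for a fixed seed.
    """
    if mbl <= 0:
        raise ValidationError("mbl must be > 0")
    if node_incr < 0:
        raise ValidationError("node_incr must be >= 0")
    missing = [t for t in topology.labels if t not in ages]
    if missing:
        raise ValidationError(f"tips missing from age-bin matrix: {missing}")
    rng = np.random.default_rng(seed)
    n = topology.n_tips
    age = np.zeros(topology.n_nodes)
    for i, tip in enumerate(topology.labels):
        early, late = ages.fad_interval(tip)
        age[i] = rng.uniform(late, early) if early > late else early
    for node in topology.postorder:
        if node >= n:
            wait = rng.exponential(node_incr) if node_incr > 0 else 0.0
            age[node] = max(age[c] for c in topology.children[node]) + mbl + wait
    out = topology.copy()
    for node in topology.postorder[:-1]:
        out.edge_length[node] = age[topology.parent[node]] - age[node]
    out.root_height = float(age[topology.root])
    return Phylogeny(
        labels=out.labels,
        parent=out.parent,
        edge_length=out.edge_length,
        root_height=out.root_height,
    )


def calibration_seeds(master_seed: int, n_trees: int) -> list[int]:
    """Expand a master seed into per-tree seeds by a fixed counter scheme."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n_trees)]


def sample_calibrated_trees(
    topology: Phylogeny,
    ages: AgeBinMatrix,
    n_trees: int = 100,
    mbl: float = 0.1,
    master_seed: int = 0,
    node_incr: float = 2.0,
) -> list[Phylogeny]:
    seeds = calibration_seeds(master_seed, n_trees)
    return [
        sample_calibrated_tree(topology, ages, mbl=mbl, seed=s, node_incr=node_incr)
        for s in seeds
    ]


def _check_same_topology(trees: list[Phylogeny]) -> None:
    first = trees[0]
    for t in trees[1:]:
        if t.labels != first.labels or not np.array_equal(t.parent, first.parent):
            raise ValidationError("average_tree requires identical topologies")


def average_tree(trees: list[Phylogeny]) -> Phylogeny:
    """Per-node arithmetic mean of node ages on the shared topology."""
    if not trees:
        raise ValidationError("average_tree requires at least one tree")
    _check_same_topology(trees)
    mean_age = np.mean([t.node_ages() for t in trees], axis=0)
    out = trees[0].copy()
    for node in out.postorder[:-1]:
        out.edge_length[node] = mean_age[out.parent[node]] - mean_age[node]
    out.root_height = float(mean_age[out.root])
    return Phylogeny(
        labels=out.labels,
        parent=out.parent,
        edge_length=out.edge_length,
        root_height=out.root_height,
    )


def prune_tree(tree: Phylogeny, drop: list[str]) -> Phylogeny:
    """Remove tips, suppress resulting degree-2 nodes, preserve path lengths."""
    keep = [t for t in tree.labels if t not in set(drop)]
    unknown = set(drop) - set(tree.labels)
    if unknown:
        raise ValidationError(f"cannot drop unknown tips: {sorted(unknown)}")
    if not keep:
        raise ValidationError("cannot drop all tips")
    if not drop:
        return tree.copy()

    keep_tip = np.zeros(tree.n_nodes, dtype=bool)
    idx = tree.tip_index()
    for name in keep:
        keep_tip[idx[name]] = True
    # number of retained tips below every node
    count = np.zeros(tree.n_nodes, dtype=int)
    for node in tree.postorder:
        if node < tree.n_tips:
            count[node] = int(keep_tip[node])
        else:
            count[node] = sum(count[c] for c in tree.children[node])

    depth = tree.depths()
    # new root = shallowest node with all retained tips below it that cannot
    # be walked further down (i.e. the MRCA of the retained tips)
    total = count[tree.root]
    new_root = tree.root
    while new_root >= tree.n_tips:
        live = [c for c in tree.children[new_root] if count[c] > 0]
        if len(live) == 1 and count[live[0]] == total:
            new_root = live[0]
        else:
            break

    labels: list[str] = []
    new_parent: list[int] = []
    new_elen: list[float] = []
    internals: list[tuple[int, float, list[int]]] = []  # (old id, depth, child new-ids)

    def build(old: int) -> int | None:
        """Return a token: >=0 tip id, or -(k+2) for internal entry k, None if empty."""
        if old < tree.n_tips:
            if not keep_tip[old]:
                return None
            labels.append(tree.labels[old])
            return len(labels) - 1
        kids = [build(c) for c in tree.children[old]]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]  # suppress degree-2 node; depths keep path lengths
        internals.append((old, depth[old], kids))
        return -(len(internals) - 1 + 2)

    root_token = build(new_root)
    n_new_tips = len(labels)
    n_new = n_new_tips + len(internals)

    def resolve(token: int) -> int:
        return token if token >= 0 else n_new_tips + (-token - 2)

    parent = np.full(n_new, -1, dtype=int)
    elen = np.zeros(n_new)
    new_depth = np.zeros(n_new)
    for k, (_old, d, _kids) in enumerate(internals):
        new_depth[n_new_tips + k] = d
    # tip depths carried over from the original tree
    for i, name in enumerate(labels):
        new_depth[i] = depth[idx[name]]
    root_new = resolve(root_token)
    for k, (_old, d, kids) in enumerate(internals):
        me = n_new_tips + k
        for kid_token in kids:
            kid = resolve(kid_token)
            parent[kid] = me
            elen[kid] = new_depth[kid] - d
    base = new_depth[root_new]
    # shift depths so the new root sits at depth 0
    pruned = Phylogeny(
        labels=labels,
        parent=parent,
        edge_length=elen,
        root_height=float(tree.root_height - base),
    )
    return pruned


def pruned_shared_path(tree: Phylogeny, drop: list[str]) -> np.ndarray:
    """Convenience: covariance of the pruned tree (used by tests/pipeline)."""
    return shared_path_matrix(prune_tree(tree, drop))


def write_trees_newick(trees: list[Phylogeny], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")
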