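"""Rooted time-calibrated trees and phylogenetic covariance matrices.

The :class:`Phylogeny` container stores a rooted tree with branch lengths in
millions of years (Myr).  Node ids are stable integers: tips are numbered
``0 .. n_tips-1`` in Newick input order, internal nodes are numbered
``n_tips .. n_nodes-1`` in post-order, so the root always carries the largest
id.  This ordering is what keys every exported node table.

Trait covariance under the four evolutionary models used for PGLS
(Brownian motion, Pagel's lambda, Early Burst, Ornstein-Uhlenbeck) is built
from the shared-path matrix ``C`` whose entry ``C[i, j]`` is the height above
the root of the most recent common ancestor of tips ``i`` and ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import NewickParseError, ParameterError, ValidationError

MODELS = ("brownian", "lambda", "early_burst", "ou")


@dataclass(frozen=True)
class CovModelSpec:
    """An evolutionary covariance model and its single free parameter.

    ``brownian`` has no parameter; ``lambda`` takes ``parameter`` = λ in
    [0, 1]; ``early_burst`` takes the (non-positive) rate-decay exponent r;
    ``ou`` takes the selection strength α > 0.  The rate scalar σ² is
    profiled out during fitting and is not stored here.
    """

    model: str
    parameter: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ParameterError(f"unknown model {self.model!r}; expected one of {MODELS}")
        p = self.parameter
        if self.model == "brownian":
            if p is not None:
                raise ParameterError("brownian motion has no free covariance parameter")
        elif p is None or not np.isfinite(p):
            raise ParameterError(f"model {self.model!r} requires a finite parameter")
        elif self.model == "lambda" and not 0.0 <= p <= 1.0:
            raise ParameterError(f"lambda must lie in [0, 1], got {p}")
        elif self.model == "early_burst" and p > 0.0:
            raise ParameterError(f"early-burst rate exponent must be <= 0, got {p}")
        elif self.model == "ou" and p <= 0.0:
            raise ParameterError(f"OU alpha must be > 0, got {p}")


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths in Myr and stable integer node ids."""

    labels: list[str]
    parent: np.ndarray            # parent[i] = id of parent node, -1 for root
    edge_length: np.ndarray       # length of the edge above node i (root: 0)
    root_height: float | None = None  # Myr before present; None -> deepest tip at 0
    children: list[list[int]] = field(init=False, repr=False)
    postorder: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.edge_length = np.asarray(self.edge_length, dtype=float)
        n = self.parent.size
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        if np.any(self.edge_length < 0):
            bad = int(np.flatnonzero(self.edge_length < 0)[0])
            raise ValidationError(f"negative edge length above node {bad}")
        self.children = [[] for _ in range(n)]
        roots = []
        for i in range(n):
            if self.parent[i] < 0:
                roots.append(i)
            else:
                self.children[self.parent[i]].append(i)
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {len(roots)}")
        self.postorder = self._postorder(roots[0])
        if self.root_height is None:
            self.root_height = float(self.tip_depths().max())
        ages = self.tip_ages()
        if np.any(~np.isfinite(ages)) or np.any(ages < -1e-9):
            raise ValidationError("a tip lies below the present (age < 0); check root height")

    # -- structure ---------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return self.postorder[-1]

    def _postorder(self, root: int) -> list[int]:
        order: list[int] = []
        stack = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
            else:
                stack.append((node, True))
                for c in reversed(self.children[node]):
                    stack.append((c, False))
        return order

    def depths(self) -> np.ndarray:
        """Cumulative path length from the root to every node (root = 0)."""
        d = np.zeros(self.n_nodes)
        for node in reversed(self.postorder):
            p = self.parent[node]
            if p >= 0:
                d[node] = d[p] + self.edge_length[node]
        return d

    def tip_depths(self) -> np.ndarray:
        return self.depths()[: self.n_tips]

    def tip_ages(self) -> np.ndarray:
        """Myr before present of every tip; 0 for tips reaching the present."""
        return self.root_height - self.tip_depths()

    def node_ages(self) -> np.ndarray:
        return self.root_height - self.depths()

    def tip_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.labels)}

    def clade_tips(self, node: int) -> list[int]:
        """Tip ids below ``node`` (the node itself if it is a tip)."""
        tips: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                tips.append(v)
            else:
                stack.extend(self.children[v])
        return sorted(tips)

    def mrca(self, tips: list[int]) -> int:
        """Most recent common ancestor of a set of tip ids."""
        want = set(tips)
        for node in self.postorder:
            if want <= set(self.clade_tips(node)):
                return node
        raise ValidationError("tip ids not found in tree")

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, root_height: float | None = None) -> "Phylogeny":
        """Parse a Newick string with branch lengths.

        The root height defaults to the maximum root-to-tip path length, i.e.
        the deepest tip is placed at the present.
        """
        _precheck_newick(text)
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises assorted DataError subclasses
            if "duplicate" in str(exc).lower():
                raise ValidationError(f"duplicate tip labels: {exc}") from exc
            raise NewickParseError(f"could not parse Newick string: {exc}") from exc
        return cls._from_dendropy(dtree, root_height)

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree, root_height: float | None) -> "Phylogeny":
        # Collect tips in input (left-to-right) order, then internal nodes in
        # post-order, to realise the documented id scheme.
        leaves, internals = [], []

        def visit(nd):
            if nd.is_leaf():
                leaves.append(nd)
            else:
                for ch in nd.child_nodes():
                    visit(ch)
                internals.append(nd)

        visit(dtree.seed_node)
        ids: dict[int, int] = {}
        labels = []
        for i, nd in enumerate(leaves):
            ids[id(nd)] = i
            name = nd.taxon.label if nd.taxon is not None else (nd.label or f"tip_{i}")
            labels.append(name)
        for j, nd in enumerate(internals):
            ids[id(nd)] = len(leaves) + j
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=int)
        elen = np.zeros(n)
        for nd in leaves + internals:
            me = ids[id(nd)]
            if nd.parent_node is not None:
                parent[me] = ids[id(nd.parent_node)]
                elen[me] = float(nd.edge.length or 0.0)
        return cls(labels=labels, parent=parent, edge_length=elen, root_height=root_height)

    def to_newick(self) -> str:
        """Serialise with branch lengths; parse∘write is the identity."""
        def render(node: int) -> str:
            if node < self.n_tips:
                core = _quote_label(self.labels[node])
            else:
                core = "(" + ",".join(render(c) for c in self.children[node]) + ")"
            if self.parent[node] >= 0:
                return f"{core}:{self.edge_length[node]:.12g}"
            return core

        return render(self.root) + ";"

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            labels=list(self.labels),
            parent=self.parent.copy(),
            edge_length=self.edge_length.copy(),
            root_height=self.root_height,
        )


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _precheck_newick(text: str) -> None:
    """Cheap structural scan so parse errors can name a character offset."""
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at offset {offset}")
    if depth != 0:
        raise NewickParseError(f"{depth} unclosed '(' at end of string (length {len(text)})")
    if ";" not in text:
        raise NewickParseError(f"missing ';' terminator (string length {len(text)})")


# -- covariance construction ------------------------------------------------


def shared_path_matrix(tree: Phylogeny) -> np.ndarray:
    """Brownian-motion covariance: C[i, j] = depth of MRCA(i, j) below the root.

    The diagonal holds root-to-tip path lengths.  Symmetric and positive
    semi-definite by construction.
    """
    if tree.n_tips < 2:
        raise ValidationError("shared_path_matrix requires at least 2 tips")
    n = tree.n_tips
    depth = tree.depths()
    C = np.zeros((n, n))
    C[np.diag_indices(n)] = depth[:n]
    # accumulate tip sets bottom-up; tips split across children share `node`
    tipsets: dict[int, np.ndarray] = {}
    for node in tree.postorder:
        if node < n:
            tipsets[node] = np.array([node])
            continue
        kids = [tipsets.pop(c) for c in tree.children[node]]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                C[np.ix_(kids[a], kids[b])] = depth[node]
                C[np.ix_(kids[b], kids[a])] = depth[node]
        tipsets[node] = np.concatenate(kids)
    return C


def patristic_distance_matrix(tree: Phylogeny) -> np.ndarray:
    C = shared_path_matrix(tree)
    d = np.diag(C)
    return d[:, None] + d[None, :] - 2.0 * C


def model_covariance(tree: Phylogeny, spec: CovModelSpec) -> np.ndarray:
    """Covariance (or correlation, for OU) matrix of tip values under a model.

    * brownian — the shared-path matrix ``C``.
    * lambda — off-diagonals of ``C`` multiplied by λ, diagonal unchanged.
    * early_burst — time is warped by the decelerating-rate integral
      ``t -> (exp(r t) - 1) / r`` before shared paths are measured; the
      r -> 0 limit recovers Brownian motion.
    * ou — stationary correlation ``exp(-alpha * d_ij)`` with unit diagonal,
      where ``d_ij`` is patristic distance.  This convention stays valid on
      non-ultrametric (fossil-bearing) trees; σ² absorbs the overall scale.
    """
    C = shared_path_matrix(tree)
    if spec.model == "brownian":
        return C
    if spec.model == "lambda":
        lam = float(spec.parameter)
        V = C * lam
        np.fill_diagonal(V, np.diag(C))
        return V
    if spec.model == "early_burst":
        r = float(spec.parameter)
        if r == 0.0:
            return C
        return np.expm1(r * C) / r
    # ou
    alpha = float(spec.parameter)
    D = patristic_distance_matrix(tree)
    return np.exp(-alpha * D)


def covariance_frame(tree: Phylogeny, spec: CovModelSpec) -> pd.DataFrame:
    """Labelled covariance matrix, for CSV export."""
    V = model_covariance(tree, spec)
    return pd.DataFrame(V, index=tree.labels, columns=tree.labels)


def write_covariance_csv(tree: Phylogeny, spec: CovModelSpec, path) -> None:
    covariance_frame(tree, spec).to_csv(path)
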