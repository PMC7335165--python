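"""Rooted, branch-length-bearing phylogenies: newick I/O, ages, pruning.

The :class:`Phylogeny` wrapper delegates newick parsing/serialisation to
dendropy and exposes a flat array view (:class:`TreeArrays`) that the
numerical modules (tip statistics, trait models, birth-death likelihoods)
consume.  Trees are treated as immutable once constructed; all mutating
operations return new objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeArrays",
    "NodeAgeMap",
    "TreeError",
    "parse_newick",
    "node_ages",
    "prune_taxa",
]


class TreeError(ValueError):
    """Raised for malformed newick input or invalid tree operations."""


@dataclass(frozen=True)
class TreeArrays:
    """Flat postorder view of a rooted tree.

    Nodes are indexed ``0..n_nodes-1`` with tips occupying indices
    ``0..n_tips-1`` in the order of ``tip_labels``.  ``parent[root] == -1``
    and ``blen[root]`` is the root edge length (0 when absent).
    """

    parent: np.ndarray
    blen: np.ndarray
    postorder: np.ndarray
    children: tuple
    tip_labels: tuple
    root: int

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (root depth 0)."""
        d = np.zeros(self.n_nodes)
        for v in self.postorder[::-1]:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.blen[v]
        return d


@dataclass(frozen=True)
class NodeAgeMap:
    """Node ages in Myr before present, measured from the deepest tip."""

    ages: Mapping[int, float]
    crown_age: float
    ultrametric: bool
    tol: float

    def tip_ages(self, arrays: TreeArrays) -> np.ndarray:
        return np.array([self.ages[i] for i in range(arrays.n_tips)])


class Phylogeny:
    """A rooted tree with finite non-negative branch lengths and unique tips."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._arrays: TreeArrays | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several DataError types
            raise TreeError(f"newick parse error: {exc}") from exc
        return cls(tree)

    def _validate(self) -> None:
        seen = set()
        for leaf in self._tree.leaf_node_iter():
            label = None if leaf.taxon is None else leaf.taxon.label
            if not label:
                raise TreeError("tip with empty or missing label")
            if label in seen:
                raise TreeError(f"duplicate tip label: {label!r}")
            seen.add(label)
        if len(seen) < 2:
            raise TreeError("tree must have at least 2 tips")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            length = node.edge.length
            if length is None:
                raise TreeError(f"missing branch length above {_describe(node)}")
            if not np.isfinite(length) or length < 0:
                raise TreeError(f"invalid branch length {length} above {_describe(node)}")

    # -- basic properties ---------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> tuple:
        return self.arrays.tip_labels

    @property
    def n_tips(self) -> int:
        return len(self.arrays.tip_labels)

    @property
    def is_binary(self) -> bool:
        for node in self._tree.preorder_internal_node_iter():
            if len(node.child_nodes()) != 2:
                return False
        return True

    @property
    def total_length(self) -> float:
        a = self.arrays
        mask = np.ones(a.n_nodes, dtype=bool)
        mask[a.root] = False
        return float(a.blen[mask].sum())

    @property
    def arrays(self) -> TreeArrays:
        if self._arrays is None:
            self._arrays = _build_arrays(self._tree)
        return self._arrays

    # -- I/O ------------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".10g",
        )
        return s.strip() + "\n"

    # -- operations ------------------------------------------------------

    def node_ages(self, tol: float | None = None) -> NodeAgeMap:
        return node_ages(self, tol=tol)

    def prune_taxa(self, drop: Iterable[str]) -> "Phylogeny":
        return prune_taxa(self, drop)

    def clone(self) -> "Phylogeny":
        return Phylogeny(self._tree.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips>"


def _describe(node) -> str:
    if node.taxon is not None:
        return f"tip {node.taxon.label!r}"
    return "an internal node"


def _build_arrays(tree: dendropy.Tree) -> TreeArrays:
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = tuple(lf.taxon.label for lf in leaves)
    index = {}
    for i, lf in enumerate(leaves):
        index[id(lf)] = i
    internals = [nd for nd in tree.preorder_internal_node_iter()]
    for j, nd in enumerate(internals):
        index[id(nd)] = len(leaves) + j
    n = len(leaves) + len(internals)
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n)
    children: list[tuple] = [() for _ in range(n)]
    for nd in tree.preorder_node_iter():
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
        blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
        children[i] = tuple(index[id(c)] for c in nd.child_nodes())
    post = np.array([index[id(nd)] for nd in tree.postorder_node_iter()], dtype=np.int64)
    root = index[id(tree.seed_node)]
    return TreeArrays(
        parent=parent,
        blen=blen,
        postorder=post,
        children=tuple(children),
        tip_labels=labels,
        root=root,
    )


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted newick statement with branch lengths."""
    return Phylogeny.from_newick(text)


DEFAULT_REL_TOL = 1e-6


def node_ages(tree: Phylogeny, tol: float | None = None) -> NodeAgeMap:
    """Node ages as crown age minus root-to-node depth.

    ``tol`` is the absolute tolerance (Myr) for declaring the tree
    ultrametric; by default it is ``1e-6`` times the crown age, which
    absorbs the rounding jitter that dating pipelines leave behind.
    """
    a = tree.arrays
    depths = a.depths()
    tip_depths = depths[: a.n_tips]
    crown = float(tip_depths.max())
    if tol is None:
        tol = DEFAULT_REL_TOL * max(crown, 1.0)
    ultrametric = bool(np.ptp(tip_depths) <= tol)
    ages = {i: crown - float(depths[i]) for i in range(a.n_nodes)}
    return NodeAgeMap(ages=ages, crown_age=crown, ultrametric=ultrametric, tol=float(tol))


def vcv_matrix(tree: Phylogeny) -> np.ndarray:
    """Phylogenetic covariance matrix: shared root-to-MRCA path lengths.

    Entry (i, j) is the depth of the MRCA of tips i and j; the diagonal is
    each tip's root-to-tip depth.  Rows/columns follow ``tree.tip_labels``.
    """
    a = tree.arrays
    depths = a.depths()
    n = a.n_tips
    C = np.zeros((n, n))
    below: list = [None] * a.n_nodes
    for v in a.postorder:
        kids = a.children[v]
        if not kids:
            below[v] = np.array([v], dtype=np.int64)
            C[v, v] = depths[v]
        else:
            groups = [below[c] for c in kids]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    C[np.ix_(groups[i], groups[j])] = depths[v]
                    C[np.ix_(groups[j], groups[i])] = depths[v]
            below[v] = np.concatenate(groups)
    return C


def prune_taxa(tree: Phylogeny, drop: Iterable[str]) -> Phylogeny:
    """Drop tips; collapse resulting unifurcations, summing edge lengths.

    Pairwise path lengths between surviving tips are unchanged.
    """
    drop = set(drop)
    have = set(tree.tip_labels)
    unknown = drop - have
    if unknown:
        raise TreeError(f"unknown tip labels: {sorted(unknown)}")
    if len(have) - len(drop) < 2:
        raise TreeError("pruning would leave fewer than 2 tips")
    if not drop:
        return tree.clone()
    import copy

    t = copy.deepcopy(tree.dendropy_tree)  # independent taxon namespace
    taxa = [t.taxon_namespace.get_taxon(lbl) for lbl in drop]
    t.prune_taxa(taxa, suppress_unifurcations=True)
    for taxon in taxa:
        t.taxon_namespace.remove_taxon(taxon)
    # collapse a unifurcate root left by dendropy: promote the single child
    while len(t.seed_node.child_nodes()) == 1:
        child = t.seed_node.child_nodes()[0]
        child.parent_node = None
        child.edge.length = None
        t.seed_node = child
    return Phylogeny(t)
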