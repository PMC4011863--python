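"""Time-calibrated trees and phylogenetic covariance matrices.

A chronogram (ultrametric tree with branch lengths in Myr) induces the
expected covariance structure of a Brownian-motion trait across its tips:
``V[i, j]`` equals the shared root-to-MRCA path length of tips *i* and *j*,
and ``V[i, i]`` equals the root-to-tip depth.  All comparative methods in
this package (model fitting, PGLS, signal estimation) consume this matrix
or one of its two single-parameter transforms:

* Pagel's lambda: multiply the off-diagonal entries by ``lam`` in [0, 1];
  0 collapses the tree to a star phylogeny, 1 leaves it untouched.
* Ornstein-Uhlenbeck: a restoring pull of strength ``alpha`` toward a
  single optimum erodes shared history exponentially,
  ``V[i, j] = exp(-2 a (T - s_ij)) (1 - exp(-2 a s_ij)) / (2 a)``,
  with the root state at the optimum and variance accumulating from zero.

Newick parsing and serialization are delegated to :mod:`dendropy`; the
matrix construction and transforms live here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "PhyloCov",
    "TreeParseError",
    "read_newick",
    "write_newick",
    "phylo_covariance",
    "shared_path_matrix",
    "lambda_scale",
    "ou_scale",
]

#: Relative tolerance on root-to-tip depths when checking ultrametricity.
ULTRAMETRIC_RTOL = 1e-6


class TreeParseError(ValueError):
    """Raised for malformed Newick input (syntax, duplicate or missing labels,
    missing branch lengths)."""


@dataclass
class PhyloCov:
    """A tip-by-tip phylogenetic covariance matrix with its tip ordering.

    ``V`` is symmetric positive semi-definite; for an untransformed
    ultrametric tree the diagonal equals the tree depth and off-diagonals
    lie in ``[0, depth]``.
    """

    tip_order: list[str]
    V: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        if self.V.shape != (len(self.tip_order), len(self.tip_order)):
            raise ValueError("V shape does not match tip_order length")

    @property
    def n(self) -> int:
        return len(self.tip_order)

    def index_of(self, labels) -> np.ndarray:
        pos = {t: i for i, t in enumerate(self.tip_order)}
        try:
            return np.array([pos[l] for l in labels], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise KeyError(f"tip label {e.args[0]!r} not in covariance matrix") from e

    def subset(self, labels) -> "PhyloCov":
        """Restrict to the given tips (order preserved as given).

        Shared path lengths are unchanged by dropping tips, so the submatrix
        is exactly the covariance of the induced subtree.
        """
        idx = self.index_of(labels)
        return PhyloCov(list(labels), self.V[np.ix_(idx, idx)])


@dataclass
class TimeTree:
    """A rooted time tree with branch lengths in Myr.

    Thin wrapper around a :class:`dendropy.Tree` that pins a canonical tip
    order (Newick traversal order) and caches the shared-path matrix.
    """

    _dtree: dendropy.Tree
    tips: list[str] = field(init=False)
    _spm_cache: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        labels = [lf.taxon.label for lf in self._dtree.leaf_node_iter()]
        if any(l is None or l == "" for l in labels):
            raise TreeParseError("tree contains an unlabeled tip")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeParseError(f"duplicate tip label(s): {', '.join(dup)}")
        self.tips = labels

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        out = {}
        for leaf in self._dtree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length (tree depth, Myr)."""
        return max(self.depths().values())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = np.array(list(self.depths().values()))
        dmax = d.max()
        if dmax == 0:
            return True
        return bool((dmax - d.min()) <= rtol * dmax)


def read_newick(text: str) -> TimeTree:
    """Parse a Newick string into a :class:`TimeTree`.

    Branch lengths are required on every non-root edge; duplicate or missing
    tip labels and syntax errors raise :class:`TreeParseError` naming the
    offence.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as e:
        raise TreeParseError(f"malformed Newick: {e}") from e
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        if dtree.seed_node is None or dtree.seed_node.taxon is None:
            raise TreeParseError("empty tree")
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            label = node.taxon.label if node.taxon else "<internal node>"
            raise TreeParseError(f"missing branch length on edge to {label!r}")
        if node.edge.length < 0:
            label = node.taxon.label if node.taxon else "<internal node>"
            raise TreeParseError(f"negative branch length on edge to {label!r}")
    return TimeTree(dtree)


def write_newick(tree: TimeTree) -> str:
    """Serialize to a Newick string with full-precision branch lengths."""
    s = tree._dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    )
    return s.strip() + "\n"


def shared_path_matrix(tree: TimeTree) -> np.ndarray:
    """Matrix of shared root-to-MRCA path lengths ``s_ij`` in tip order.

    Computed by a single postorder sweep: tip pairs split across the children
    of a node at depth *d* share exactly *d* of their root paths.
    """
    if tree._spm_cache is not None:
        return tree._spm_cache
    n = tree.n_tips
    idx = {t: i for i, t in enumerate(tree.tips)}
    S = np.zeros((n, n))
    # depth of every node from the root
    node_depth: dict[int, float] = {id(tree._dtree.seed_node): 0.0}
    for node in tree._dtree.preorder_node_iter():
        if node.parent_node is not None:
            node_depth[id(node)] = node_depth[id(node.parent_node)] + (
                node.edge.length or 0.0
            )
    below: dict[int, list[int]] = {}
    for node in tree._dtree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            S[i, i] = node_depth[id(node)]
            below[id(node)] = [i]
        else:
            d = node_depth[id(node)]
            kids = [below[id(c)] for c in node.child_nodes()]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            S[i, j] = S[j, i] = d
            below[id(node)] = [i for k in kids for i in k]
    tree._spm_cache = S
    return S


def phylo_covariance(tree: TimeTree) -> PhyloCov:
    """Brownian-motion covariance of the tree: ``V_ij = s_ij``, ``V_ii`` the
    root-to-tip depth.

    Warns (does not fail) if the tree is not ultrametric within tolerance.
    """
    if not tree.is_ultrametric():
        import warnings

        warnings.warn(
            "tree is not ultrametric within tolerance; covariance diagonal "
            "will not be constant",
            stacklevel=2,
        )
    return PhyloCov(list(tree.tips), shared_path_matrix(tree).copy())


def lambda_scale(cov: PhyloCov, lam: float) -> PhyloCov:
    """Pagel's lambda transform: off-diagonals multiplied by ``lam``.

    ``lam`` must lie in [0, 1]; 1 is the identity, 0 the star-tree limit.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    V = cov.V * lam
    np.fill_diagonal(V, np.diag(cov.V))
    return PhyloCov(list(cov.tip_order), V)


def ou_scale(tree: TimeTree, alpha: float) -> PhyloCov:
    """Ornstein-Uhlenbeck covariance of an ultrametric tree.

    ``V_ij = exp(-2 a (T - s_ij)) (1 - exp(-2 a s_ij)) / (2 a)`` with the
    root state at the optimum; the overall rate sigma^2 is *not* baked in and
    is fitted separately.  As ``alpha -> 0`` this tends to the Brownian
    covariance ``s_ij``; for large ``alpha`` tips decorrelate and the
    diagonal tends to the stationary variance ``1 / (2 a)``.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if not tree.is_ultrametric():
        raise ValueError("OU transform requires an ultrametric tree")
    S = shared_path_matrix(tree)
    T = tree.depth
    V = np.exp(-2.0 * alpha * (T - S)) * (-np.expm1(-2.0 * alpha * S)) / (2.0 * alpha)
    return PhyloCov(list(tree.tips), V)
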