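"""Time-calibrated trees and the phylogenetic covariance structure.

Trees are rooted chronograms with branch lengths in Myr. Parsing and pruning
are delegated to :mod:`dendropy`; the covariance computation (shared
root-to-MRCA path lengths, the Brownian-motion covariance of tip values) is
implemented here.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Chronogram",
    "PhyloCovariance",
    "NotUltrametricWarning",
    "read_newick",
    "prune_to",
    "phylo_covariance",
    "write_covariance_csv",
]

#: relative tolerance for the ultrametricity check on tip depths
ULTRAMETRIC_RTOL = 1e-6


class NotUltrametricWarning(UserWarning):
    """Tip depths deviate from the root age beyond tolerance.

    Dating software rounds branch lengths, so this is a warning rather than
    an error; downstream covariance math is still well defined.
    """


class NewickError(ValueError):
    """Malformed newick input or missing branch lengths."""


@dataclass
class Chronogram:
    """A rooted, (nominally) ultrametric tree with branch lengths in Myr."""

    _tree: dendropy.Tree
    tip_labels: tuple[str, ...] = field(init=False)
    root_age: float = field(init=False)

    def __post_init__(self) -> None:
        tips = [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]
        if len(set(tips)) != len(tips):
            raise NewickError("duplicate tip labels")
        self.tip_labels = tuple(tips)
        depths = self.tip_depths()
        self.root_age = float(max(depths.values()))
        self._check_ultrametric(depths)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Chronogram":
        return read_newick(text)

    # -- interrogation -----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip."""
        depths: dict[str, float] = {}
        for label, depth in self._node_depths()[1].items():
            depths[label] = depth
        return depths

    def _node_depths(self):
        """Depth of every node from the root; returns (node->depth, tip label->depth)."""
        node_depth: dict[dendropy.Node, float] = {}
        tip_depth: dict[str, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                # a root edge length (a stem retained by pruning) offsets all
                # depths so tip depths and shared paths match the full tree
                node_depth[node] = float(node.edge.length or 0.0)
                continue
            length = node.edge.length
            if length is None:
                raise NewickError("branch without a length")
            if length < 0:
                raise NewickError(f"negative branch length {length}")
            node_depth[node] = node_depth[node.parent_node] + float(length)
            if node.is_leaf():
                tip_depth[node.taxon.label] = node_depth[node]
        if not tip_depth:  # single-node tree
            for node in self._tree.leaf_node_iter():
                tip_depth[node.taxon.label] = 0.0
        return node_depth, tip_depth

    def _check_ultrametric(self, depths: dict[str, float]) -> None:
        if not depths:
            return
        dmax = max(depths.values())
        dmin = min(depths.values())
        if dmax > 0 and (dmax - dmin) / dmax > ULTRAMETRIC_RTOL:
            warnings.warn(
                f"tree is not ultrametric: tip depths span [{dmin:g}, {dmax:g}]",
                NotUltrametricWarning,
                stacklevel=3,
            )

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        depths = list(self.tip_depths().values())
        dmax = max(depths)
        return dmax == 0 or (dmax - min(depths)) / dmax <= rtol

    # -- export ------------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return s.strip() + ("" if s.strip().endswith(";") else ";")

    def clone(self) -> "Chronogram":
        return Chronogram(self._tree.clone(depth=1))


def read_newick(text: str) -> Chronogram:
    """Parse a newick string into a :class:`Chronogram`.

    Branch lengths are mandatory on every non-root edge. Internal node
    support/annotation labels are tolerated and ignored. A tree whose tip
    depths disagree beyond ``ULTRAMETRIC_RTOL`` triggers
    :class:`NotUltrametricWarning` but still parses.
    """
    text = text.strip()
    if not text:
        raise NewickError("empty newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"newick parse failure: {exc}") from exc
    for label in (t.label for t in tree.taxon_namespace):
        if label is None:
            raise NewickError("unnamed tip")
    # trim whitespace on tip names: exact matching downstream, no fuzz
    for taxon in tree.taxon_namespace:
        taxon.label = taxon.label.strip()
    return Chronogram(tree)


def prune_to(tree: Chronogram, keep: Iterable[str]) -> Chronogram:
    """Prune to the given taxa, collapsing unifurcations by summing lengths.

    Tip depths are preserved, so the covariance of the pruned tree is the
    corresponding submatrix of the full covariance.
    """
    keep = [str(t).strip() for t in keep]
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")
    unknown = sorted(set(keep) - set(tree.tip_labels))
    if unknown:
        raise KeyError(f"taxa not in tree: {unknown}")
    pruned = tree._tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=False
    )
    # Collapse unifurcations below the root by summing the incident branch
    # lengths. The root itself is allowed to keep a single child (the stem up
    # to the kept taxa's MRCA): preserving that stem keeps every tip depth —
    # and hence the covariance submatrix — identical to the full tree.
    for node in list(pruned.preorder_node_iter()):
        parent = node.parent_node
        if parent is None:
            continue
        children = node.child_nodes()
        if len(children) == 1:
            child = children[0]
            child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
            parent.remove_child(node)
            parent.add_child(child)
    return Chronogram(pruned)


@dataclass(frozen=True)
class PhyloCovariance:
    """Shared-path-length matrix C of a chronogram in a fixed taxon order.

    Under Brownian motion, tip values have covariance ``sigma2 * C`` where
    ``C[i, j]`` is the root-to-MRCA(i, j) path length and ``C[i, i]`` the
    depth of tip i.
    """

    taxa: tuple[str, ...]
    C: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("covariance shape does not match taxon count")
        object.__setattr__(self, "C", C)

    def submatrix(self, taxa: Sequence[str]) -> "PhyloCovariance":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(tuple(taxa), self.C[np.ix_(idx, idx)])


def phylo_covariance(tree: Chronogram, taxa: Sequence[str] | None = None) -> PhyloCovariance:
    """Brownian-motion covariance structure of the tips, in ``taxa`` order.

    ``taxa`` must be a permutation of the tree's tip labels (defaults to the
    tree's own tip order).
    """
    if taxa is None:
        taxa = tree.tip_labels
    taxa = tuple(str(t).strip() for t in taxa)
    if sorted(taxa) != sorted(tree.tip_labels):
        raise ValueError("taxa must be a permutation of the tree's tip labels")
    index = {label: i for i, label in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))
    node_depth, _ = tree._node_depths()

    # postorder sweep: at each internal node, tip pairs drawn from different
    # child subtrees have their MRCA here, so C[i, j] = this node's depth.
    tips_below: dict[dendropy.Node, list[int]] = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = node_depth[node]
            tips_below[node] = [i]
            continue
        children = node.child_nodes()
        groups = [tips_below.pop(ch) for ch in children]
        depth = node_depth[node]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = np.asarray(groups[a])
                ib = np.asarray(groups[b])
                C[np.ix_(ia, ib)] = depth
                C[np.ix_(ib, ia)] = depth
        tips_below[node] = [i for g in groups for i in g]
    return PhyloCovariance(taxa, C)


def write_covariance_csv(cov: PhyloCovariance, path_or_buf) -> None:
    """CSV export with a header row/column of taxon names."""
    import pandas as pd

    df = pd.DataFrame(cov.C, index=list(cov.taxa), columns=list(cov.taxa))
    if isinstance(path_or_buf, (str,)):
        df.to_csv(path_or_buf)
    elif isinstance(path_or_buf, io.IOBase) or hasattr(path_or_buf, "write"):
        df.to_csv(path_or_buf)
    else:
        df.to_csv(str(path_or_buf))
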