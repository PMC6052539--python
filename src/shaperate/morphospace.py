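"""Phylomorphospace: PCA of mean shapes with the phylogeny projected through
Brownian-motion ancestral states of the score columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .landmarks import ShapeMatrix
from .rates import _covariance_roots
from .trees import Chronogram, phylo_covariance

__all__ = ["MorphospaceResult", "pca", "ancestral_states", "phylomorphospace"]


def pca(Y: ShapeMatrix | np.ndarray):
    """Column-centered PCA with a deterministic sign convention.

    Returns ``(scores, loadings, variance_explained)`` where the variance
    fractions cover the full spectrum (they sum to 1) and each component's
    largest-magnitude loading is positive.
    """
    data = Y.Y if isinstance(Y, ShapeMatrix) else np.asarray(Y, dtype=float)
    n, p = data.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 rows")
    X = data - data.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("degenerate input: zero variance")
    for j in range(len(s)):
        col = Vt[j]
        if col[np.argmax(np.abs(col))] < 0:
            Vt[j] = -col
            U[:, j] = -U[:, j]
    scores = U * s
    loadings = Vt.T
    var = s**2
    variance_explained = var / var.sum()
    return scores, loadings, variance_explained


def ancestral_states(
    tree: Chronogram, X: np.ndarray, taxa: Sequence[str] | None = None
):
    """ML (GLS) Brownian-motion estimates of trait values at internal nodes.

    ``X`` holds one row per tip in ``taxa`` order (defaults to the tree's tip
    order). Implemented as the conditional expectation
    ``a_hat_v = mu_hat + C_vt C^-1 (x - mu_hat 1)`` per trait, where C_vt is
    the shared-path length between internal node v and each tip and mu_hat is
    the GLS root estimate; for Brownian motion this equals the joint ML
    reconstruction. Returns ``(node_values, node_ids, edges)`` where nodes are
    indexed tips-first (tip i = index i, internal nodes follow in preorder)
    and ``edges`` lists (parent_index, child_index) pairs covering every
    branch exactly once.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if taxa is None:
        taxa = tree.tip_labels
    taxa = tuple(taxa)
    if X.shape[0] != len(taxa):
        raise ValueError("one row per taxon required")
    cov = phylo_covariance(tree, taxa)
    n = len(taxa)
    tip_index = {t: i for i, t in enumerate(taxa)}

    node_depth, _ = tree._node_depths()
    internal = [nd for nd in tree._tree.preorder_node_iter() if not nd.is_leaf()]
    node_of_index: dict = {}
    index_of_node: dict = {}
    for j, nd in enumerate(internal):
        index_of_node[nd] = n + j
        node_of_index[n + j] = nd

    # shared path between internal node v and tip t: depth of the deepest
    # common ancestor = depth(v) if t descends from v, else depth(MRCA)
    tips_below: dict = {}
    for nd in tree._tree.postorder_node_iter():
        if nd.is_leaf():
            tips_below[nd] = {tip_index[nd.taxon.label]}
        else:
            tips_below[nd] = set().union(*(tips_below[ch] for ch in nd.child_nodes()))
    V = np.zeros((len(internal), n))
    for j, v in enumerate(internal):
        below = tips_below[v]
        V[j, list(below)] = node_depth[v]
        anc = v.parent_node
        while anc is not None:
            outside = tips_below[anc] - below
            if outside:
                V[j, list(outside)] = np.maximum(V[j, list(outside)], node_depth[anc])
            below = tips_below[anc]
            anc = anc.parent_node

    inv_half, _, w = _covariance_roots(cov.C)
    mu = w @ X  # GLS root mean, one per trait
    resid = X - mu
    Cinv_resid = inv_half @ (inv_half @ resid)
    node_values = mu + V @ Cinv_resid

    edges: list[tuple[int, int]] = []
    for nd in internal:
        for ch in nd.child_nodes():
            child_idx = (
                tip_index[ch.taxon.label] if ch.is_leaf() else index_of_node[ch]
            )
            edges.append((index_of_node[nd], child_idx))
    node_ids = [f"node{j}" for j in range(len(internal))]
    return node_values, node_ids, edges


@dataclass(frozen=True)
class MorphospaceResult:
    taxa: tuple[str, ...]
    tip_scores: np.ndarray
    node_scores: np.ndarray
    edges: tuple[tuple[int, int], ...]
    variance_explained: np.ndarray
    loadings: np.ndarray

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        for key in ("tip_scores", "node_scores", "variance_explained", "loadings"):
            d[key] = np.asarray(d[key]).tolist()
        d["edges"] = [list(e) for e in self.edges]
        d["taxa"] = list(self.taxa)
        return json.dumps(d, sort_keys=True, **kwargs)

    def to_csv(self, path) -> None:
        import pandas as pd

        n = len(self.taxa)
        labels = list(self.taxa) + [f"node{j}" for j in range(len(self.node_scores))]
        kind = ["tip"] * n + ["node"] * len(self.node_scores)
        pts = np.vstack([self.tip_scores, self.node_scores])
        pd.DataFrame(
            {"label": labels, "kind": kind, "pc1": pts[:, 0], "pc2": pts[:, 1]}
        ).to_csv(path, index=False)

    def plot(self, ax=None, group_of=None):
        """Optional matplotlib rendering; everything scientific lives in the
        data fields, so this stays a thin display layer."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = np.vstack([self.tip_scores, self.node_scores])
        for a, b in self.edges:
            ax.plot(pts[[a, b], 0], pts[[a, b], 1], color="0.7", lw=0.8, zorder=1)
        colors = None
        if group_of is not None:
            labels = sorted(set(group_of[t] for t in self.taxa))
            cmap = {g: f"C{i}" for i, g in enumerate(labels)}
            colors = [cmap[group_of[t]] for t in self.taxa]
        ax.scatter(self.tip_scores[:, 0], self.tip_scores[:, 1], c=colors, zorder=2)
        ax.set_xlabel(f"PC1 ({100 * self.variance_explained[0]:.0f}%)")
        ax.set_ylabel(f"PC2 ({100 * self.variance_explained[1]:.0f}%)")
        return ax


def phylomorphospace(
    tree: Chronogram, Y: ShapeMatrix, n_components: int = 2
) -> MorphospaceResult:
    """Project tips and BM ancestral states into the first principal components."""
    if Y.n < 3:
        raise ValueError("phylomorphospace needs at least 3 taxa")
    if sorted(Y.taxa) != sorted(tree.tip_labels):
        raise ValueError("taxa of tree and shape matrix do not match")
    scores, loadings, variance_explained = pca(Y)
    m = min(n_components, scores.shape[1])
    tip_scores = scores[:, :m]
    node_scores, _, edges = ancestral_states(tree, tip_scores, Y.taxa)
    return MorphospaceResult(
        taxa=Y.taxa,
        tip_scores=tip_scores,
        node_scores=node_scores,
        edges=tuple(edges),
        variance_explained=variance_explained,
        loadings=loadings[:, :m],
    )
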