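"""Patristic (cophenetic) distances between the tips of a phylogeny.

Every null model downstream consumes the tip-to-tip distance matrix, never
the tree itself: the "taxa labels" randomization is exactly a relabeling of
this matrix, so distances are computed once and cached in an array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PhyloTree, ValidationError

__all__ = ["PairwiseDistanceMatrix", "cophenetic_matrix"]


@dataclass
class PairwiseDistanceMatrix:
    """Symmetric matrix of path-length distances between taxa.

    ``d[i, j]`` is the sum of branch lengths along the unique path between
    tips ``labels[i]`` and ``labels[j]``, in the tree's branch-length units.
    """

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValidationError("distances must be finite and non-negative")

    def reorder(self, labels) -> "PairwiseDistanceMatrix":
        """Return a copy with rows/columns in the given label order."""
        idx = [self.labels.index(l) for l in labels]
        return PairwiseDistanceMatrix(list(labels), self.d[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="taxon")


def cophenetic_matrix(tree: PhyloTree, labels=None) -> PairwiseDistanceMatrix:
    """Compute all tip-to-tip patristic distances of a tree.

    Distances are accumulated in a single postorder pass: each internal node
    combines the tip-to-ancestor path lengths of its child subtrees, so the
    whole matrix costs O(n^2) regardless of tree shape.

    Parameters
    ----------
    tree
        Validated phylogeny (branch lengths guaranteed present).
    labels
        Optional output row/column order; defaults to the tree's tip order.
        Must be a subset of the tree's tips.
    """
    tips = tree.tip_labels
    index = {label: i for i, label in enumerate(tips)}
    n = len(tips)
    d = np.zeros((n, n))
    # depths[node] maps tip index -> path length from that tip up to node
    depths: dict[int, dict[int, float]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            depths[id(node)] = {index[node.taxon.label]: 0.0}
            continue
        children = node.child_nodes()
        merged: dict[int, float] = {}
        done: list[dict[int, float]] = []
        for child in children:
            bl = child.edge.length or 0.0
            sub = {tip: dist + bl for tip, dist in depths.pop(id(child)).items()}
            for prev in done:
                for i, di in prev.items():
                    for j, dj in sub.items():
                        d[i, j] = d[j, i] = di + dj
            done.append(sub)
            merged.update(sub)
        depths[id(node)] = merged
    order = list(labels) if labels is not None else tips
    missing = [l for l in order if l not in index]
    if missing:
        raise ValidationError(f"labels not in tree: {missing}")
    idx = [index[l] for l in order]
    return PairwiseDistanceMatrix(order, d[np.ix_(idx, idx)])
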