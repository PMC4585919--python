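"""Euclidean distances and average-linkage (UPGMA) hierarchical clustering.

The agglomeration is implemented directly rather than delegated to
:func:`scipy.cluster.hierarchy.linkage` because the pipeline needs a fully
specified tie-break rule — when several cluster pairs attain the minimal
average distance, the pair whose smallest original leaf indices are
lexicographically least is merged — so that results are deterministic and
invariant to input permutation up to relabeling.  SciPy's linkage serves as
an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .partition import Partition

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "standardize",
    "euclidean_distances",
    "average_linkage",
    "cut",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, zero-diagonal, non-negative pairwise distances with entity IDs."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(v < 0):
            raise ValueError("negative distances")
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class Dendrogram:
    """Result of agglomerative clustering.

    ``merges`` lists the n−1 agglomeration steps as ``(left, right, height)``
    where left/right are node indices: 0..n−1 are leaves (in ``leaf_ids``
    order) and n+t is the cluster created by merge step t.
    """

    leaf_ids: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(h for _, _, h in self.merges)

    def to_newick(self) -> str:
        """Serialize as a Newick string; branch lengths are height deltas."""
        n = self.n_leaves
        node_height = {i: 0.0 for i in range(n)}
        node_str = {i: self.leaf_ids[i] for i in range(n)}
        for t, (a, b, h) in enumerate(self.merges):
            node = n + t
            node_height[node] = h
            la = max(h - node_height[a], 0.0)
            lb = max(h - node_height[b], 0.0)
            node_str[node] = f"({node_str[a]}:{la:g},{node_str[b]}:{lb:g})"
        root = n + len(self.merges) - 1 if self.merges else 0
        return node_str[root] + ";"


def standardize(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across samples (rows = genes).

    Constant genes (zero standard deviation) are mapped to all-zero rows
    rather than NaN so they carry no weight in sample distances.
    """
    # contiguous copy so reduction order does not depend on the frame's layout
    values = np.ascontiguousarray(expr.to_numpy(dtype=float))
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((values - mean) / sd, index=expr.index, columns=expr.columns)


def euclidean_distances(expr: pd.DataFrame, axis: str = "samples") -> DistanceMatrix:
    """Pairwise Euclidean distances over genes or samples of an expression matrix.

    Parameters
    ----------
    expr
        Genes × samples expression matrix.
    axis
        ``"samples"`` treats each sample as a point in gene space;
        ``"genes"`` treats each gene as a point in sample space.
    """
    if axis not in ("samples", "genes"):
        raise ValueError(f"axis must be 'samples' or 'genes', got {axis!r}")
    data = expr.T if axis == "samples" else expr
    if data.shape[0] < 2:
        raise ValueError(f"need at least 2 {axis}, got {data.shape[0]}")
    if data.isna().to_numpy().any():
        raise ValueError(
            "expression matrix contains missing values; impute first "
            "(e.g. io.impute_gene_means)"
        )
    dm = squareform(pdist(data.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(tuple(str(i) for i in data.index), dm)


def average_linkage(dm: DistanceMatrix) -> Dendrogram:
    """UPGMA agglomeration with a deterministic tie-break.

    At each step the pair of active clusters with minimal mean inter-cluster
    distance is merged; the distance of the merged cluster to every other
    cluster is the size-weighted average of its parents' distances.  Among
    tied pairs the one whose (smaller, larger) smallest-original-leaf indices
    sort lexicographically least is merged, which makes the merge sequence a
    pure function of the distance values and the input order.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    total = 2 * n - 1
    big = np.full((total, total), np.inf)
    big[:n, :n] = dm.values
    np.fill_diagonal(big, np.inf)
    size = np.zeros(total, dtype=np.int64)
    size[:n] = 1
    min_leaf = np.arange(total)
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        act = np.array(active)
        sub = big[np.ix_(act, act)]
        iu, ju = np.triu_indices(len(act), k=1)
        dvals = sub[iu, ju]
        h = dvals.min()
        ties = np.flatnonzero(dvals == h)
        # lexicographic tie-break on sorted smallest-leaf index pairs
        best = min(
            ties,
            key=lambda t: tuple(sorted((min_leaf[act[iu[t]]], min_leaf[act[ju[t]]]))),
        )
        a, b = int(act[iu[best]]), int(act[ju[best]])
        if min_leaf[b] < min_leaf[a]:
            a, b = b, a
        new = n + step
        others = [c for c in active if c != a and c != b]
        if others:
            oth = np.array(others)
            upd = (size[a] * big[a, oth] + size[b] * big[b, oth]) / (size[a] + size[b])
            big[new, oth] = upd
            big[oth, new] = upd
        size[new] = size[a] + size[b]
        min_leaf[new] = min(min_leaf[a], min_leaf[b])
        merges.append((a, b, float(h)))
        active = others + [new]
    return Dendrogram(dm.ids, tuple(merges))


def cut(dendrogram: Dendrogram, k: int) -> Partition:
    """Cut a dendrogram into exactly k clusters by undoing the last k−1 merges.

    Cluster labels are ``C1..Ck``, numbered by each cluster's earliest leaf
    in input order, so the labeling is deterministic.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):  # apply all but the last k-1 merges
        a, b, _ = dendrogram.merges[t]
        node = n + t
        parent[find(a)] = node
        parent[find(b)] = node
    roots: dict[int, list[int]] = {}
    for leaf in range(n):
        roots.setdefault(find(leaf), []).append(leaf)
    # label clusters by earliest member leaf
    ordered = sorted(roots.values(), key=lambda members: members[0])
    clusters = {
        f"C{i + 1}": [dendrogram.leaf_ids[m] for m in members]
        for i, members in enumerate(ordered)
    }
    return Partition.from_clusters(clusters)
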