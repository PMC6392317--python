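"""Hierarchical agglomerative clustering of risk profiles.

Ward's minimum-variance criterion on squared Euclidean distances, run through
the Lance–Williams recurrence

    d(k, i∪j) = [(n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) − n_k d(i,j)]
                / (n_i + n_j + n_k)

with deterministic tie-breaking (lowest leaf-index pair).  Merge heights are
the Lance–Williams distances themselves; with squared Euclidean input Ward
admits no inversions, so heights are non-decreasing.  Cophenetic distances
(the height at which two leaves first share a cluster) validate the
dendrogram against the original distances, and split-half re-clustering
probes the stability of the groupings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "MergeTree",
    "squared_euclidean",
    "ward_agglomerate",
    "cophenetic_distances",
    "cophenetic_correlation",
    "cut_tree",
    "cut_tree_k",
    "co_membership_agreement",
    "split_half_stability",
    "to_newick",
    "merge_table",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with item labels."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape mismatch with ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class MergeTree:
    """Agglomeration history: for n leaves, n−1 merges.

    Clusters are numbered scipy-style: leaves 0..n−1, the cluster created by
    merge t gets id n+t.  ``merges`` rows are (cluster_a, cluster_b, height,
    size of the new cluster).
    """

    leaf_ids: tuple[str, ...]
    merges: list[tuple[int, int, float, int]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def members(self) -> dict[int, list[int]]:
        """Cluster id → leaf indices."""
        n = self.n_leaves
        out: dict[int, list[int]] = {i: [i] for i in range(n)}
        for t, (a, b, _, _) in enumerate(self.merges):
            out[n + t] = out[a] + out[b]
        return out


def squared_euclidean(matrix: pd.DataFrame | np.ndarray,
                      ids: Sequence[str] | None = None) -> DistanceMatrix:
    """Pairwise squared Euclidean distances between the rows of a features
    matrix.  Missing values are rejected with the offending item/feature
    named — exclusion decisions must be made upstream, explicitly."""
    if isinstance(matrix, pd.DataFrame):
        if matrix.isna().any().any():
            bad = [(i, c) for i, c in zip(*np.where(matrix.isna().to_numpy()))]
            i, c = bad[0]
            raise ValueError(
                f"missing feature value at item {matrix.index[i]!r}, "
                f"feature {matrix.columns[c]!r}")
        ids = tuple(str(i) for i in matrix.index)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        if np.isnan(x).any():
            i, c = np.argwhere(np.isnan(x))[0]
            raise ValueError(f"missing feature value at item {i}, feature {c}")
        ids = tuple(ids) if ids is not None else tuple(str(i) for i in range(len(x)))
    if len(x) < 2:
        raise ValueError("need at least 2 items")
    sq = (x[:, None, :] - x[None, :, :]) ** 2
    d = sq.sum(axis=2)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(ids=ids, values=d)


def ward_agglomerate(D: DistanceMatrix) -> MergeTree:
    """Agglomerate by Ward's criterion via the Lance–Williams recurrence.

    At each step the active pair with the smallest current distance is
    merged; ties break on the lexicographically smallest pair of smallest
    leaf indices, so runs are reproducible across platforms.
    """
    n = D.n
    if n < 2:
        raise ValueError("need at least 2 items to agglomerate")
    d = D.values.astype(float).copy()
    size = {i: 1 for i in range(n)}
    minleaf = {i: i for i in range(n)}          # tie-break key
    active = set(range(n))
    dist = {}                                    # (lo, hi) cluster-id pairs
    for i, j in itertools.combinations(range(n), 2):
        dist[(i, j)] = d[i, j]

    def get(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    tree = MergeTree(leaf_ids=D.ids)
    next_id = n
    for _ in range(n - 1):
        best = None
        best_key = None
        for a, b in itertools.combinations(sorted(active), 2):
            val = get(a, b)
            key = (val, min(minleaf[a], minleaf[b]), max(minleaf[a], minleaf[b]))
            if best_key is None or key < best_key:
                best_key = key
                best = (a, b)
        i, j = best
        h = get(i, j)
        ni, nj = size[i], size[j]
        new = next_id
        next_id += 1
        for k in active - {i, j}:
            nk = size[k]
            dk = ((ni + nk) * get(k, i) + (nj + nk) * get(k, j)
                  - nk * h) / (ni + nj + nk)
            dist[(min(k, new), max(k, new))] = dk
        active -= {i, j}
        active.add(new)
        size[new] = ni + nj
        minleaf[new] = min(minleaf[i], minleaf[j])
        tree.merges.append((i, j, float(h), ni + nj))
    return tree


def cophenetic_distances(tree: MergeTree) -> np.ndarray:
    """Full matrix of cophenetic distances: the merge height at which each
    pair of leaves first joins the same cluster."""
    n = tree.n_leaves
    coph = np.zeros((n, n))
    members = {i: [i] for i in range(n)}
    for t, (a, b, h, _) in enumerate(tree.merges):
        for x in members[a]:
            for y in members[b]:
                coph[x, y] = coph[y, x] = h
        members[n + t] = members.pop(a) + members.pop(b)
    return coph


def cophenetic_correlation(D: DistanceMatrix, tree: MergeTree) -> float | None:
    """Pearson correlation between original and cophenetic distances over the
    n(n−1)/2 pairs; ``None`` when either vector is constant (undefined)."""
    if tuple(tree.leaf_ids) != tuple(D.ids):
        raise ValueError("tree was not built from this distance matrix's items")
    iu = np.triu_indices(D.n, k=1)
    orig = D.values[iu]
    coph = cophenetic_distances(tree)[iu]
    if np.ptp(orig) == 0 or np.ptp(coph) == 0:
        return None
    r = float(np.corrcoef(orig, coph)[0, 1])
    return max(-1.0, min(1.0, r))


def cut_tree(tree: MergeTree, height: float) -> pd.Series:
    """Cluster assignment from merges strictly below ``height``.

    Returns a Series leaf id → cluster label (labels numbered by first
    appearance in leaf order).  height 0 leaves every item a singleton;
    any height above the root yields one cluster.
    """
    if height < 0:
        raise ValueError("cut height must be non-negative")
    n = tree.n_leaves
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (a, b, h, _) in enumerate(tree.merges):
        if h < height:
            new = n + t
            parent[find(a)] = new
            parent[find(b)] = new
    roots = [find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    labels = []
    for r in roots:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    return pd.Series(labels, index=list(tree.leaf_ids), name="cluster")


def cut_tree_k(tree: MergeTree, k: int) -> pd.Series:
    """Cluster assignment with exactly ``k`` clusters: apply the first n−k
    merges of the agglomeration (robust to tied heights)."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        a, b, _, _ = tree.merges[t]
        new = n + t
        parent[find(a)] = new
        parent[find(b)] = new
    roots = [find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    labels = []
    for r in roots:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    return pd.Series(labels, index=list(tree.leaf_ids), name="cluster")


def co_membership_agreement(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Rand-style pairwise co-membership agreement between two clusterings,
    restricted to the items present in both."""
    common = labels_a.index.intersection(labels_b.index)
    if len(common) < 2:
        raise ValueError("need at least 2 shared items")
    a = labels_a.loc[common].to_numpy()
    b = labels_b.loc[common].to_numpy()
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(len(common), k=1)
    return float((same_a[iu] == same_b[iu]).mean())


def split_half_stability(
    matrix: pd.DataFrame,
    n_splits: int,
    seed: int,
    *,
    n_clusters: int = 2,
) -> dict:
    """Split-half stability of the clustering of ``matrix`` rows.

    Each split assigns a random integer in [1, 5000] to every item, sorts by
    it and divides the order into two halves; each half is re-clustered and
    compared (pairwise co-membership) with the full solution restricted to
    that half.  A half is cut into as many clusters as the full solution has
    represented within it (at most ``n_clusters``), so a half that happens to
    draw items from a single full-solution cluster is not forced to split
    them.  Deterministic under ``seed``.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if len(matrix) < 4:
        raise ValueError("need at least 4 items for split-half analysis")
    rng = np.random.default_rng(seed)
    full = cut_tree_k(ward_agglomerate(squared_euclidean(matrix)), n_clusters)
    splits = []
    for s in range(n_splits):
        keys = rng.integers(1, 5001, size=len(matrix))
        order = np.argsort(keys, kind="stable")
        half_n = len(matrix) // 2
        halves = (order[:half_n], order[half_n:])
        agreements = []
        for idx in halves:
            sub = matrix.iloc[np.sort(idx)]
            k = min(int(full.loc[sub.index].nunique()), len(sub))
            labels = cut_tree_k(ward_agglomerate(squared_euclidean(sub)), k)
            agreements.append(co_membership_agreement(labels, full))
        splits.append({"split": s, "agreement_half1": agreements[0],
                       "agreement_half2": agreements[1]})
    all_agree = [v for s in splits for v in (s["agreement_half1"], s["agreement_half2"])]
    return {
        "seed": seed,
        "n_splits": n_splits,
        "n_clusters": n_clusters,
        "splits": splits,
        "mean_agreement": float(np.mean(all_agree)),
        "min_agreement": float(np.min(all_agree)),
    }


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def merge_table(tree: MergeTree) -> pd.DataFrame:
    """Merge history as a table (cluster_a, cluster_b, height, size)."""
    return pd.DataFrame(tree.merges,
                        columns=["cluster_a", "cluster_b", "height", "size"])


def to_newick(tree: MergeTree) -> str:
    """Serialize the dendrogram as Newick with branch lengths set so each
    leaf/node sits at its merge height below its parent."""
    n = tree.n_leaves
    height_of = {i: 0.0 for i in range(n)}
    node_str = {i: tree.leaf_ids[i] for i in range(n)}
    for t, (a, b, h, _) in enumerate(tree.merges):
        new = n + t
        la = h - height_of[a]
        lb = h - height_of[b]
        node_str[new] = f"({node_str[a]}:{la:.12g},{node_str[b]}:{lb:.12g})"
        height_of[new] = h
    root = n + len(tree.merges) - 1
    return node_str[root] + ";"
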