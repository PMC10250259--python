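"""Category discovery from a group RDM.

The analysis mirrors standard practice for behavioral similarity data:
pick the linkage whose cophenetic distances best correlate with the raw
dissimilarities, build the UPGMA (average-linkage) tree, choose the number
of clusters by scanning the mean silhouette index over a range of cuts,
and drop clusters below a minimum size before treating the remainder as
categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster, linkage, to_tree

from .rdm import RDM


class ClusteringError(ValueError):
    pass


DEFAULT_LINKAGE_METHODS = ("single", "complete", "average", "weighted")


@dataclass(frozen=True)
class DendrogramModel:
    """Agglomerative merge table in scipy linkage form plus the method name."""

    Z: np.ndarray  # (n-1, 4): left, right, height, size
    method: str

    def __post_init__(self):
        Z = np.asarray(self.Z, dtype=float)
        n = Z.shape[0] + 1
        sizes = Z[:, 3]
        if not np.all(sizes >= 2) or sizes[-1] != n:
            raise ClusteringError("merge-table sizes are inconsistent")
        object.__setattr__(self, "Z", Z)

    @property
    def n_leaves(self) -> int:
        return self.Z.shape[0] + 1


@dataclass(frozen=True)
class CategoryAssignment:
    """Item-to-category map after singleton filtering."""

    assignment: dict            # item_id -> category label
    dropped: tuple              # items removed with their sub-min_size clusters
    k_total: int                # clusters before filtering
    labels: tuple = field(default_factory=tuple)  # retained category labels

    @property
    def categories(self) -> tuple:
        return self.labels

    def members(self, category: str) -> list:
        return [i for i, c in self.assignment.items() if c == category]


def cophenetic_score(rdm: RDM, method: str) -> float:
    """Pearson correlation between RDM distances and cophenetic tree distances."""
    if np.ptp(rdm.d) == 0:
        raise ClusteringError("cophenetic correlation undefined for a constant RDM")
    Z = linkage(rdm.d, method=method)
    c, _ = cophenet(Z, rdm.d)
    return float(c)


def select_linkage(rdm: RDM, methods=DEFAULT_LINKAGE_METHODS):
    """Best linkage by cophenetic correlation; ties broken by list order.

    Returns ``(best_method, {method: score})``.
    """
    methods = list(methods)
    if not methods:
        raise ClusteringError("need at least one linkage method")
    table = {m: cophenetic_score(rdm, m) for m in methods}
    best = methods[0]
    for m in methods[1:]:
        if table[m] > table[best]:
            best = m
    return best, table


def upgma_tree(rdm: RDM) -> DendrogramModel:
    """UPGMA tree: merge the two clusters with the smallest mean cross-pair distance."""
    if rdm.n < 2:
        raise ClusteringError("need at least two items to build a tree")
    return DendrogramModel(linkage(rdm.d, method="average"), "average")


def cut_tree(tree: DendrogramModel, k: int) -> np.ndarray:
    """Cluster labels (1..k) from cutting the tree into (at most) k clusters."""
    if not (1 <= k <= tree.n_leaves):
        raise ClusteringError(f"cannot cut {tree.n_leaves}-leaf tree into {k} clusters")
    return fcluster(tree.Z, t=k, criterion="maxclust")


def silhouette_samples_precomputed(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette s(i) = (b - a)/max(a, b) on a precomputed matrix.

    a(i): mean distance to own cluster excluding self; b(i): smallest mean
    distance to another cluster.  Points in singleton clusters score 0
    (Rousseeuw's convention).
    """
    labels = np.asarray(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        return np.zeros(labels.size)
    onehot = np.zeros((labels.size, uniq.size))
    onehot[np.arange(labels.size), inv] = 1.0
    sums = D @ onehot                      # (n, k) summed distance to each cluster
    counts = onehot.sum(axis=0)            # (k,)
    own = counts[inv]
    s = np.zeros(labels.size)
    multi = own > 1
    a = np.zeros(labels.size)
    a[multi] = sums[np.arange(labels.size), inv][multi] / (own[multi] - 1)
    mean_to = sums / counts                # (n, k)
    mean_to[np.arange(labels.size), inv] = np.inf
    b = mean_to.min(axis=1)
    denom = np.maximum(a, b)
    ok = multi & (denom > 0)
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    return s


def silhouette_scan(rdm: RDM, tree: DendrogramModel, k_min: int = 3, k_max: int = 50):
    """Mean silhouette per candidate cluster count; best k by max (ties: smallest k).

    Returns ``(best_k, {k: mean_silhouette})``.
    """
    if k_min > k_max:
        raise ClusteringError(f"empty scan range [{k_min}, {k_max}]")
    if k_max >= rdm.n:
        raise ClusteringError("k_max must be smaller than the number of items")
    D = rdm.to_square()
    scores: dict = {}
    for k in range(k_min, k_max + 1):
        labels = cut_tree(tree, k)
        scores[k] = float(np.mean(silhouette_samples_precomputed(D, labels)))
    best_k = min(scores, key=lambda k: (-scores[k], k))
    return best_k, scores


def extract_categories(
    tree: DendrogramModel,
    k: int,
    item_ids,
    min_size: int = 2,
    label_fmt: str = "C{:02d}",
) -> CategoryAssignment:
    """Cut at k clusters and drop clusters with fewer than ``min_size`` items.

    Retained clusters get placeholder labels in order of first appearance;
    human-readable labels attach downstream.
    """
    item_ids = tuple(item_ids)
    if len(item_ids) != tree.n_leaves:
        raise ClusteringError("item_ids length does not match tree leaves")
    raw = cut_tree(tree, k)
    sizes = {c: int(np.sum(raw == c)) for c in np.unique(raw)}
    assignment: dict = {}
    dropped: list = []
    relabel: dict = {}
    labels: list = []
    for item, c in zip(item_ids, raw):
        if sizes[c] < min_size:
            dropped.append(item)
            continue
        if c not in relabel:
            relabel[c] = label_fmt.format(len(relabel) + 1)
            labels.append(relabel[c])
        assignment[item] = relabel[c]
    return CategoryAssignment(assignment, tuple(dropped), k_total=len(sizes), labels=tuple(labels))


def to_newick(tree: DendrogramModel, item_ids) -> str:
    """Newick string of the dendrogram (branch lengths from merge heights)."""
    item_ids = tuple(item_ids)
    root = to_tree(tree.Z)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{item_ids[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(root, root.dist) + ";"
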