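"""Representational dissimilarity matrices (RDMs) and their 2-D embedding.

An RDM holds one dissimilarity per unordered pair of items, stored as a
condensed vector (the strict upper triangle in lexicographic pair order,
the same convention as :func:`scipy.spatial.distance.pdist`).  The RDM is
the lingua franca of this package: behavioral multi-arrangement data,
feature-rating models, and category structures are all compared in this
form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS


class RDMError(ValueError):
    """Invalid RDM construction or incompatible RDM operands."""


@dataclass(frozen=True)
class RDM:
    """Condensed representational dissimilarity matrix.

    Parameters
    ----------
    item_ids : tuple of str
        Unique, ordered item identifiers (n items).
    d : ndarray, shape (n*(n-1)/2,)
        Non-negative finite dissimilarities, pair (i, j) with i < j stored
        at ``condensed_index(i, j, n)``.
    meta : dict
        Free-form provenance tags.
    """

    item_ids: tuple
    d: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = tuple(self.item_ids)
        object.__setattr__(self, "item_ids", ids)
        if len(set(ids)) != len(ids):
            raise RDMError("item_ids must be unique")
        d = np.asarray(self.d, dtype=float)
        n = len(ids)
        if d.ndim != 1 or d.size != n * (n - 1) // 2:
            raise RDMError(
                f"condensed vector has length {d.size}, expected {n * (n - 1) // 2} for {n} items"
            )
        if not np.all(np.isfinite(d)):
            raise RDMError("dissimilarities must be finite")
        if np.any(d < 0):
            raise RDMError("dissimilarities must be non-negative")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return len(self.item_ids)

    def to_square(self) -> np.ndarray:
        """Full symmetric matrix with a zero diagonal."""
        return squareform(self.d, checks=False)

    @classmethod
    def from_square(cls, item_ids: Sequence[str], mat: np.ndarray, meta: dict | None = None) -> "RDM":
        mat = np.asarray(mat, dtype=float)
        if mat.shape != (len(item_ids), len(item_ids)):
            raise RDMError("square matrix shape does not match item count")
        if not np.allclose(mat, mat.T, atol=1e-8):
            raise RDMError("matrix is not symmetric (tolerance 1e-8)")
        sym = 0.5 * (mat + mat.T)
        np.fill_diagonal(sym, 0.0)
        return cls(tuple(item_ids), squareform(sym, checks=False), meta or {})

    def pair(self, a: str, b: str) -> float:
        i, j = self.item_ids.index(a), self.item_ids.index(b)
        return float(self.d[condensed_index(i, j, self.n)])


def condensed_index(i: int, j: int, n: int) -> int:
    """Index of unordered pair (i, j) in a condensed vector over n items.

    Pairs are ordered lexicographically by (min, max); indices are 0-based.
    """
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"item index out of range for n={n}: ({i}, {j})")
    if i == j:
        raise ValueError(f"pair ({i}, {i}) is undefined: dissimilarity needs two distinct items")
    if i > j:
        i, j = j, i
    return i * n - i * (i + 1) // 2 + (j - i - 1)


def condensed_pairs(n: int) -> np.ndarray:
    """(m, 2) array of the (i, j) pairs in condensed order."""
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


def euclidean_rdm(X: np.ndarray, item_ids: Sequence[str] | None = None, meta: dict | None = None) -> RDM:
    """RDM of pairwise Euclidean distances between the rows of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise RDMError("need at least two rows")
    if not np.all(np.isfinite(X)):
        raise RDMError("input contains non-finite values")
    if item_ids is None:
        item_ids = tuple(f"item{i:03d}" for i in range(X.shape[0]))
    return RDM(tuple(item_ids), pdist(X), meta or {})


def average_rdms(rdms: Sequence[RDM]) -> RDM:
    """Entrywise arithmetic mean of RDMs sharing one item set and order."""
    rdms = list(rdms)
    if not rdms:
        raise RDMError("no RDMs to average")
    ids = rdms[0].item_ids
    for r in rdms[1:]:
        if r.item_ids != ids:
            raise RDMError("cannot average RDMs with mismatched item sets/orderings")
    d = np.mean([r.d for r in rdms], axis=0)
    return RDM(ids, d, {"n_averaged": len(rdms)})


# ---------------------------------------------------------------------------
# 2-D embedding


@dataclass(frozen=True)
class Embedding:
    """2-D configuration of an RDM with its stress value."""

    item_ids: tuple
    coords: np.ndarray  # (n, 2)
    stress: float
    variant: str = "nonmetric"

    def __post_init__(self):
        if self.coords.shape != (len(self.item_ids), 2):
            raise RDMError("one coordinate row per item required")
        if self.stress < 0:
            raise RDMError("stress must be >= 0")


def evaluate_stress(rdm: RDM, coords: np.ndarray, variant: str = "nonmetric") -> float:
    """Kruskal stress-1 of a configuration against an RDM.

    ``nonmetric`` fits monotone disparities to the configuration distances
    by isotonic regression over the rank order of the input dissimilarities;
    ``metric`` uses the raw dissimilarities as disparities after a
    least-squares scale fit.  Both return
    sqrt(sum((dhat - dist)^2) / sum(dist^2)).
    """
    dist = pdist(np.asarray(coords, dtype=float))
    dis = rdm.d
    den = float(np.sum(dist**2))
    if den == 0.0:
        return 0.0 if np.all(dis == 0) else float("inf")
    if variant == "nonmetric":
        order = np.argsort(dis, kind="stable")
        dhat = IsotonicRegression().fit_transform(np.arange(dis.size), dist[order])
        num = float(np.sum((dist[order] - dhat) ** 2))
    elif variant == "metric":
        scale = float(np.dot(dis, dist) / np.dot(dis, dis)) if np.any(dis) else 0.0
        num = float(np.sum((scale * dis - dist) ** 2))
    else:
        raise ValueError(f"unknown stress variant: {variant!r}")
    return float(np.sqrt(num / den))


def embed_2d(
    rdm: RDM,
    seed: int,
    restarts: int = 8,
    variant: str = "nonmetric",
    max_iter: int = 1000,
    eps: float = 1e-11,
) -> Embedding:
    """Best-of-``restarts`` SMACOF 2-D embedding of an RDM.

    The non-metric variant (default) minimizes Kruskal stress-1 with
    monotone regression; the metric variant fits raw dissimilarities.
    Deterministic given ``seed``.
    """
    if rdm.n < 3:
        raise RDMError("2-D embedding needs at least three items")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if variant not in ("nonmetric", "metric"):
        raise ValueError(f"unknown MDS variant: {variant!r}")
    D = rdm.to_square()
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        # one classical-scaling-initialized run plus random restarts
        for init, n_init in (("classical_mds", 1), ("random", restarts)):
            mds = MDS(
                n_components=2,
                metric_mds=(variant == "metric"),
                metric="precomputed",
                init=init,
                n_init=n_init,
                max_iter=max_iter,
                eps=eps,
                random_state=int(seed),
                normalized_stress=(variant == "nonmetric"),
            )
            coords = mds.fit_transform(D)
            stress = evaluate_stress(rdm, coords, variant=variant)
            if best is None or stress < best[0]:
                best = (stress, coords)
    return Embedding(rdm.item_ids, best[1], best[0], variant)
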